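import numpy as np
import pytest

from orthok.meshing import (LensDesign, MeshError, build_cornea_mesh,
                            build_lens_mesh, build_lens_profile,
                            default_lens_design, disk_grid,
                            spherical_template_map, sphere_shell_mesh)
from orthok.topography import RadialSurface, extend_surface


@pytest.mark.parametrize("base, rings", [(2, 3), (4, 30), (6, 12)])
def test_disk_grid_counts(base, rings):
    pts, quads, perimeter = disk_grid(base, rings)
    assert pts.shape[0] == (base + 1) ** 2 + 4 * base * rings
    assert quads.shape[0] == base**2 + 4 * base * rings
    assert perimeter.size == 4 * base
    assert np.allclose(np.hypot(*pts[perimeter].T), 1.0)


def _sphere_radial(R=5.0):
    az = np.linspace(0, 360, 72, endpoint=False)
    el = np.linspace(0, 1.2, 100)
    return RadialSurface(np.zeros(3), az, el, np.full((72, 100), R))


def test_template_map_sphere_exact():
    rs = _sphere_radial(5.0)
    az = np.array([3.3, 100.1, 250.7])
    el = np.array([0.15, 0.6, 1.1])
    pts = spherical_template_map(rs, az, el)
    assert np.abs(np.linalg.norm(pts, axis=1) - 5.0).max() < 1e-9


def test_template_map_passthrough_at_grid_directions():
    rng = np.random.default_rng(0)
    az = np.linspace(0, 360, 72, endpoint=False)
    el = np.linspace(0, 1.2, 100)
    grid = 5.0 + 0.05 * rng.random((72, 100))
    rs = RadialSurface(np.zeros(3), az, el, grid)
    pts = spherical_template_map(rs, np.repeat(az[5], el.size), el)
    assert np.abs(np.linalg.norm(pts, axis=1) - grid[5]).max() < 1e-9


def test_template_map_ellipsoid_matches_closed_form():
    A, B, C = 5.2, 4.8, 5.6
    az = np.linspace(0, 360, 180, endpoint=False)
    el = np.linspace(0, 1.3, 240)
    TH, EL = np.meshgrid(np.deg2rad(az), el, indexing="ij")
    inv_r2 = ((np.sin(EL) * np.cos(TH) / A) ** 2
              + (np.sin(EL) * np.sin(TH) / B) ** 2 + (np.cos(EL) / C) ** 2)
    rs = RadialSurface(np.zeros(3), az, el, 1.0 / np.sqrt(inv_r2))
    q_az = np.array([13.7, 95.2, 201.9, 333.1])
    q_el = np.array([0.21, 0.55, 0.9, 1.2])
    pts = spherical_template_map(rs, q_az, q_el)
    r_got = np.linalg.norm(pts, axis=1)
    a, e = np.deg2rad(q_az), q_el
    r_true = 1.0 / np.sqrt((np.sin(e) * np.cos(a) / A) ** 2
                           + (np.sin(e) * np.sin(a) / B) ** 2
                           + (np.cos(e) / C) ** 2)
    assert np.abs(r_got / r_true - 1).max() < 1e-4


def test_query_outside_angular_support_raises():
    rs = _sphere_radial()
    with pytest.raises(ValueError, match="angular support"):
        spherical_template_map(rs, np.array([0.0]), np.array([1.5]))


def test_cornea_mesh_thickness_law(toric_record):
    ext = extend_surface(toric_record)
    cct = 0.554
    mesh = build_cornea_mesh(ext, cct)
    mesh.check()
    ant = mesh.nodes[mesh.node_sets["anterior_nodes"]]
    post = mesh.nodes[: ant.shape[0]]          # layer 0 = posterior
    t = np.linalg.norm(ant - post, axis=1)
    r_lat = np.hypot(ant[:, 0], ant[:, 1])
    apex = np.argmin(r_lat)
    assert abs(t[apex] - cct) < 1e-6
    # linear law everywhere: t(r) = cct + 0.18 * min(r/5.5, 1); at half the
    # limbal radius that is cct + 0.09
    law = cct + 0.18 * np.minimum(r_lat / 5.5, 1.0)
    assert np.abs(t - law).max() < 1e-6
    assert abs(np.interp(2.75, np.sort(r_lat),
                         law[np.argsort(r_lat)]) - (cct + 0.09)) < 1e-9
    rim = r_lat > 5.5
    assert np.allclose(t[rim], cct + 0.18, atol=1e-6)


def test_cornea_anterior_reproduces_surface(toric_record):
    ext = extend_surface(toric_record)
    radial = ext.to_radial()
    mesh = build_cornea_mesh(ext, 0.554)
    ant = mesh.nodes[mesh.node_sets["anterior_nodes"]]
    assert np.abs(radial.signed_gap(ant)).max() < 1e-6
    # element count for the desk template is documented: (b^2+4 b r) layers
    assert mesh.n_elems == (16 + 4 * 4 * 12) * 5


def test_lens_profile_continuity_and_thickness(lens_design):
    prof = build_lens_profile(lens_design)
    assert prof.junction_gaps().max() < 1e-6
    ct = prof.front_at(np.array([0.0]))[0] - prof.back_at(np.array([0.0]))[0]
    assert abs(ct - 0.22) < 1e-12


def test_inconsistent_zone_widths_rejected():
    with pytest.raises(ValueError, match="widths sum"):
        LensDesign(base_width=3.5)


def test_lens_mesh_counts_and_profile(lens_design, lens_mesh):
    per_layer = 4**2 + 4 * 4 * 30
    assert lens_mesh.n_elems == per_layer * 2
    lens_mesh.check()
    prof = build_lens_profile(lens_design)
    back = lens_mesh.nodes[lens_mesh.node_sets["back_nodes"]]
    rb = np.hypot(back[:, 0], back[:, 1])
    assert np.abs(back[:, 2] - prof.back_at(rb)).max() < 1e-6
    front = lens_mesh.nodes[lens_mesh.node_sets["front_nodes"]]
    rf = np.hypot(front[:, 0], front[:, 1])
    assert np.abs(front[:, 2] - prof.front_at(rf)).max() < 1e-6


def test_lens_mesh_quarter_turn_symmetry(lens_mesh):
    c, s = 0.0, 1.0
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    rotated = lens_mesh.nodes @ R.T
    key = lambda pts: np.lexsort((np.round(pts[:, 2], 9), np.round(pts[:, 1], 9),
                                  np.round(pts[:, 0], 9)))
    orig = lens_mesh.nodes[key(lens_mesh.nodes)]
    rot = rotated[key(rotated)]
    assert np.allclose(orig, rot, atol=1e-9)


def test_sphere_shell_mesh_is_watertight():
    shell = sphere_shell_mesh(11.5, 12.05, base=4, rings=8, layers=2)
    shell.check()
    rn = np.linalg.norm(shell.nodes, axis=1)
    assert rn.min() > 11.5 - 1e-9 and rn.max() < 12.05 + 1e-9


def test_exports_round_trip_counts(tmp_path, lens_mesh):
    vtk = tmp_path / "lens.vtk"
    inp = tmp_path / "lens.inp"
    lens_mesh.to_vtk(vtk)
    lens_mesh.to_inp(inp)
    lines = vtk.read_text().splitlines()
    assert f"POINTS {lens_mesh.n_nodes} double" in lines
    assert f"CELL_TYPES {lens_mesh.n_elems}" in lines
    text = inp.read_text()
    assert "*ELEMENT, TYPE=C3D8" in text
    assert "*SURFACE, TYPE=ELEMENT, NAME=LENS_BACK" in text
    assert text.count("\n") > lens_mesh.n_nodes + lens_mesh.n_elems
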