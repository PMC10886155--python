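import numpy as np
import pytest

from orthok.eyelid import (EyelidBoundary, build_eyelid_mesh,
                           detect_eyelid_boundary, landmark_bins)
from orthok.synthetic import generate_coverage_mask
from orthok.topography import default_polar_grid

TABLE_UPPER = (-0.0832, -0.0262, 3.5809)
TABLE_LOWER = (0.0842, 0.0163, -3.9734)


def _lid_mask(upper=TABLE_UPPER, lower=TABLE_LOWER, slits=0):
    az, r = default_polar_grid()
    lids = EyelidBoundary(upper, lower)
    return generate_coverage_mask(lids, az, r, slit_count=slits), az, r


def test_mean_parabolas_recovered_within_5_percent():
    mask, az, r = _lid_mask()
    det = detect_eyelid_boundary(mask, az, r)
    assert det is not None
    for got, want in zip(det.upper, TABLE_UPPER):
        assert abs(got - want) <= 0.05 * abs(want)
    for got, want in zip(det.lower, TABLE_LOWER):
        assert abs(got - want) <= 0.05 * abs(want)


def test_recovery_survives_lash_slits():
    az, r = default_polar_grid()
    lids = EyelidBoundary(TABLE_UPPER, TABLE_LOWER)
    mask = generate_coverage_mask(lids, az, r, slit_count=6,
                                  rng=np.random.default_rng(4))
    det = detect_eyelid_boundary(mask, az, r)
    assert det is not None
    assert abs(det.upper[2] - TABLE_UPPER[2]) <= 0.05 * TABLE_UPPER[2]


def test_circular_mask_reports_no_lid():
    az, r = default_polar_grid()
    mask = generate_coverage_mask(None, az, r)
    assert detect_eyelid_boundary(mask, az, r) is None


def test_histogram_mechanics_single_bin():
    lows, counts = landmark_bins(np.full(37, 5.0))
    assert lows.size == 1
    assert np.isclose(lows[0], 4.8)
    assert counts[0] == 37


def test_landmark_radii_invariant_under_rotation():
    mask, az, r = _lid_mask()
    det = detect_eyelid_boundary(mask, az, r)
    centre = np.array([det.landmarks_upper.mean(axis=0),
                       det.landmarks_lower.mean(axis=0)]).mean(axis=0)
    # rotating the mask rotates the boundary but leaves radii (about the
    # geometric centre) unchanged: compare histograms
    shift = 75   # grid steps of 1.2 deg
    rot = np.roll(mask, shift, axis=0)
    det_r = detect_eyelid_boundary(rot, az, r)
    all_r = np.sort(np.hypot(*np.vstack([det.landmarks_upper,
                                         det.landmarks_lower]).T))
    all_r2 = np.sort(np.hypot(*np.vstack([det_r.landmarks_upper,
                                          det_r.landmarks_lower]).T))
    # same landmark count and radii multiset (rotation maps grid to grid)
    assert all_r.size == all_r2.size
    assert np.allclose(all_r, all_r2, atol=1e-9)


def test_mirror_symmetric_mask_gives_mirrored_fits():
    up = (-0.08, 0.03, 3.6)
    lo = (0.08, -0.02, -3.9)
    mask, az, r = _lid_mask(up, lo)
    det = detect_eyelid_boundary(mask, az, r)
    mirrored_mask, _, _ = _lid_mask((up[0], -up[1], up[2]), (lo[0], -lo[1], lo[2]))
    det_m = detect_eyelid_boundary(mirrored_mask, az, r)
    assert np.isclose(det.upper[1], -det_m.upper[1], atol=0.01)
    assert np.isclose(det.upper[0], det_m.upper[0], atol=0.003)


def test_boundary_validation():
    with pytest.raises(ValueError, match="concavity"):
        EyelidBoundary((0.05, 0.0, 3.5), (0.08, 0.0, -3.9))
    with pytest.raises(ValueError, match="vertex"):
        EyelidBoundary((-0.05, 0.0, -3.5), (0.08, 0.0, -3.9))


def test_eyelid_mesh_counts_and_thickness(toric_radial):
    lids = EyelidBoundary(TABLE_UPPER, TABLE_LOWER)
    mesh = build_eyelid_mesh(lids, toric_radial)
    assert mesh.n_elems == 50 * 40 * 2 == 4000
    assert mesh.n_nodes == 51 * 41 * 3 == 6273
    assert np.all(mesh.jacobians() > 0)
    back = mesh.nodes[mesh.node_sets["back_nodes"]]
    outer = mesh.nodes[mesh.node_sets["outer_nodes"]]
    t = np.linalg.norm(outer - back, axis=1)
    assert np.all(np.abs(t - 0.5) <= 0.005)
    assert "eyelid_perimeter" in mesh.node_sets
    assert {"eyelid_back", "eyelid_outer"} <= set(mesh.facet_sets)
    mesh.check()


def test_eyelid_mesh_clears_the_anterior_surface(toric_radial):
    lids = EyelidBoundary(TABLE_UPPER, TABLE_LOWER)
    mesh = build_eyelid_mesh(lids, toric_radial, clearance_mm=0.05)
    back = mesh.nodes[mesh.node_sets["back_nodes"]]
    gaps = toric_radial.signed_gap(back)
    assert gaps.min() > 0.04
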