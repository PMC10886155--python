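import numpy as np
import pytest

from orthok import fea
from orthok.fea import elements
from orthok.fea.verification import lame_benchmark, patch_test
from orthok.meshing import HexMesh, build_cornea_mesh, sphere_shell_mesh
from orthok.topography import extend_surface


def test_patch_test_exact_to_machine_precision():
    err_target, err_other = patch_test()
    assert err_target < 1e-12
    assert err_other < 1e-12


@pytest.mark.parametrize("age, E", [(18.0, 0.2576), (38.0, 0.3216)])
def test_age_modulus_law(age, E):
    assert abs(fea.young_modulus_from_age(age) - E) < 1e-12


def test_age_modulus_limits():
    assert abs(fea.young_modulus_from_age(1e-9) - 0.2) < 1e-9
    with pytest.raises(ValueError):
        fea.young_modulus_from_age(0.0)


def test_lame_thick_sphere_within_2_percent():
    res = lame_benchmark(preset="desk")
    assert res.u_rel_err < 0.02
    assert res.hoop_rel_err < 0.02


def test_lame_error_decreases_under_refinement():
    errs = [lame_benchmark(preset=p).u_rel_err
            for p in ("coarse", "desk", "fine")]
    assert errs[0] > errs[1] > errs[2]


def test_zero_load_zero_response():
    shell = sphere_shell_mesh(11.5, 12.05, 4, 6, 2)
    model = fea.FEModel(shell, 0.25, 0.49)
    model.fix_rigid_modes()
    res = model.solve([fea.PressureLoad(shell.facet_quads("inner_wall"), 0.0)])
    assert np.abs(res.u).max() < 1e-12
    assert np.abs(res.gp_stress).max() < 1e-12


def test_global_equilibrium_of_reactions(toric_record):
    ext = extend_surface(toric_record)
    mesh = build_cornea_mesh(ext, 0.554, base=4, rings=8)
    model = fea.FEModel(mesh, 0.25, 0.49)
    model.fix(mesh.node_sets["rim_fixed"])
    load = fea.PressureLoad(mesh.facet_quads("inner_wall"), 15 * fea.MMHG_TO_MPA)
    res = model.solve([load], increments=2, tol=1e-9)
    reactions = model.reactions(res, [load])
    f_ext = load.nodal_forces(mesh.nodes)
    imbalance = np.linalg.norm(reactions.sum(axis=0) + f_ext.sum(axis=0))
    assert imbalance <= 1e-6 * max(np.linalg.norm(f_ext, axis=1).sum(), 1e-12)


def test_scalar_fields_are_frame_indifferent():
    """Rotating the whole scene leaves Mises/pressure/principal maps unchanged."""
    shell = sphere_shell_mesh(11.5, 12.05, 4, 6, 2)
    p = 2e-3

    def mises_of(mesh):
        model = fea.FEModel(mesh, 0.25, 0.49)
        model.add_springs(np.arange(mesh.n_nodes), 1e-9)
        res = model.solve([fea.PressureLoad(mesh.facet_quads("inner_wall"), p)],
                          tol=1e-10)
        T = elements.voigt_to_tensor(res.gp_stress)
        dev = T - np.trace(T, axis1=-2, axis2=-1)[..., None, None] / 3 * np.eye(3)
        return np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))

    base = mises_of(shell)
    ang = 0.7
    R = np.array([[np.cos(ang), -np.sin(ang), 0],
                  [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
    R2 = np.array([[1.0, 0, 0], [0, np.cos(0.3), -np.sin(0.3)],
                   [0, np.sin(0.3), np.cos(0.3)]])
    rotated = shell.transform(R2 @ R, np.zeros(3))
    rot = mises_of(rotated)
    denom = np.abs(base).max()
    assert np.abs(base - rot).max() / denom < 1e-8


def test_stress_free_zero_iop_is_identity(toric_record):
    ext = extend_surface(toric_record)
    mesh = build_cornea_mesh(ext, 0.554, base=4, rings=8)
    out, history = fea.find_stress_free_geometry(mesh, 0.25, 0.49, 0.0)
    assert np.array_equal(out.nodes, mesh.nodes)


def test_stress_free_residuals_decrease(toric_record):
    ext = extend_surface(toric_record)
    mesh = build_cornea_mesh(ext, 0.554, base=4, rings=8)
    _, history = fea.find_stress_free_geometry(mesh, 0.245, 0.49, 15.0,
                                               accelerate=False)
    assert all(b < a for a, b in zip(history[1:], history[2:]))


def test_uniaxial_extraction_analytics():
    """Mises, pressure, principal stress and log strain on a uniaxial state."""
    nodes = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                      [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], float)
    mesh = HexMesh(nodes, np.array([[0, 1, 2, 3, 4, 5, 6, 7]]), {},
                   {"top": np.array([[0, 1]])})
    model = fea.FEModel(mesh, 1.0, 0.3)
    model.fix([0]); model.fix([1], dofs=(1, 2))
    model.fix([2], dofs=(2,)); model.fix([3], dofs=(2,))
    sigma = 0.4
    res = model.solve([fea.PressureLoad(mesh.facet_quads("top"), -sigma)], tol=1e-13)
    T = elements.voigt_to_tensor(res.gp_stress)[0, 0]
    dev = T - np.trace(T) / 3 * np.eye(3)
    assert abs(np.sqrt(1.5 * np.sum(dev * dev)) - sigma) < 1e-12     # Mises
    assert abs(-np.trace(T) / 3 - (-sigma / 3)) < 1e-12              # pressure
    assert abs(np.linalg.eigvalsh(T)[-1] - sigma) < 1e-12            # max principal
    F = elements.deformation_gradients(model.dNdX, mesh.elems,
                                       res.u.reshape(-1, 3))
    lnV = elements.log_strain_tensors(F)[0, 0]
    lam = 1.0 + sigma / 1.0            # engineering stretch, small strain
    assert abs(np.linalg.eigvalsh(lnV)[-1] - np.log(lam)) < 1e-3


def test_hydrostatic_state_analytics():
    s = -0.2 * np.eye(3)                # compression sigma*I with sigma=-0.2
    dev = s - np.trace(s) / 3 * np.eye(3)
    assert np.sqrt(1.5 * np.sum(dev * dev)) < 1e-12
    assert -np.trace(s) / 3 == pytest.approx(0.2)


def test_fea_rpc_is_zero_for_rigid_motion(toric_record):
    """A rigid-body displacement of the anterior eye changes no curvature."""
    ext = extend_surface(toric_record)
    mesh = build_cornea_mesh(ext, 0.554, base=4, rings=12)
    model = fea.FEModel(mesh, 0.25, 0.49)
    n = mesh.n_nodes
    u_pre = np.zeros(3 * n)
    ang = np.deg2rad(0.5)
    R = np.array([[1, 0, 0], [0, np.cos(ang), -np.sin(ang)],
                  [0, np.sin(ang), np.cos(ang)]])
    moved = mesh.nodes @ R.T + np.array([0.05, -0.03, 0.08])
    u_post = (moved - mesh.nodes).reshape(-1)
    zeros = np.zeros((mesh.n_elems, 8, 6))
    pre = fea.StepResult("iop_inflation", u_pre, zeros, {}, 0, 0.0)
    post = fea.StepResult("eyelid_closure", u_post, zeros, {}, 0, 0.0)
    prog = fea.ProgramResult(
        model=model, mesh=mesh, node_ranges={"cornea": (0, n)},
        elem_ranges={"cornea": (0, mesh.n_elems)},
        result=fea.FEAResult(mesh=mesh, steps=[pre, post]),
        loads_at_end=[], contacts=[],
        anterior_node_ids=mesh.node_sets["anterior_nodes"],
        anterior_quads=mesh.facet_quads("anterior_surface"),
        program=fea.LoadProgram())
    rpc = fea.fea_rpc(prog, n_az=90, n_r=90)
    inner = rpc.radii_mm < 5.0
    assert np.nanmax(np.abs(rpc.values[:, inner])) < 0.01


def test_central_indentation_flattens_the_map(toric_record):
    ext = extend_surface(toric_record)
    mesh = build_cornea_mesh(ext, 0.554, base=4, rings=12)
    model = fea.FEModel(mesh, 0.25, 0.49)
    n = mesh.n_nodes
    ids = mesh.node_sets["anterior_nodes"]
    ant = mesh.nodes[ids]
    rl = np.hypot(ant[:, 0], ant[:, 1])
    u_post = np.zeros((n, 3))
    u_post[ids, 2] = -0.02 * np.exp(-(rl / 1.5) ** 2)   # inward central dent
    zeros = np.zeros((mesh.n_elems, 8, 6))
    pre = fea.StepResult("iop_inflation", np.zeros(3 * n), zeros, {}, 0, 0.0)
    post = fea.StepResult("eyelid_closure", u_post.reshape(-1), zeros, {}, 0, 0.0)
    prog = fea.ProgramResult(
        model=model, mesh=mesh, node_ranges={"cornea": (0, n)},
        elem_ranges={"cornea": (0, mesh.n_elems)},
        result=fea.FEAResult(mesh=mesh, steps=[pre, post]),
        loads_at_end=[], contacts=[],
        anterior_node_ids=ids, anterior_quads=mesh.facet_quads("anterior_surface"),
        program=fea.LoadProgram())
    rpc = fea.fea_rpc(prog, n_az=90, n_r=90)
    centre = np.nanmean(rpc.values[:, rpc.radii_mm < 0.7])
    assert centre < -0.5
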