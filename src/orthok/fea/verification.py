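"""Solver verification problems with closed-form solutions.

The thick-walled sphere under internal pressure (Lame) exercises the
full 3-D element/assembly/solve path on the benchmark geometry
(a = 11.5 mm, b = 12.05 mm, E = 0.25 MPa, nu = 0.49, p = 2 kPa), close
to the inflated-eye regime; the single-element uniform-traction patch
test checks consistency to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..meshing import HexMesh, sphere_shell_mesh
from .elements import voigt_to_tensor
from .model import FEModel, PressureLoad

# (base, rings, layers) of each hemisphere cap of the shell
SPHERE_PRESETS = {"coarse": (4, 8, 2), "desk": (6, 12, 3), "fine": (8, 16, 3)}


def lame_solution(r, a, b, E, nu, p):
    """(radial displacement, radial stress, hoop stress) at radius r."""
    C = p * a**3 / (b**3 - a**3)
    sr = C * (1 - b**3 / r**3)
    st = C * (1 + b**3 / (2 * r**3))
    return r / E * ((1 - nu) * st - nu * sr), sr, st


@dataclass
class LameBenchmarkResult:
    u_inner_fem: float
    u_inner_exact: float
    hoop_fem: float
    hoop_exact: float
    dof: int

    @property
    def u_rel_err(self) -> float:
        return abs(self.u_inner_fem - self.u_inner_exact) / abs(self.u_inner_exact)

    @property
    def hoop_rel_err(self) -> float:
        return abs(self.hoop_fem - self.hoop_exact) / abs(self.hoop_exact)


def lame_benchmark(a: float = 11.5, b: float = 12.05, E: float = 0.25,
                   nu: float = 0.49, p: float = 2e-3,
                   preset: str = "desk") -> LameBenchmarkResult:
    """Closed thick spherical shell under internal pressure.

    Reports the surface-averaged inner radial displacement and the
    volume-averaged hoop stress against the closed form.  Rigid modes of
    the self-equilibrated problem are regularised by negligible symmetric
    grounding springs (no point constraints, so the spherical symmetry of
    the discrete solution is preserved).
    """
    base, rings, layers = SPHERE_PRESETS[preset]
    shell = sphere_shell_mesh(a, b, base, rings, layers)
    model = FEModel(shell, E, nu)
    model.add_springs(np.arange(shell.n_nodes), 1e-9)
    res = model.solve([PressureLoad(shell.facet_quads("inner_wall"), p)], tol=1e-10)

    u = res.u.reshape(-1, 3)
    rn = np.linalg.norm(shell.nodes, axis=1)
    ur = np.einsum("ij,ij->i", u, shell.nodes / rn[:, None])
    inner = np.abs(rn - a) < 1e-6

    T = voigt_to_tensor(res.gp_stress.mean(axis=1))
    X = shell.nodes[shell.elems].mean(axis=1)
    rc = np.linalg.norm(X, axis=1)
    nh = X / rc[:, None]
    srr = np.einsum("mi,mij,mj->m", nh, T, nh)
    shoop = (np.trace(T, axis1=1, axis2=2) - srr) / 2

    st_exact = np.array([lame_solution(r, a, b, E, nu, p)[2] for r in rc])
    return LameBenchmarkResult(
        u_inner_fem=float(ur[inner].mean()),
        u_inner_exact=float(lame_solution(a, a, b, E, nu, p)[0]),
        hoop_fem=float(shoop.mean()),
        hoop_exact=float(st_exact.mean()),
        dof=model.ndof,
    )


def patch_test(E: float = 1.0, nu: float = 0.3, sigma: float = 0.5):
    """Single-element uniform-traction patch test.

    Returns (max |sigma_zz - sigma| over quadrature points, max of the
    other stress components), both of which must vanish to machine
    precision for a consistent element + load formulation.
    """
    nodes = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                      [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], float)
    mesh = HexMesh(nodes, np.array([[0, 1, 2, 3, 4, 5, 6, 7]]), {},
                   {"top": np.array([[0, 1]])})
    model = FEModel(mesh, E, nu)
    model.fix([0])
    model.fix([1], dofs=(1, 2))
    model.fix([2], dofs=(2,))
    model.fix([3], dofs=(2,))
    res = model.solve([PressureLoad(mesh.facet_quads("top"), -sigma)], tol=1e-13)
    s = res.gp_stress[0]
    return (float(np.abs(s[:, 2] - sigma).max()),
            float(np.abs(s[:, [0, 1, 3, 4, 5]]).max()))
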