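"""Stress-free reference geometry by iterative inverse inflation.

Topography measures the loaded (IOP-inflated) eye, so the finite-element
reference configuration must be an unloaded ("shrunk") geometry that
reproduces the measured shape when inflated.  The classic fixed-point
iteration updates the candidate unloaded nodes by the inflation mismatch

    X0 <- X0 - (x(X0) - X_target)

until the re-inflated geometry matches the target within tolerance
(default 1e-4 mm maximum nodal error).
"""

from __future__ import annotations

import numpy as np

from ..meshing import HexMesh
from .model import FEModel, MMHG_TO_MPA, PressureLoad, SolverError


def find_stress_free_geometry(
    mesh: HexMesh,
    E_mpa: float,
    nu: float,
    iop_mmhg: float,
    tol_mm: float = 1e-4,
    max_iter: int = 30,
    increments: int = 4,
    nlgeom: bool = True,
    accelerate: bool = True,
    fixed_set: str = "rim_fixed",
    pressure_set: str = "inner_wall",
):
    """Return (stress-free mesh, residual history list).

    ``iop = 0`` returns the input mesh unchanged.  Raises
    :class:`SolverError` with the residual history attached when the
    fixed point does not reach tolerance within ``max_iter``.
    """
    if iop_mmhg < 0:
        raise ValueError("IOP must be non-negative")
    if iop_mmhg == 0:
        return mesh.copy(), [0.0]

    target = mesh.nodes.copy()
    X0 = target.copy()
    history = []
    p = iop_mmhg * MMHG_TO_MPA
    omega = 1.0
    X0_prev = err_prev = None
    u_warm = None
    cooldown = 0
    for it in range(max_iter):
        cand = mesh.copy()
        cand.nodes = X0
        try:
            model = FEModel(cand, E_mpa, nu, nlgeom=nlgeom)
            model.fix(cand.node_sets[fixed_set])
            load = PressureLoad(cand.facet_quads(pressure_set), p)
            res = model.solve([load],
                              increments=1 if u_warm is not None else increments,
                              u0=u_warm, tol=3e-6 if nlgeom else 1e-9,
                              max_newton=30)
            u_warm = res.u
        except (ValueError, SolverError):
            # over-relaxed update broke the candidate: plain step instead
            if X0_prev is None:
                raise
            X0 = X0_prev - err_prev
            history.append(history[-1])
            omega, cooldown = 1.0, 3
            u_warm = None
            continue
        x = X0 + res.u.reshape(-1, 3)
        err = x - target
        resid = float(np.max(np.linalg.norm(err, axis=1)))
        history.append(resid)
        if resid < tol_mm:
            out = mesh.copy()
            out.nodes = X0
            return out, history
        if X0_prev is not None and len(history) >= 2 and resid > history[-2]:
            # accelerated step overshot: revert and take the plain update
            X0 = X0_prev - err_prev
            omega, cooldown = 1.0, 3
            continue
        # secant acceleration of the dominant contraction mode: with an
        # observed ratio rho the plain update converges like rho^k, while
        # scaling it by 1/(1 - rho) removes the slow mode
        if accelerate and cooldown == 0 and it >= 1 and history[-2] > 0:
            rho = history[-1] / history[-2]
            omega = min(1.0 / (1.0 - rho), 3.0) if 0.05 < rho < 1.0 else 1.0
        else:
            omega = 1.0
            cooldown = max(cooldown - 1, 0)
        X0_prev, err_prev = X0, err
        X0 = X0 - omega * err
    exc = SolverError(
        f"stress-free iteration did not reach {tol_mm} mm in {max_iter} "
        f"iterations (last residual {history[-1]:.3e} mm)")
    exc.history = history
    raise exc
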