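"""Implicit static finite-element model: assembly, loads, Newton solver.

Consistent units: mm, N, MPa (so pressures in MPa and forces in N).
Displacement-driven Newton iterations on the free degrees of freedom;
contact re-evaluated on deformed coordinates every iteration; divergence
handled by increment bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from ..meshing import HexMesh
from . import elements
from .contact import ContactPair, evaluate_contact

MMHG_TO_MPA = 133.3223684 * 1e-6


class SolverError(RuntimeError):
    pass


@dataclass
class MaterialModel:
    """Linear elastic material."""

    E: float                 # MPa
    nu: float
    density: float = 1000.0  # kg/m^3 (metadata; statics ignores inertia)
    kind: str = "linear_elastic"

    def __post_init__(self) -> None:
        if not 0 < self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")
        if not self.E > 0:
            raise ValueError("Young's modulus must be positive")


def young_modulus_from_age(age_years: float) -> float:
    """Age-related corneal Young's modulus (MPa): E = 0.0032*age + 0.2."""
    if not age_years > 0:
        raise ValueError("age must be positive")
    return 0.0032 * age_years + 0.2


@dataclass
class PressureLoad:
    """Uniform pressure on a facet set (positive pushes against the facet).

    Nodal forces are f = -p * integral(N n dA) on the reference surface,
    so a positive pressure on ``inner_wall`` facets (element-outward
    normals pointing into the cavity) inflates the shell.
    """

    quads: np.ndarray           # (k, 4) node ids
    pressure_mpa: float

    def nodal_forces(self, coords: np.ndarray) -> np.ndarray:
        f = np.zeros_like(coords)
        P = coords[self.quads]                       # (k, 4, 3)
        g = 1.0 / np.sqrt(3.0)
        for xi, eta in ((-g, -g), (g, -g), (g, g), (-g, g)):
            N = 0.25 * np.array([(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
                                 (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)])
            dNx = 0.25 * np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)])
            dNe = 0.25 * np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)])
            tx = np.einsum("a,kai->ki", dNx, P)
            te = np.einsum("a,kai->ki", dNe, P)
            nvec = np.cross(tx, te)                  # |n| = surface Jacobian
            contrib = -self.pressure_mpa * np.einsum("a,ki->kai", N, nvec)
            np.add.at(f, self.quads.ravel(), contrib.reshape(-1, 3))
        return f


@dataclass
class Assembly:
    """Named parts (mesh + material) merged into one model."""

    parts: dict = field(default_factory=dict)        # name -> (HexMesh, MaterialModel)
    _merged: HexMesh | None = None

    def add_part(self, name: str, mesh: HexMesh, material: MaterialModel) -> None:
        self.parts[name] = (mesh, material)
        self._merged = None

    def merged(self) -> tuple[HexMesh, np.ndarray, np.ndarray, dict, dict]:
        """(mesh, E per element, nu per element, node ranges, elem ranges)."""
        mesh = HexMesh.merge({k: m for k, (m, _) in self.parts.items()})
        E = np.concatenate([np.full(m.n_elems, mat.E) for m, mat in self.parts.values()])
        nu = np.concatenate([np.full(m.n_elems, mat.nu) for m, mat in self.parts.values()])
        nrange, erange = {}, {}
        n_off = e_off = 0
        for name, (m, _) in self.parts.items():
            nrange[name] = (n_off, n_off + m.n_nodes)
            erange[name] = (e_off, e_off + m.n_elems)
            n_off += m.n_nodes
            e_off += m.n_elems
        return mesh, E, nu, nrange, erange


@dataclass
class StepResult:
    name: str
    u: np.ndarray
    gp_stress: np.ndarray          # (m, 8gp, 6) MPa
    contact_states: dict           # pair name -> ContactState
    newton_iterations: int
    residual_norm: float


@dataclass
class FEAResult:
    """Displacements, stresses, and contact tractions per converged step."""

    mesh: HexMesh
    steps: list = field(default_factory=list)
    convergence_log: list = field(default_factory=list)

    @property
    def final(self) -> StepResult:
        return self.steps[-1]

    def step(self, name: str) -> StepResult:
        for s in self.steps:
            if s.name == name:
                return s
        raise KeyError(name)


class FEModel:
    """Small-strain (optionally finite-displacement) implicit model."""

    def __init__(self, mesh: HexMesh, E_elem, nu_elem, nlgeom: bool = False):
        self.mesh = mesh
        self.E = np.broadcast_to(np.atleast_1d(np.asarray(E_elem, float)),
                                 (mesh.n_elems,)).copy()
        self.nu = np.broadcast_to(np.atleast_1d(np.asarray(nu_elem, float)),
                                  (mesh.n_elems,)).copy()
        self.nlgeom = nlgeom
        self.ndof = 3 * mesh.n_nodes
        self.fixed = np.zeros(self.ndof, dtype=bool)
        self.spring_k = np.zeros(self.ndof)
        self._build()

    def _build(self) -> None:
        Ke, Bbar, w, D, dNdX = elements.element_stiffness(
            self.mesh.nodes, self.mesh.elems, self.E, self.nu)
        self.Bbar, self.w, self.D, self.dNdX = Bbar, w, D, dNdX
        edof = (3 * self.mesh.elems[:, :, None] + np.arange(3)).reshape(-1, 24)
        rows = np.repeat(edof, 24, axis=1).ravel()
        cols = np.tile(edof, (1, 24)).ravel()
        self.K0 = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                                shape=(self.ndof, self.ndof)).tocsr()

    # -- constraints and springs -----------------------------------------

    def fix(self, node_ids, dofs=(0, 1, 2)) -> None:
        for d in dofs:
            self.fixed[3 * np.asarray(node_ids, int) + d] = True

    def fix_rigid_modes(self) -> None:
        """3-2-1 constraint of rigid motions for self-equilibrated loads."""
        n = self.mesh.nodes
        a = int(np.argmin(n[:, 0] + n[:, 1] + n[:, 2]))
        b = int(np.argmax(n[:, 0]))
        c = int(np.argmax(n[:, 1]))
        self.fix([a])
        self.fix([b], dofs=(1, 2))
        self.fix([c], dofs=(2,))

    def add_springs(self, node_ids, k: float) -> None:
        for d in range(3):
            self.spring_k[3 * np.asarray(node_ids, int) + d] += k

    # -- forces ------------------------------------------------------------

    def internal_force(self, u: np.ndarray) -> np.ndarray:
        if self.nlgeom:
            f, _ = self._nl_internal(u, want_tangent=False)
            return f + self.spring_k * u
        return (self.K0 @ u) + self.spring_k * u

    def _nl_internal(self, u: np.ndarray, want_tangent: bool = True):
        """Total-Lagrangian St.Venant-Kirchhoff force and consistent tangent.

        The volumetric part of the Green strain is replaced by its element
        mean (the finite-strain analogue of the B-bar treatment); the
        tangent combines the material stiffness built on the deformed
        strain-displacement operator B_L(F) with the exact geometric
        (initial-stress) stiffness.
        """
        uv = u.reshape(-1, 3)
        F = elements.deformation_gradients(self.dNdX, self.mesh.elems, uv)
        C = np.einsum("mgki,mgkj->mgij", F, F)
        Egr = 0.5 * (C - np.eye(3))
        tr = np.trace(Egr, axis1=-2, axis2=-1)
        tr_mean = np.einsum("mg,mg->m", tr, self.w) / self.w.sum(axis=1)
        shift = (tr_mean[:, None] - tr) / 3.0
        Ebar = Egr + shift[..., None, None] * np.eye(3)
        ev = np.stack([Ebar[..., 0, 0], Ebar[..., 1, 1], Ebar[..., 2, 2],
                       2 * Ebar[..., 0, 1], 2 * Ebar[..., 1, 2],
                       2 * Ebar[..., 0, 2]], axis=-1)
        Sv = np.einsum("mij,mgj->mgi", self.D, ev)
        S = elements.voigt_to_tensor(Sv)
        self._last_S = Sv

        # strain-displacement operator at the current state:
        # delta E_ij = 1/2 (F_ki dNa/dXj + F_kj dNa/dXi) delta u_ka
        dN = self.dNdX                                    # (m, g, a, j)
        BL = np.zeros(F.shape[:2] + (6, 8, 3))            # (m, g, 6, a, k)
        pairs = ((0, 0, 0), (1, 1, 1), (2, 2, 2),
                 (3, 0, 1), (4, 1, 2), (5, 0, 2))
        for row, i, j in pairs:
            if i == j:
                BL[:, :, row] = np.einsum("mgk,mga->mgak", F[..., :, i],
                                          dN[..., i])
            else:
                BL[:, :, row] = (np.einsum("mgk,mga->mgak", F[..., :, i], dN[..., j])
                                 + np.einsum("mgk,mga->mgak", F[..., :, j], dN[..., i]))
        BLm = BL.reshape(F.shape[0], F.shape[1], 6, 24)
        # B-bar on the deformed operator: the volumetric rows carry the
        # element-mean so the force is the consistent gradient of the
        # mean-dilatation strain energy
        Bvol = (BLm[:, :, 0] + BLm[:, :, 1] + BLm[:, :, 2]) / 3.0   # (m, g, 24)
        vol = self.w.sum(axis=1)
        Bvol_mean = np.einsum("mgk,mg->mk", Bvol, self.w) / vol[:, None]
        BLm = BLm.copy()
        for i in range(3):
            BLm[:, :, i] = BLm[:, :, i] - Bvol + Bvol_mean[:, None, :]
        fe = np.einsum("mgik,mgi,mg->mk", BLm, Sv, self.w)    # (m, 24)
        f = np.zeros_like(uv)
        np.add.at(f, self.mesh.elems.ravel(), fe.reshape(-1, 8, 3).reshape(-1, 3))
        if not want_tangent:
            return f.reshape(-1), None

        DB = np.einsum("mij,mgjk->mgik", self.D, BLm)
        Kmat = np.einsum("mgji,mgjk,mg->mik", BLm, DB, self.w)   # (m, 24, 24)
        # geometric stiffness: Kg_{ai,bj} = delta_ij dN_a.S.dN_b
        G = np.einsum("mgak,mgkl,mgbl,mg->mab", self.dNdX, S, self.dNdX, self.w)
        Kg = np.zeros_like(Kmat)
        for d in range(3):
            Kg[:, d::3, d::3] = G
        Ke = Kmat + Kg
        edof = (3 * self.mesh.elems[:, :, None] + np.arange(3)).reshape(-1, 24)
        rows = np.repeat(edof, 24, axis=1).ravel()
        cols = np.tile(edof, (1, 24)).ravel()
        Ktan = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                             shape=(self.ndof, self.ndof)).tocsr()
        return f.reshape(-1), Ktan

    def gp_stress(self, u: np.ndarray) -> np.ndarray:
        if self.nlgeom:
            self._nl_internal(u, want_tangent=False)
            return self._last_S
        return elements.gp_stresses(self.Bbar, self.D, self.mesh.elems,
                                    u.reshape(-1, 3))

    # -- solver ------------------------------------------------------------

    def solve(
        self,
        loads: list,
        contacts: list | None = None,
        held_loads: list | None = None,
        u0: np.ndarray | None = None,
        load_start: float = 0.0,
        increments: int = 1,
        tol: float = 1e-6,
        max_newton: int = 40,
        min_dlam: float = 1e-3,
        chatter_tol_rel: float = 0.0,
        log: list | None = None,
        step_name: str = "step",
    ) -> StepResult:
        """Ramp ``loads`` from ``load_start`` to 1 (``held_loads`` stay at 1).

        ``u0`` continues from a previous step.  Residual convergence:
        ||R_free|| <= tol * max(||f_ext_free||, 1e-9).
        """
        contacts = contacts or []
        u = np.zeros(self.ndof) if u0 is None else u0.reshape(-1).copy()
        free = ~self.fixed
        f_ramp = np.zeros(self.ndof)
        for ld in loads:
            f_ramp += ld.nodal_forces(self.mesh.nodes).reshape(-1)
        f_held = np.zeros(self.ndof)
        for ld in (held_loads or []):
            f_held += ld.nodal_forces(self.mesh.nodes).reshape(-1)

        for pair in contacts:
            if pair.anchors is None:     # friction anchors persist across steps
                pair.start_step(self.mesh.nodes + u.reshape(-1, 3))

        lam = load_start
        dlam = (1.0 - load_start) / increments
        newton_total = 0
        res_norm = np.nan
        guard = 0
        while lam < 1.0 - 1e-12:
            guard += 1
            if guard > 10000:
                raise SolverError("increment loop failed to progress")
            lam_t = min(1.0, lam + dlam)
            ok, u_new, iters, res_norm = self._newton(
                u, f_held + lam_t * f_ramp, contacts, free, tol, max_newton)
            loose = False
            loose_band = max(20 * tol, chatter_tol_rel)
            if not ok and res_norm <= loose_band * max(
                    np.linalg.norm((f_held + lam_t * f_ramp)[free]), 1e-9):
                # near-converged contact chatter: accept at the loosened
                # tolerance rather than bisecting indefinitely
                ok, loose = True, True
            if log is not None:
                log.append({"step": step_name, "lambda": lam_t, "converged": bool(ok),
                            "loose": loose, "newton": iters, "residual": res_norm})
            if ok:
                u = u_new
                lam = lam_t
                newton_total += iters
                coords_now = self.mesh.nodes + u.reshape(-1, 3)
                for pair in contacts:
                    pair.convect_anchors(coords_now)
                if iters <= 6 and dlam < (1.0 - load_start) / increments:
                    dlam = min(dlam * 2, (1.0 - load_start) / increments)
            else:
                dlam /= 2
                if dlam < min_dlam:
                    raise SolverError(
                        f"Newton divergence at load factor {lam_t:.4f} "
                        f"(residual {res_norm:.3e}); increment floor reached")
        gp_s = self.gp_stress(u)
        states = {}
        coords = self.mesh.nodes + u.reshape(-1, 3)
        for pair in contacts:
            _, _, _, _, st = evaluate_contact(pair, coords)
            states[pair.name] = st
        return StepResult(step_name, u.copy(), gp_s, states, newton_total, res_norm)

    def _residual_and_tangent(self, u, f_ext, contacts, want_tangent=True):
        coords = self.mesh.nodes + u.reshape(-1, 3)
        fc = np.zeros_like(u)
        Kc_data = []
        for pair in contacts:
            f, rows, cols, vals, _ = evaluate_contact(pair, coords)
            fc += f.reshape(-1)
            if want_tangent and len(rows):
                Kc_data.append((np.asarray(rows), np.asarray(cols),
                                np.asarray(vals)))
        if self.nlgeom:
            fint, Ktan = self._nl_internal(u, want_tangent=want_tangent)
            fint = fint + self.spring_k * u
        else:
            fint, Ktan = (self.K0 @ u) + self.spring_k * u, None
        R = fint - fc - f_ext
        if not want_tangent:
            return R, None
        K = (Ktan if Ktan is not None else self.K0) + sp.diags(self.spring_k)
        if Kc_data:
            rows = np.concatenate([r for r, _, _ in Kc_data])
            cols = np.concatenate([c for _, c, _ in Kc_data])
            vals = np.concatenate([v for _, _, v in Kc_data])
            K = K + sp.coo_matrix((vals, (rows, cols)),
                                  shape=(self.ndof, self.ndof)).tocsr()
        return R, K

    def _newton(self, u, f_ext, contacts, free, tol, max_newton):
        u = u.copy()
        ref = max(np.linalg.norm(f_ext[free]), 1e-9)
        res_norm = np.inf
        bad_steps = 0
        for it in range(max_newton):
            R, K = self._residual_and_tangent(u, f_ext, contacts)
            res_norm = float(np.linalg.norm(R[free]))
            if res_norm <= max(tol * ref, 1e-10):
                return True, u, it, res_norm
            if not np.isfinite(res_norm) or res_norm > 1e8 * ref:
                return False, u, it, res_norm
            Kff = K[free][:, free].tocsc()
            try:
                du = splu(Kff).solve(-R[free])
            except RuntimeError as exc:
                raise SolverError(f"linear solve failed: {exc}") from exc
            # fast path: linear problem without contact converges in one update
            if not contacts and not self.nlgeom:
                u[free] += du
                R, _ = self._residual_and_tangent(u, f_ext, contacts,
                                                  want_tangent=False)
                res_norm = float(np.linalg.norm(R[free]))
                return res_norm <= max(tol, 1e-8) * ref * 10, u, it + 1, res_norm
            # line search on the residual norm damps contact chatter; one
            # non-improving step is allowed (an active-set flip may need
            # it), two in a row means a stall
            best = None
            for alpha in (1.0, 0.5, 0.25, 0.1):
                u_try = u.copy()
                u_try[free] += alpha * du
                R_try, _ = self._residual_and_tangent(u_try, f_ext, contacts,
                                                      want_tangent=False)
                r_try = float(np.linalg.norm(R_try[free]))
                if r_try < res_norm:
                    best = (u_try, r_try)
                    break
                if best is None or r_try < best[1]:
                    best = (u_try, r_try)
            if best[1] >= res_norm:
                bad_steps += 1
                if bad_steps >= 4 or best[1] > 10 * res_norm:
                    return False, u, it + 1, res_norm
            else:
                bad_steps = 0
            u = best[0]
        R, _ = self._residual_and_tangent(u, f_ext, contacts, want_tangent=False)
        res_norm = float(np.linalg.norm(R[free]))
        return res_norm <= max(tol * ref, 1e-10), u, max_newton, res_norm

    # -- reactions ---------------------------------------------------------

    def reactions(self, result: StepResult, loads: list, contacts: list | None = None):
        """Reaction forces at fixed dofs: f_int - f_ext - f_contact."""
        u = result.u
        f_ext = np.zeros(self.ndof)
        for ld in loads:
            f_ext += ld.nodal_forces(self.mesh.nodes).reshape(-1)
        fc = np.zeros(self.ndof)
        coords = self.mesh.nodes + u.reshape(-1, 3)
        for pair in (contacts or []):
            f, *_ = evaluate_contact(pair, coords)
            fc += f.reshape(-1)
        R = self.internal_force(u) - f_ext - fc
        out = np.zeros(self.ndof)
        out[self.fixed] = R[self.fixed]
        return out.reshape(-1, 3)
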