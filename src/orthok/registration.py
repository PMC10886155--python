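"""Rigid lens seating on the cornea by constrained iterative closest point.

The lens is first offset laterally by the clinically detected
decentration, dropped until it touches the anterior surface, and then
fine-tuned by ICP: each iteration pairs every lens back-surface node with
its closest point on the anterior-eye surface, computes the best rigid
fit (Kabsch), clamps the step to small translation/rotation bounds, and
projects the pose outward if the back surface penetrates the eye.  The
objective (RMS closest-point distance) is kept non-increasing by
backtracking, and iterations are hard-capped (default 50).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .meshing import HexMesh
from .topography import RadialSurface

__all__ = ["RigidTransform", "compose_transform", "apply_transform", "seat_lens",
           "SeatingReport"]


@dataclass
class RigidTransform:
    """Rotation (angles about X, Y, Z) + translation; R assembled as

        [ ca*cb   ca*sb*sg - sa*cg   ca*sb*cg + sa*sg ]
        [ sa*cb   sa*sb*sg + ca*cg   sa*sb*cg - ca*sg ]
        [ -sb     cb*sg              cb*cg            ]

    with a = alpha, b = beta, g = gamma.
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @property
    def rotation(self) -> np.ndarray:
        ca, sa = np.cos(self.alpha), np.sin(self.alpha)
        cb, sb = np.cos(self.beta), np.sin(self.beta)
        cg, sg = np.cos(self.gamma), np.sin(self.gamma)
        return np.array([
            [ca * cb, ca * sb * sg - sa * cg, ca * sb * cg + sa * sg],
            [sa * cb, sa * sb * sg + ca * cg, sa * sb * cg - ca * sg],
            [-sb, cb * sg, cb * cg],
        ])

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> R_self (R_other x + T_other) + T_self."""
        R = self.rotation @ other.rotation
        T = self.rotation @ other.translation + self.translation
        return RigidTransform.from_matrix(R, T)

    def inverse(self) -> "RigidTransform":
        R = self.rotation.T
        return RigidTransform.from_matrix(R, -R @ self.translation)

    @staticmethod
    def from_matrix(R: np.ndarray, T: np.ndarray) -> "RigidTransform":
        beta = -np.arcsin(np.clip(R[2, 0], -1.0, 1.0))
        cb = np.cos(beta)
        if abs(cb) > 1e-12:
            alpha = np.arctan2(R[1, 0], R[0, 0])
            gamma = np.arctan2(R[2, 1], R[2, 2])
        else:   # gimbal: fold gamma into alpha
            alpha = np.arctan2(-R[0, 1], R[1, 1])
            gamma = 0.0
        return RigidTransform(alpha, beta, gamma, np.asarray(T, float))

    def magnitude(self) -> tuple[float, float]:
        """(translation norm mm, rotation angle rad)."""
        ang = np.arccos(np.clip((np.trace(self.rotation) - 1) / 2, -1.0, 1.0))
        return float(np.linalg.norm(self.translation)), float(ang)


def compose_transform(alpha: float, beta: float, gamma: float,
                      xt: float, yt: float, zt: float) -> RigidTransform:
    return RigidTransform(alpha, beta, gamma, np.array([xt, yt, zt]))


def apply_transform(points: np.ndarray, t: RigidTransform) -> np.ndarray:
    return t.apply(points)


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best rigid (R, T) mapping src -> dst in least squares."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cd - R @ cs


def _clamp_step(R: np.ndarray, T: np.ndarray, max_trans: float, max_rot: float):
    """Scale a rigid step down to the per-iteration bounds."""
    ang = np.arccos(np.clip((np.trace(R) - 1) / 2, -1.0, 1.0))
    s = min(1.0,
            max_trans / max(np.linalg.norm(T), 1e-15),
            max_rot / max(ang, 1e-15))
    if s >= 1.0:
        return R, T
    # interpolate the rotation through its axis-angle form
    if ang > 1e-12:
        w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        w = w / np.linalg.norm(w)
        th = ang * s
        K = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
        Rs = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    else:
        Rs = np.eye(3)
    return Rs, T * s


@dataclass
class SeatingReport:
    objective_mm: list
    iterations: int = 0
    converged: bool = False
    warning: str = ""
    final_min_gap_mm: float = float("nan")

    def to_dict(self) -> dict:
        return {"objective_mm": [float(v) for v in self.objective_mm],
                "iterations": self.iterations, "converged": self.converged,
                "warning": self.warning,
                "final_min_gap_mm": self.final_min_gap_mm}


def seat_lens(
    lens: HexMesh,
    decentration: tuple,
    cornea: RadialSurface,
    max_iter: int = 50,
    max_step_trans_mm: float = 0.05,
    max_step_rot_rad: float = np.deg2rad(0.25),
    max_total_trans_mm: float = 1.0,
    max_total_lateral_mm: float = 0.1,
    max_total_rot_rad: float = np.deg2rad(5.0),
    tol_mm: float = 1e-6,
    standoff_mm: float = 0.0,
    point_to_plane: bool = False,
    cloud: np.ndarray | None = None,
) -> tuple[HexMesh, RigidTransform, SeatingReport]:
    """Seat a lens mesh on the anterior eye at a given decentration.

    Returns the repositioned mesh, the accumulated rigid transform (from
    the input pose), and a report whose per-iteration objective is
    non-increasing.  Penetration of the anterior surface is projected out
    after every step (final minimum signed clearance >= -1e-6 mm).
    """
    back_ids = lens.node_sets.get("back_nodes")
    if back_ids is None:
        back_ids = lens.facet_set_nodes("lens_back")

    nodes = lens.nodes.copy()
    # initial pose: lateral decentration, dropped to touch the surface
    nodes[:, 0] += decentration[0]
    nodes[:, 1] += decentration[1]
    shift0 = 0.0
    for _ in range(8):
        gap = cornea.signed_gap(nodes[back_ids])
        step_z = standoff_mm - gap.min()
        if abs(step_z) < 1e-12:
            break
        nodes[:, 2] += step_z
        shift0 += step_z
    init = RigidTransform(0, 0, 0, np.array([decentration[0], decentration[1], shift0]))
    icp = RigidTransform()          # fine-tuning beyond the initial placement
    total = icp.compose(init)

    def objective(nds):
        feet = cornea.closest_points(nds[back_ids])
        return float(np.sqrt(np.mean(np.sum((nds[back_ids] - feet) ** 2, axis=1))))

    def gauss_newton_step(src, feet, normals):
        """Pose step minimising the point-to-plane distances.

        The point-to-point fit cannot slide a smooth cap tangentially
        (closest-point vectors are normal to the surface), so a damped
        Gauss-Newton step on the signed normal distances supplies the
        sliding/rolling correction.
        """
        c = src.mean(axis=0)
        d = np.einsum("ij,ij->i", src - feet, normals)
        J = np.hstack([normals, np.cross(src - c, normals)])
        A = J.T @ J + 1e-9 * np.eye(6)
        x = np.linalg.solve(A, -J.T @ d)
        w = x[3:]
        ang = np.linalg.norm(w)
        if ang > 1e-15:
            k = w / ang
            K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
            R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        else:
            R = np.eye(3)
        # rotation about the centroid: T = t + c - R c
        T = x[:3] + c - R @ c
        return R, T

    obj = [objective(nodes)]
    report = SeatingReport(objective_mm=obj)
    for it in range(max_iter):
        src = nodes[back_ids]
        dst, nrm = cornea.closest_points(src, return_normals=True)
        R0, T0 = _kabsch(src, dst)
        # suppress spin about the lens axis: it is a neutral direction for
        # a rotationally symmetric lens and would otherwise drift freely
        ang0 = RigidTransform.from_matrix(R0, T0)
        R0 = RigidTransform(0.0, ang0.beta, ang0.gamma, T0).rotation
        Rg, Tg = gauss_newton_step(src, dst, nrm)
        angg = RigidTransform.from_matrix(Rg, Tg)
        Rg = RigidTransform(0.0, angg.beta, angg.gamma, Tg).rotation

        accepted = False
        candidates = [(Rg, Tg), (R0, T0), (R0, np.zeros(3)), (np.eye(3), T0)]
        if point_to_plane:
            candidates = [(Rg, Tg), (np.eye(3), Tg)]
        for Rc, Tc in candidates:
            lim_t, lim_r = max_step_trans_mm, max_step_rot_rad
            for _ in range(10):
                R, T = _clamp_step(Rc, Tc, lim_t, lim_r)
                cand = nodes @ R.T + T
                # re-settle along the axis: non-penetration with the
                # standoff clearance restored (two-sided, so the normal
                # offset is not a direction the closest-point fit fights;
                # iterated because a vertical shift changes the radial
                # clearance only by its cos(elevation) component)
                dzp = 0.0
                for _ in range(8):
                    g = cornea.signed_gap(cand[back_ids])
                    step_z = standoff_mm - g.min()
                    if abs(step_z) < 1e-12:
                        break
                    cand[:, 2] += step_z
                    dzp += step_z
                step = RigidTransform.from_matrix(R, T + np.array([0.0, 0.0, dzp]))
                cand_icp = step.compose(icp)
                tt, rr = cand_icp.magnitude()
                # the clinically detected decentration must survive the
                # fine-tuning: lateral drift gets its own, tighter budget
                tt_lat = float(np.hypot(*cand_icp.translation[:2]))
                if (tt > max_total_trans_mm or rr > max_total_rot_rad
                        or tt_lat > max_total_lateral_mm):
                    break
                val = objective(cand)
                if val < obj[-1] - 1e-16:
                    nodes, icp, accepted = cand, cand_icp, True
                    total = icp.compose(init)
                    obj.append(val)
                    break
                lim_t, lim_r = lim_t / 2, lim_r / 2
            if accepted:
                break
        report.iterations = it + 1
        if not accepted:
            report.converged = True
            break
        if len(obj) >= 2 and obj[-2] - obj[-1] < tol_mm:
            report.converged = True
            break
    else:
        report.warning = f"ICP did not converge in {max_iter} iterations; best iterate kept"

    for _ in range(5):
        g = cornea.signed_gap(nodes[back_ids])
        if abs(g.min() - standoff_mm) < 1e-9:
            break
        nodes[:, 2] += standoff_mm - g.min()
    g = cornea.signed_gap(nodes[back_ids])
    report.final_min_gap_mm = float(g.min())
    out = lens.copy()
    out.nodes = nodes
    return out, total, report
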