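"""Eyelid boundary detection from topography coverage and the lid solid.

Eyelashes truncate videokeratoscope coverage, so the lid margins leave a
footprint on the coverage mask.  Detection follows the footprint: extract
the boundary points of the valid region, compute their geometric centre,
histogram the boundary radii with a 0.3 mm bin, keep the most frequent
radii as lid-edge landmarks, split them into upper/lower sets about the
centre, and least-squares fit a second-order curve y = a x^2 + b x + c
per lid (upper concave down, a < 0; lower concave up, a > 0).

The eyelid solid treats the closed upper and lower lids as one continuous
surface draped over the anterior eye (and anything resting on it): a
uniform 51 x 41 mid-surface grid offset outward from the covering
envelope by a small clearance, extruded 0.5 mm along the surface normal
in two layers of hexahedra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator

from .meshing import HexMesh, MeshError, _extrude_quads_to_hexes
from .topography import RadialSurface

__all__ = ["EyelidBoundary", "detect_eyelid_boundary", "build_eyelid_mesh",
           "EYELID_YOUNG_MPA", "EYELID_POISSON", "EYELID_DENSITY"]

# lid material: elastic, near-incompressible, density of water
EYELID_YOUNG_MPA = 1.73
EYELID_POISSON = 0.49
EYELID_DENSITY = 1000.0

HISTOGRAM_BIN_MM = 0.3


@dataclass
class EyelidBoundary:
    """Second-order lid edges y = a x^2 + b x + c (mm)."""

    upper: tuple       # (a, b, c), a < 0
    lower: tuple       # (a, b, c), a > 0
    landmarks_upper: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    landmarks_lower: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        if not (self.upper[0] < 0 < self.lower[0]):
            raise ValueError("upper lid needs a < 0 and lower lid a > 0 "
                             "(concavity toward the aperture)")
        if not (self.upper[2] > 0 > self.lower[2]):
            raise ValueError("upper lid vertex must sit above the axis, lower below")

    def upper_y(self, x: np.ndarray) -> np.ndarray:
        a, b, c = self.upper
        return a * x**2 + b * x + c

    def lower_y(self, x: np.ndarray) -> np.ndarray:
        a, b, c = self.lower
        return a * x**2 + b * x + c


def detect_eyelid_boundary(
    coverage: np.ndarray,
    azimuths_deg: np.ndarray,
    radii_mm: np.ndarray,
    bin_mm: float = HISTOGRAM_BIN_MM,
    rim_tolerance_mm: float = 0.05,
    landmark_fraction: float = 0.2,
) -> EyelidBoundary | None:
    """Fit lid parabolas from a polar coverage mask.

    Returns ``None`` ("no lid detected") when coverage reaches the device
    rim everywhere (no lid truncation).  Raises when a lid is present but
    has fewer than 3 landmark points.
    """
    cov = np.asarray(coverage, bool)
    r = np.asarray(radii_mm, float)
    th = np.deg2rad(np.asarray(azimuths_deg, float))
    device_radius = r[-1]

    # outermost covered station per azimuth = boundary point
    pts = []
    for i in range(cov.shape[0]):
        idx = np.flatnonzero(cov[i])
        if idx.size == 0:
            continue
        rb = r[idx[-1]]
        pts.append((rb * np.cos(th[i]), rb * np.sin(th[i]), rb))
    if not pts:
        return None
    pts = np.array(pts)
    # geometric centre of the footprint boundary
    centre = pts[:, :2].mean(axis=0)

    # points on the device rim carry no lid information
    lid_pts = pts[pts[:, 2] < device_radius - rim_tolerance_mm]
    if lid_pts.shape[0] < 6:
        return None

    radii_c = np.hypot(lid_pts[:, 0] - centre[0], lid_pts[:, 1] - centre[1])
    bins = np.floor(radii_c / bin_mm).astype(int)
    uniq, counts = np.unique(bins, return_counts=True)
    keep_bins = uniq[counts >= max(3, landmark_fraction * counts.max())]
    landmark = lid_pts[np.isin(bins, keep_bins)]

    upper = landmark[landmark[:, 1] > centre[1]]
    lower = landmark[landmark[:, 1] <= centre[1]]
    if upper.shape[0] < 3 and lower.shape[0] < 3:
        return None
    if upper.shape[0] < 3 or lower.shape[0] < 3:
        raise ValueError("lid truncation detected on one side only: "
                         f"{upper.shape[0]} upper / {lower.shape[0]} lower landmarks")
    cu = np.polyfit(upper[:, 0], upper[:, 1], 2)
    cl = np.polyfit(lower[:, 0], lower[:, 1], 2)
    return EyelidBoundary(tuple(cu), tuple(cl),
                          landmarks_upper=upper[:, :2], landmarks_lower=lower[:, :2])


def landmark_bins(radii_mm: np.ndarray, bin_mm: float = HISTOGRAM_BIN_MM):
    """Histogram helper: 0.3 mm bins anchored at zero -> (bin lows, counts)."""
    bins = np.floor(np.asarray(radii_mm, float) / bin_mm).astype(int)
    uniq, counts = np.unique(bins, return_counts=True)
    return uniq * bin_mm, counts


def build_eyelid_mesh(
    boundary: EyelidBoundary,
    anterior: RadialSurface,
    thickness_mm: float = 0.5,
    nx: int = 51,
    ny: int = 41,
    layers: int = 2,
    clearance_mm: float = 0.05,
    overlay_points: np.ndarray | None = None,
    disc_radius_mm: float | None = None,
) -> HexMesh:
    """Two-layer lid solid draped over the anterior eye.

    The mid-surface grid spans the lid-covered disc uniformly ``nx x ny``
    (odd counts put nodes on both axes); each node sits on the upper
    envelope of the anterior eye and ``overlay_points`` (e.g. the seated
    lens front), offset outward along the local radial direction by
    ``clearance_mm``, then extruded ``thickness_mm`` outward in ``layers``
    element layers.

    Sets: facets ``eyelid_back`` (toward eye/lens) and ``eyelid_outer``;
    nodes ``eyelid_perimeter`` for boundary conditions.
    """
    if disc_radius_mm is None:
        lat_max = anterior.radius(0.0, anterior.el_max) * np.sin(anterior.el_max)
        disc_radius_mm = 0.95 * float(lat_max)
    Rd = disc_radius_mm
    y_top = min(0.92 * Rd, boundary.upper[2] + 3.0)
    y_bot = max(-0.92 * Rd, boundary.lower[2] - 3.0)
    ys = np.linspace(y_bot, y_top, ny)
    half_chord = 0.98 * np.sqrt(np.maximum(Rd**2 - ys**2, 0.05 * Rd**2))
    X = np.linspace(-1.0, 1.0, nx)[None, :] * half_chord[:, None]
    Y = np.broadcast_to(ys[:, None], X.shape)

    pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    az, el = _direction_of_lateral(anterior, pts[:, 0], pts[:, 1])
    surf_pts = anterior.point(az, el)
    z_surf = surf_pts[:, 2]
    if overlay_points is not None and len(overlay_points):
        interp = LinearNDInterpolator(overlay_points[:, :2], overlay_points[:, 2])
        z_over = interp(pts[:, 0], pts[:, 1])
        z_env = np.where(np.isfinite(z_over), np.maximum(z_surf, z_over), z_surf)
        # drape smoothly over the lens edge: a Gaussian-smoothed skirt,
        # re-maxed so the lid never dips below the envelope
        from scipy.ndimage import gaussian_filter
        z_sm = gaussian_filter(z_env.reshape(ys.size, -1), sigma=2.0,
                               mode="nearest").ravel()
        z_surf = np.maximum(z_env, z_sm)

    base = np.column_stack([pts[:, 0], pts[:, 1], z_surf])
    n_hat = base - anterior.centre
    n_hat /= np.linalg.norm(n_hat, axis=1, keepdims=True)

    npl = base.shape[0]
    node_layers = [base + n_hat * (clearance_mm + thickness_mm * k / layers)
                   for k in range(layers + 1)]
    nodes = np.vstack(node_layers)

    idx = np.arange(npl).reshape(ny, nx)
    quads = np.column_stack([
        idx[:-1, :-1].ravel(), idx[:-1, 1:].ravel(),
        idx[1:, 1:].ravel(), idx[1:, :-1].ravel(),
    ])
    elems = _extrude_quads_to_hexes(quads, npl, layers)

    nq = quads.shape[0]
    fsets = {
        "eyelid_back": np.column_stack([np.arange(nq), np.zeros(nq, dtype=int)]),
        "eyelid_outer": np.column_stack([np.arange(nq) + (layers - 1) * nq,
                                         np.ones(nq, dtype=int)]),
    }
    per2d = np.concatenate([idx[0], idx[-1], idx[1:-1, 0], idx[1:-1, -1]])
    perimeter = np.concatenate([per2d + k * npl for k in range(layers + 1)])
    mesh = HexMesh(nodes, elems,
                   {"eyelid_perimeter": perimeter,
                    "back_nodes": np.arange(npl),
                    "outer_nodes": np.arange(npl) + layers * npl},
                   fsets)
    det = mesh.jacobians()
    if np.any(det <= 0):
        bad = np.unique(np.nonzero(det <= 0)[0])
        raise MeshError(f"eyelid mesh inverted elements {bad.tolist()[:10]}")
    return mesh


def _direction_of_lateral(surface: RadialSurface, x: np.ndarray, y: np.ndarray):
    """(azimuth, elevation) of the surface point above lateral position (x, y).

    Solved by bisection on elevation per ray (lateral radius is monotone in
    elevation for star-shaped surfaces).
    """
    az = np.rad2deg(np.arctan2(y, x)) % 360.0
    target = np.hypot(x, y)
    lo = np.full_like(target, 1e-6)
    hi = np.full_like(target, surface.el_max)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        lat = surface.radius(az, mid) * np.sin(mid)
        too_far = lat > target
        hi = np.where(too_far, mid, hi)
        lo = np.where(too_far, lo, mid)
    return az, 0.5 * (lo + hi)
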