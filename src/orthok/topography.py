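"""Corneal topography records, text container I/O, and surface extension.

The unit of clinical input is a polar anterior-surface elevation grid
(azimuth x radial station, default 300 x 333) with a coverage mask, as
produced by a videokeratoscope.  Proprietary binary formats are out of
scope; records live in a small documented text container (header, radii,
azimuths, elevation block, coverage block).

Elevation convention: right-handed frame, origin on the instrument axis at
the anterior apex, +Z anterior (toward the device).  Elevation is the
surface height z(theta, r) in mm, so a convex cornea has z <= 0 away from
the apex (z = -sag).  X is temporal-positive for right eyes; left-eye
records can be mirrored into the right-eye frame with
:func:`to_right_eye_frame` so downstream analysis is laterality-agnostic.

Measured coverage typically stops short of the limbus.
:func:`extend_surface` reconstructs the missing annulus with a low-order
(<= 3) Zernike fit out to 5.5 mm, keeps the measured samples verbatim, and
continues the surface past the limbus with tangent-matched circular arcs
(default 12 mm radius) out to the model rim so finite-element boundary
conditions sit far from the lens interaction zone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, RectBivariateSpline

__all__ = [
    "TopographyRecord",
    "TopographyFormatError",
    "ExtendedSurface",
    "RadialSurface",
    "default_polar_grid",
    "read_topography",
    "write_topography",
    "to_right_eye_frame",
    "polar_to_cartesian",
    "cartesian_to_polar",
    "zernike_fit",
    "zernike_eval",
    "extend_surface",
]

N_AZIMUTH = 300
N_RADIAL = 333
MAX_MEASURED_RADIUS_MM = 4.98

# provenance codes for extended-surface points
PROV_MEASURED = 0
PROV_ZERNIKE = 1
PROV_SCLERAL = 2


class TopographyFormatError(ValueError):
    """Raised for malformed topography container files."""


def default_polar_grid(
    n_az: int = N_AZIMUTH, n_r: int = N_RADIAL, r_max: float = MAX_MEASURED_RADIUS_MM
) -> tuple[np.ndarray, np.ndarray]:
    """Default measurement grid: uniform azimuths [0, 360) and uniform radii."""
    az = np.arange(n_az) * (360.0 / n_az)
    r = np.linspace(0.0, r_max, n_r)
    return az, r


@dataclass
class TopographyRecord:
    """A single topography exam: polar elevation grid + exam metadata."""

    elevation: np.ndarray          # (n_az, n_r) mm, NaN where not covered
    radii_mm: np.ndarray           # (n_r,) strictly increasing
    azimuths_deg: np.ndarray       # (n_az,)
    coverage: np.ndarray           # (n_az, n_r) bool
    eye: str = "right"             # {"right", "left"}
    exam_date: str = "1970-01-01"
    simk_flat_d: float = float("nan")
    simk_steep_d: float = float("nan")
    flat_angle_deg: float = float("nan")
    steep_angle_deg: float = float("nan")

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        self.radii_mm = np.asarray(self.radii_mm, dtype=float)
        self.azimuths_deg = np.asarray(self.azimuths_deg, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=bool)
        n_az, n_r = self.azimuths_deg.size, self.radii_mm.size
        if self.elevation.shape != (n_az, n_r):
            raise TopographyFormatError(
                f"elevation block is {self.elevation.shape}, header declares ({n_az}, {n_r})"
            )
        if self.coverage.shape != (n_az, n_r):
            raise TopographyFormatError("coverage block does not match declared grid")
        if np.any(np.diff(self.radii_mm) <= 0):
            raise TopographyFormatError("radial positions must be strictly increasing")
        if not np.all(np.isfinite(self.elevation[self.coverage])):
            raise TopographyFormatError("non-finite elevation inside coverage mask")

    @property
    def n_az(self) -> int:
        return self.azimuths_deg.size

    @property
    def n_r(self) -> int:
        return self.radii_mm.size

    def copy(self) -> "TopographyRecord":
        return TopographyRecord(
            self.elevation.copy(), self.radii_mm.copy(), self.azimuths_deg.copy(),
            self.coverage.copy(), self.eye, self.exam_date, self.simk_flat_d,
            self.simk_steep_d, self.flat_angle_deg, self.steep_angle_deg,
        )

    def points(self, valid_only: bool = True) -> np.ndarray:
        """(N, 3) Cartesian point cloud of the (covered) surface samples."""
        x, y = polar_to_cartesian(self.azimuths_deg, self.radii_mm)
        z = self.elevation
        if valid_only:
            m = self.coverage
            return np.column_stack([x[m], y[m], z[m]])
        return np.column_stack([x.ravel(), y.ravel(), z.ravel()])


def polar_to_cartesian(az_deg: np.ndarray, r_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Broadcast polar grid axes to (n_az, n_r) Cartesian coordinates."""
    th = np.deg2rad(np.asarray(az_deg, float))[:, None]
    r = np.asarray(r_mm, float)[None, :]
    return r * np.cos(th), r * np.sin(th)


def cartesian_to_polar(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    az = np.rad2deg(np.arctan2(y, x)) % 360.0
    return az, np.hypot(x, y)


# ----------------------------------------------------------------------------
# Text container I/O
# ----------------------------------------------------------------------------

_SECTIONS = ("RADII", "AZIMUTHS", "ELEVATION", "COVERAGE", "END")


def write_topography(record: TopographyRecord, path) -> None:
    """Write a record in the text topography container (lossless)."""
    with open(path, "w") as fh:
        fh.write("ORTHOK-TOPO 1\n")
        fh.write(f"eye {record.eye}\n")
        fh.write(f"exam_date {record.exam_date}\n")
        fh.write(f"simk_flat_d {record.simk_flat_d:.17g}\n")
        fh.write(f"simk_steep_d {record.simk_steep_d:.17g}\n")
        fh.write(f"flat_angle_deg {record.flat_angle_deg:.17g}\n")
        fh.write(f"steep_angle_deg {record.steep_angle_deg:.17g}\n")
        fh.write(f"n_az {record.n_az}\n")
        fh.write(f"n_r {record.n_r}\n")
        fh.write("RADII\n")
        fh.write(" ".join(f"{v:.17g}" for v in record.radii_mm) + "\n")
        fh.write("AZIMUTHS\n")
        fh.write(" ".join(f"{v:.17g}" for v in record.azimuths_deg) + "\n")
        fh.write("ELEVATION\n")
        for row in record.elevation:
            fh.write(" ".join("nan" if not np.isfinite(v) else f"{v:.17g}" for v in row) + "\n")
        fh.write("COVERAGE\n")
        for row in record.coverage:
            fh.write("".join("1" if v else "0" for v in row) + "\n")
        fh.write("END\n")


def read_topography(path) -> TopographyRecord:
    """Read a record from the text topography container.

    Dimension mismatches, non-monotone radii, unparseable numbers and
    truncated files each raise :class:`TopographyFormatError` with a
    diagnostic naming the offending section.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0].startswith("ORTHOK-TOPO"):
        raise TopographyFormatError("missing ORTHOK-TOPO signature line")
    meta: dict[str, str] = {}
    i = 1
    while i < len(lines) and lines[i].strip() not in _SECTIONS:
        parts = lines[i].split(None, 1)
        if len(parts) == 2:
            meta[parts[0]] = parts[1]
        i += 1
    try:
        n_az = int(meta["n_az"])
        n_r = int(meta["n_r"])
    except KeyError as exc:
        raise TopographyFormatError(f"header missing grid dimension {exc}") from None

    def _expect(section: str) -> int:
        nonlocal i
        if i >= len(lines) or lines[i].strip() != section:
            raise TopographyFormatError(f"truncated file: missing {section} section")
        i += 1
        return i

    def _floats(line: str, section: str) -> np.ndarray:
        try:
            return np.array([float(tok) for tok in line.split()])
        except ValueError:
            raise TopographyFormatError(f"unparseable number in {section} section") from None

    _expect("RADII")
    radii = _floats(lines[i], "RADII"); i += 1
    _expect("AZIMUTHS")
    az = _floats(lines[i], "AZIMUTHS"); i += 1
    if radii.size != n_r:
        raise TopographyFormatError(
            f"RADII section has {radii.size} values, header declares n_r {n_r}")
    if az.size != n_az:
        raise TopographyFormatError(
            f"AZIMUTHS section has {az.size} values, header declares n_az {n_az}")
    _expect("ELEVATION")
    if i + n_az > len(lines):
        raise TopographyFormatError("truncated file: missing ELEVATION rows")
    elev = np.empty((n_az, n_r))
    for k in range(n_az):
        row = _floats(lines[i + k], "ELEVATION")
        if row.size != n_r:
            raise TopographyFormatError(
                f"ELEVATION row {k} has {row.size} values, expected {n_r}")
        elev[k] = row
    i += n_az
    _expect("COVERAGE")
    if i + n_az > len(lines):
        raise TopographyFormatError("truncated file: missing COVERAGE rows")
    cov = np.empty((n_az, n_r), dtype=bool)
    for k in range(n_az):
        row = lines[i + k].strip()
        if len(row) != n_r or set(row) - {"0", "1"}:
            raise TopographyFormatError(f"COVERAGE row {k} is not {n_r} binary digits")
        cov[k] = np.frombuffer(row.encode(), dtype=np.uint8) == ord("1")
    i += n_az
    _expect("END")

    def _f(key: str) -> float:
        return float(meta.get(key, "nan"))

    return TopographyRecord(
        elev, radii, az, cov,
        eye=meta.get("eye", "right"), exam_date=meta.get("exam_date", "1970-01-01"),
        simk_flat_d=_f("simk_flat_d"), simk_steep_d=_f("simk_steep_d"),
        flat_angle_deg=_f("flat_angle_deg"), steep_angle_deg=_f("steep_angle_deg"),
    )


def to_right_eye_frame(record: TopographyRecord) -> TopographyRecord:
    """Mirror a left-eye record about the vertical axis (x -> -x).

    Right-eye records are returned unchanged (a copy).  Requires the
    uniform default azimuth grid so mirrored azimuths land exactly on grid
    nodes.  Laterality metadata is retained.
    """
    out = record.copy()
    if record.eye != "left":
        return out
    az = record.azimuths_deg
    target = (180.0 - az) % 360.0
    idx = np.argmin(np.abs((az[None, :] - target[:, None] + 180) % 360 - 180), axis=1)
    if not np.allclose(az[idx], target, atol=1e-9):
        raise ValueError("azimuth grid is not mirror-symmetric; cannot mirror record")
    out.elevation = record.elevation[idx]
    out.coverage = record.coverage[idx]
    out.flat_angle_deg = (180.0 - record.flat_angle_deg) % 360.0
    out.steep_angle_deg = (180.0 - record.steep_angle_deg) % 360.0
    return out


# ----------------------------------------------------------------------------
# Zernike fitting (Noll indexing, order <= 3)
# ----------------------------------------------------------------------------

# Noll j -> (n, m) for the first 10 modes (orders 0..3)
_NOLL_NM = {
    1: (0, 0), 2: (1, 1), 3: (1, -1), 4: (2, 0), 5: (2, -2),
    6: (2, 2), 7: (3, -1), 8: (3, 1), 9: (3, -3), 10: (3, 3),
}


def _zernike_radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    m = abs(m)
    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        c = ((-1) ** k * math.factorial(n - k)
             / (math.factorial(k)
                * math.factorial((n + m) // 2 - k)
                * math.factorial((n - m) // 2 - k)))
        out = out + c * rho ** (n - 2 * k)
    return out


def zernike_basis(rho: np.ndarray, theta: np.ndarray, max_order: int = 3) -> np.ndarray:
    """Orthonormal (Noll) Zernike design matrix, columns j = 1..J."""
    cols = []
    for j, (n, m) in _NOLL_NM.items():
        if n > max_order:
            continue
        R = _zernike_radial(n, m, rho)
        norm = np.sqrt(n + 1.0) if m == 0 else np.sqrt(2.0 * (n + 1.0))
        if m == 0:
            cols.append(norm * R)
        elif m > 0:
            cols.append(norm * R * np.cos(m * theta))
        else:
            cols.append(norm * R * np.sin(-m * theta))
    return np.column_stack(cols)


def zernike_fit(points: np.ndarray, disc_radius: float, max_order: int = 3,
                min_points_per_mode: int = 10) -> np.ndarray:
    """Least-squares Zernike coefficients for z(x, y) over a disc.

    points : (N, 3) with columns x, y, z (mm).  Raises if the system is
    rank-deficient or has fewer than ``min_points_per_mode`` points per mode.
    """
    pts = np.asarray(points, float)
    rho = np.hypot(pts[:, 0], pts[:, 1]) / disc_radius
    theta = np.arctan2(pts[:, 1], pts[:, 0])
    A = zernike_basis(rho, theta, max_order)
    if pts.shape[0] < min_points_per_mode * A.shape[1]:
        raise ValueError(
            f"only {pts.shape[0]} valid points for {A.shape[1]} Zernike modes "
            f"(need >= {min_points_per_mode} per mode)")
    coef, _, rank, _ = np.linalg.lstsq(A, pts[:, 2], rcond=None)
    if rank < A.shape[1]:
        raise ValueError("rank-deficient Zernike fit; refusing to extrapolate")
    return coef


def zernike_eval(coef: np.ndarray, x: np.ndarray, y: np.ndarray,
                 disc_radius: float, max_order: int = 3) -> np.ndarray:
    rho = np.hypot(x, y) / disc_radius
    theta = np.arctan2(y, x)
    A = zernike_basis(np.ravel(rho), np.ravel(theta), max_order)
    return (A @ coef).reshape(np.shape(rho))


def _zernike_radial_derivative(coef, az_deg, r, disc_radius, max_order=3, h=1e-5):
    """dz/dr along each meridian, central difference on the fitted surface."""
    th = np.deg2rad(az_deg)
    xp, yp = (r + h) * np.cos(th), (r + h) * np.sin(th)
    xm, ym = (r - h) * np.cos(th), (r - h) * np.sin(th)
    zp = zernike_eval(coef, xp, yp, disc_radius, max_order)
    zm = zernike_eval(coef, xm, ym, disc_radius, max_order)
    return (zp - zm) / (2 * h)


# ----------------------------------------------------------------------------
# Extended surface
# ----------------------------------------------------------------------------

@dataclass
class ExtendedSurface:
    """Anterior-eye surface extended to the model rim.

    Structured polar storage: elevation (n_az, n_rext) over ``radii_mm``
    stations; ``provenance`` codes 0 = measured, 1 = Zernike-extrapolated,
    2 = scleral extension.
    """

    azimuths_deg: np.ndarray
    radii_mm: np.ndarray
    elevation: np.ndarray
    provenance: np.ndarray
    fit_radius_mm: float
    rim_radius_mm: float
    scleral_radius_mm: float
    zernike_coef: np.ndarray

    def points(self) -> np.ndarray:
        x, y = polar_to_cartesian(self.azimuths_deg, self.radii_mm)
        return np.column_stack([x.ravel(), y.ravel(), self.elevation.ravel()])

    @property
    def apex_z(self) -> float:
        return float(np.mean(self.elevation[:, 0]))

    def to_radial(self, n_el: int = 181, smooth_sigma: float = 2.0) -> "RadialSurface":
        return RadialSurface.from_extended(self, n_el=n_el,
                                           smooth_sigma=smooth_sigma)

    def to_xyz_csv(self, path) -> None:
        labels = {PROV_MEASURED: "measured", PROV_ZERNIKE: "zernike_extrapolated",
                  PROV_SCLERAL: "scleral_extension"}
        pts = self.points()
        prov = self.provenance.ravel()
        with open(path, "w") as fh:
            fh.write("x_mm,y_mm,z_mm,provenance\n")
            for (x, y, z), p in zip(pts, prov):
                fh.write(f"{x:.9g},{y:.9g},{z:.9g},{labels[int(p)]}\n")

    def to_ply(self, path) -> None:
        pts = self.points()
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(pts)}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write("end_header\n")
            for x, y, z in pts:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")


def extend_surface(
    record: TopographyRecord,
    fit_radius_mm: float = 5.5,
    rim_radius_mm: float = 8.2,
    scleral_radius_mm: float = 12.0,
    max_order: int = 3,
    min_points_per_mode: int = 10,
) -> ExtendedSurface:
    """Extend a measured record to the model rim.

    Zernike (order <= ``max_order``) fit on covered samples fills gaps and
    the annulus out to ``fit_radius_mm``; measured samples are retained
    verbatim.  Beyond the fit radius each meridian continues along a
    circular arc of radius ``scleral_radius_mm`` tangent-matched at the
    rim, out to ``rim_radius_mm`` lateral radius.
    """
    if not record.coverage.any():
        raise ValueError("record has empty coverage; nothing to fit")
    coef = zernike_fit(record.points(valid_only=True), fit_radius_mm,
                       max_order, min_points_per_mode)

    az = record.azimuths_deg
    r_meas = record.radii_mm
    dr = max(float(np.mean(np.diff(r_meas))), 1e-3)
    r_zern = np.arange(r_meas[-1] + dr, fit_radius_mm + dr / 2, dr)
    if r_zern.size == 0 or r_zern[-1] < fit_radius_mm - 1e-9:
        r_zern = np.append(r_zern, fit_radius_mm)
    else:
        r_zern[-1] = fit_radius_mm
    dr_scl = 0.05
    r_scl = np.arange(fit_radius_mm + dr_scl, rim_radius_mm + dr_scl / 2, dr_scl)
    radii = np.concatenate([r_meas, r_zern, r_scl])

    n_az = az.size
    elev = np.empty((n_az, radii.size))
    prov = np.empty((n_az, radii.size), dtype=np.int8)

    # measured block: verbatim where covered, Zernike elsewhere
    x_m, y_m = polar_to_cartesian(az, r_meas)
    z_fit_meas = zernike_eval(coef, x_m, y_m, fit_radius_mm, max_order)
    elev[:, : r_meas.size] = np.where(record.coverage, record.elevation, z_fit_meas)
    prov[:, : r_meas.size] = np.where(record.coverage, PROV_MEASURED, PROV_ZERNIKE)

    # Zernike annulus out to the fit radius, with a C1 Hermite correction
    # that absorbs the per-meridian fit residual at the measured rim (the
    # low-order fit would otherwise leave a step where measured data end)
    x_z, y_z = polar_to_cartesian(az, r_zern)
    z_ann = zernike_eval(coef, x_z, y_z, fit_radius_mm, max_order)
    rim_idx = np.array([np.flatnonzero(record.coverage[i])[-1]
                        if record.coverage[i].any() else -1
                        for i in range(n_az)])
    for i in range(n_az):
        j = rim_idx[i]
        if j < 1:
            continue
        rm = r_meas[j]
        span = fit_radius_mm - rm
        if span <= 1e-6:
            continue
        z_meas_rim = record.elevation[i, j]
        th_i = np.deg2rad(az[i])
        z_fit_rim = zernike_eval(coef, rm * np.cos(th_i), rm * np.sin(th_i),
                                 fit_radius_mm, max_order)
        offset = z_meas_rim - z_fit_rim
        jm = max(j - 2, 0)
        slope_meas = (record.elevation[i, j] - record.elevation[i, jm]) \
            / max(r_meas[j] - r_meas[jm], 1e-9)
        slope_fit = _zernike_radial_derivative(
            coef, np.array([az[i]]), rm, fit_radius_mm, max_order)[0]
        dslope = slope_meas - slope_fit
        t = np.clip((r_zern - rm) / span, 0.0, 1.0)
        h00 = 2 * t**3 - 3 * t**2 + 1
        h10 = (t**3 - 2 * t**2 + t) * span
        z_ann[i] += offset * h00 + dslope * h10
        # correct Zernike-filled gaps just inside the rim the same way
        inside = ~record.coverage[i, : r_meas.size] & (r_meas > rm)
        if inside.any():
            ti = np.clip((r_meas[inside] - rm) / span, 0.0, 1.0)
            elev[i, : r_meas.size][inside] += (
                offset * (2 * ti**3 - 3 * ti**2 + 1)
                + dslope * (ti**3 - 2 * ti**2 + ti) * span)
    elev[:, r_meas.size: r_meas.size + r_zern.size] = z_ann
    prov[:, r_meas.size: r_meas.size + r_zern.size] = PROV_ZERNIKE

    # scleral continuation: per-meridian tangent arcs
    r0 = fit_radius_mm
    th = np.deg2rad(az)
    z0 = zernike_eval(coef, r0 * np.cos(th), r0 * np.sin(th), fit_radius_mm, max_order)
    slope = _zernike_radial_derivative(coef, az, r0, fit_radius_mm, max_order)
    Rs = scleral_radius_mm
    denom = np.sqrt(1.0 + slope**2)
    rc = r0 + Rs * slope / denom          # arc centre, meridian-plane coords
    zc = z0 - Rs / denom
    rr = r_scl[None, :]
    arg = Rs**2 - (rr - rc[:, None]) ** 2
    if np.any(arg <= 0):
        raise ValueError("scleral radius too small to reach the model rim")
    elev[:, r_meas.size + r_zern.size:] = zc[:, None] + np.sqrt(arg)
    prov[:, r_meas.size + r_zern.size:] = PROV_SCLERAL

    return ExtendedSurface(az.copy(), radii, elev, prov, fit_radius_mm,
                           rim_radius_mm, scleral_radius_mm, coef)


class RadialSurface:
    """Star-shaped surface as radius r(azimuth, elevation) about a centre.

    The centre sits on the instrument axis, at the mean scleral-arc centre
    depth, so every surface point is single-valued in the polar angle from
    the centre.  Radius queries use a bicubic spline on a uniform
    (azimuth, elevation) grid with wrapped azimuth padding.
    """

    def __init__(self, centre: np.ndarray, az_deg: np.ndarray, el_rad: np.ndarray,
                 radius_grid: np.ndarray):
        self.centre = np.asarray(centre, float)
        self.az_deg = az_deg
        self.el_rad = el_rad
        self.radius_grid = radius_grid
        # wrap azimuth: pad 4 columns each side for smooth periodic cubic
        pad = 4
        az_ext = np.concatenate([az_deg[-pad:] - 360.0, az_deg, az_deg[:pad] + 360.0])
        grid_ext = np.concatenate([radius_grid[-pad:], radius_grid, radius_grid[:pad]], axis=0)
        self._spline = RectBivariateSpline(az_ext, el_rad, grid_ext, kx=3, ky=3)

    @classmethod
    def from_extended(cls, surf: ExtendedSurface, n_el: int = 181,
                      smooth_sigma: float = 2.0) -> "RadialSurface":
        """Radius interpolant for meshing/seating.

        ``smooth_sigma`` (grid samples) applies a gentle Gaussian to the
        radius grid: the low-order fill of lid-truncated regions can leave
        a faint crease along the lid seam which would otherwise imprint
        bending wiggles on the finite-element wall.  On smooth corneal
        shapes the induced radius change is sub-micrometre.
        """
        az = surf.azimuths_deg
        th = np.deg2rad(az)[:, None]
        r_lat = surf.radii_mm[None, :]
        z = surf.elevation
        # centre depth: mean scleral-arc centre (keeps polar angle well under 90 deg)
        coef = surf.zernike_coef
        r0 = surf.fit_radius_mm
        z0 = zernike_eval(coef, r0 * np.cos(th[:, 0]), r0 * np.sin(th[:, 0]), r0)
        slope = _zernike_radial_derivative(coef, az, r0, r0)
        zc = float(np.mean(z0 - surf.scleral_radius_mm / np.sqrt(1 + slope**2)))
        centre = np.array([0.0, 0.0, zc])

        dz = z - zc
        el = np.arctan2(np.broadcast_to(r_lat, z.shape), dz)   # 0 at apex
        rad = np.hypot(r_lat, dz)
        # enforce strict monotonicity (tiny fit-residual wiggles otherwise
        # break the angle parametrisation near data seams)
        el = np.maximum.accumulate(el, axis=1)
        el += np.arange(el.shape[1]) * 1e-12
        el_max = float(np.min(el[:, -1]))
        el_grid = np.linspace(0.0, el_max, n_el)
        radius_grid = np.empty((az.size, n_el))
        for i in range(az.size):
            radius_grid[i] = np.interp(el_grid, el[i], rad[i])
        if smooth_sigma > 0:
            from scipy.ndimage import gaussian_filter
            radius_grid = gaussian_filter(
                radius_grid, sigma=(smooth_sigma, smooth_sigma),
                mode=("wrap", "nearest"))
        return cls(centre, az.copy(), el_grid, radius_grid)

    @property
    def el_max(self) -> float:
        return float(self.el_rad[-1])

    def radius(self, az_deg: np.ndarray, el_rad: np.ndarray) -> np.ndarray:
        az = np.asarray(az_deg, float) % 360.0
        el = np.asarray(el_rad, float)
        if np.any(el > self.el_max + 1e-9) or np.any(el < -1e-12):
            raise ValueError("query elevation outside surface angular support")
        return self._spline(az, np.clip(el, 0.0, self.el_max), grid=False)

    def point(self, az_deg: np.ndarray, el_rad: np.ndarray) -> np.ndarray:
        """Cartesian points for direction arrays (broadcast 1-D)."""
        az = np.deg2rad(np.asarray(az_deg, float))
        el = np.asarray(el_rad, float)
        r = self.radius(np.rad2deg(az), el)
        return self.centre + np.column_stack([
            r * np.sin(el) * np.cos(az), r * np.sin(el) * np.sin(az), r * np.cos(el)])

    def direction_of_points(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = np.asarray(pts, float) - self.centre
        az = np.rad2deg(np.arctan2(d[:, 1], d[:, 0])) % 360.0
        el = np.arctan2(np.hypot(d[:, 0], d[:, 1]), d[:, 2])
        return az, el

    def signed_gap(self, pts: np.ndarray) -> np.ndarray:
        """Signed radial clearance of points: positive outside the surface."""
        d = np.asarray(pts, float) - self.centre
        az, el = self.direction_of_points(pts)
        return np.linalg.norm(d, axis=1) - self.radius(az, el)

    def surface_point_and_tangents(self, az_deg, el_rad):
        """p(az, el) with partial derivatives wrt azimuth (rad) and elevation."""
        az = np.asarray(az_deg, float) % 360.0
        el = np.clip(np.asarray(el_rad, float), 1e-9, self.el_max - 1e-9)
        r = self._spline(az, el, grid=False)
        dr_da = self._spline(az, el, dx=1, grid=False) * 180.0 / np.pi
        dr_de = self._spline(az, el, dy=1, grid=False)
        a = np.deg2rad(az)
        sa, ca, se, ce = np.sin(a), np.cos(a), np.sin(el), np.cos(el)
        u = np.column_stack([se * ca, se * sa, ce])
        du_da = np.column_stack([-se * sa, se * ca, np.zeros_like(a)])
        du_de = np.column_stack([ce * ca, ce * sa, -se])
        p = self.centre + r[:, None] * u
        pa = dr_da[:, None] * u + r[:, None] * du_da
        pe = dr_de[:, None] * u + r[:, None] * du_de
        return p, pa, pe

    def closest_points(self, pts: np.ndarray, iters: int = 4,
                       return_normals: bool = False):
        """True closest points on the smooth surface (Gauss-Newton in
        (azimuth, elevation) from the radial-direction initial guess)."""
        pts = np.asarray(pts, float)
        az, el = self.direction_of_points(pts)
        for _ in range(iters):
            p, pa, pe = self.surface_point_and_tangents(az, el)
            d = pts - p
            # 2x2 normal equations per point
            a11 = np.einsum("ij,ij->i", pa, pa)
            a12 = np.einsum("ij,ij->i", pa, pe)
            a22 = np.einsum("ij,ij->i", pe, pe)
            b1 = np.einsum("ij,ij->i", pa, d)
            b2 = np.einsum("ij,ij->i", pe, d)
            det = np.maximum(a11 * a22 - a12**2, 1e-30)
            daz = (a22 * b1 - a12 * b2) / det
            dele = (a11 * b2 - a12 * b1) / det
            az = (az + np.rad2deg(daz)) % 360.0
            el = np.clip(el + dele, 1e-9, self.el_max - 1e-9)
        p, pa, pe = self.surface_point_and_tangents(az, el)
        if not return_normals:
            return p
        n = np.cross(pe, pa)
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        return p, n

    def dense_cloud(self, n_az: int = 240, n_el: int = 160) -> np.ndarray:
        az = np.linspace(0, 360, n_az, endpoint=False)
        el = np.linspace(1e-4, self.el_max, n_el)
        A, E = np.meshgrid(az, el, indexing="ij")
        return self.point(A.ravel(), E.ravel())

    def el_at_lateral_radius(self, r_lat: float) -> float:
        """Elevation angle at which the surface reaches lateral radius r_lat."""
        els = np.linspace(1e-4, self.el_max, 2000)
        r = self.radius(np.zeros_like(els), els)
        lat = np.mean(
            [self.radius(np.full_like(els, a), els) * np.sin(els)
             for a in (0.0, 90.0, 180.0, 270.0)], axis=0)
        if r_lat > lat[-1] + 1e-9:
            raise ValueError(f"surface does not reach lateral radius {r_lat} mm")
        return float(np.interp(r_lat, lat, els))
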