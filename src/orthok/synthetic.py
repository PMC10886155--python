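"""Seeded synthetic cohort generation.

The generator emulates the clinical material the pipeline is built for:
conicoid-with-astigmatism anterior corneal surfaces whose simulated
keratometry, asphericity, and metadata (age, IOP, CCT) follow the study
cohort's reported distributions; an overnight Ortho-K effect — a central
flattened zone with an annular steepened zone, optionally decentred —
imposed on the elevation so that the induced *power* change hits the
requested dioptric targets; lash-gap coverage footprints bounded by
upper/lower parabolic lid edges; and matched rigid reverse-geometry lens
designs.

Everything is deterministic: one integer cohort seed, per-patient streams
derived by hashing (seed, index), so a cohort can be regenerated
patient-by-patient in any order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter

from .eyelid import EyelidBoundary
from .maps import GridMap
from .meshing import LensDesign
from .topography import TopographyRecord, default_polar_grid, polar_to_cartesian

__all__ = [
    "PatientRecord",
    "OrthokEffectSpec",
    "CohortSpec",
    "generate_patient",
    "apply_orthok_effect",
    "generate_coverage_mask",
    "generate_correlated_field",
    "sample_eyelid_boundary",
    "write_cohort_manifest",
]

KERATOMETRIC_CONSTANT = 337.5   # (1.3375 - 1) * 1000: D <-> mm radius

# Cohort second-order lid-edge statistics (a, b, c): mean and SD per lid
LID_STATS = {
    "right": {"upper": ((-0.0832, -0.0262, 3.5809), (0.0197, 0.0445, 0.4375)),
              "lower": ((0.0842, 0.0163, -3.9734), (0.0197, 0.0445, 0.4375))},
    "left": {"upper": ((-0.0864, 0.0256, 3.6564), (0.0187, 0.0463, 0.3865)),
             "lower": ((0.0868, -0.0206, -3.9902), (0.0187, 0.0463, 0.3865))},
}


@dataclass
class PatientRecord:
    """Clinical metadata for one synthetic eye."""

    id: str
    age: float            # years
    iop: float            # mmHg
    cct: float            # mm
    eye: str              # {"right", "left"}
    exam_date: str = "2024-01-01"

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError("age must be positive")
        if not 5.0 <= self.iop <= 40.0:
            raise ValueError(f"IOP {self.iop} mmHg outside plausible range [5, 40]")
        if not 0.35 <= self.cct <= 0.75:
            raise ValueError(f"CCT {self.cct} mm outside plausible range [0.35, 0.75]")


@dataclass
class OrthokEffectSpec:
    """Imposed treatment effect, specified in power space (dioptres)."""

    central_flattening: float = -2.5      # D, < 0
    annulus_steepening: float = 1.5       # D, > 0
    annulus_radius: float = 2.8           # mm
    decentration: tuple = (0.0, 0.0)      # (dx, dy) mm
    transition_width: float = 0.6         # mm

    def __post_init__(self) -> None:
        zero = self.central_flattening == 0 and self.annulus_steepening == 0
        if not zero:
            if not self.central_flattening < 0:
                raise ValueError("central flattening must be negative (dioptres)")
            if not self.annulus_steepening > 0:
                raise ValueError("annulus steepening must be positive (dioptres)")
        if not self.annulus_radius > 0:
            raise ValueError("annulus radius must be positive")
        if not self.transition_width > 0:
            raise ValueError("transition width must be positive")

    @property
    def outer_support_mm(self) -> float:
        return self.annulus_radius + 2.0 * self.transition_width


@dataclass
class CohortSpec:
    """Cohort size, seed, and sampling distributions (mean, sd)."""

    n: int = 10
    seed: int = 0
    age_years: tuple = (14.1, 4.0)
    iop_mmhg: tuple = (15.0, 3.0)
    cct_mm: tuple = (0.554, 0.033)
    simk_flat_d: tuple = (42.6, 1.3)
    simk_steep_d: tuple = (44.0, 1.3)
    asphericity_flat: tuple = (0.66, 0.10)
    asphericity_steep: tuple = (0.40, 0.18)
    asphericity_convention: str = "e2"     # {"e2", "q", "neg_q", "p"}
    central_flattening_d: tuple = (-2.5, 0.75)
    annulus_steepening_d: tuple = (1.5, 0.5)
    annulus_radius_mm: tuple = (2.8, 0.3)
    decentration_sd_mm: float = 0.3
    transition_width_mm: float = 0.6
    right_eye_fraction: float = 132.0 / 249.0
    slit_count: int = 6
    slit_width_deg: float = 2.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        for name in ("age_years", "iop_mmhg", "cct_mm", "simk_flat_d",
                     "simk_steep_d", "asphericity_flat", "asphericity_steep",
                     "central_flattening_d", "annulus_steepening_d",
                     "annulus_radius_mm"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"negative sd for {name}")
        if self.asphericity_convention not in ("e2", "q", "neg_q", "p"):
            raise ValueError("unknown asphericity convention")


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def _as_q(value: float, convention: str) -> float:
    """Convert a tabulated asphericity to the conicoid Q."""
    if convention == "q":
        return value
    if convention == "neg_q":
        return -value
    if convention == "e2":
        return -value          # Q = -e^2, prolate for e^2 > 0
    if convention == "p":
        return value - 1.0     # p = 1 + Q
    raise ValueError(convention)


def conicoid_elevation(az_deg, r_mm, k_flat_d, k_steep_d, flat_angle_deg,
                       q_flat, q_steep) -> np.ndarray:
    """Toric conicoid sag z(theta, r) = -r^2 / (R (1 + sqrt(1-(1+Q) r^2/R^2))).

    Apical radius and asphericity vary with the meridian as
    K(theta) = Kf + (Ks - Kf) sin^2(theta - flat axis); +Z anterior.
    """
    th = np.deg2rad(np.asarray(az_deg, float))[:, None]
    r = np.asarray(r_mm, float)[None, :]
    s2 = np.sin(th - np.deg2rad(flat_angle_deg)) ** 2
    K = k_flat_d + (k_steep_d - k_flat_d) * s2
    Q = q_flat + (q_steep - q_flat) * s2
    R = KERATOMETRIC_CONSTANT / K
    arg = 1.0 - (1.0 + Q) * r**2 / R**2
    if np.any(arg <= 0):
        raise ValueError("conicoid parameters do not span the requested radius")
    return -(r**2) / (R * (1.0 + np.sqrt(arg)))


def sample_eyelid_boundary(rng: np.random.Generator, eye: str = "right") -> EyelidBoundary:
    """Draw lid parabolas from the cohort lid statistics."""
    stats = LID_STATS[eye]
    for _ in range(100):
        up = tuple(rng.normal(m, s) for m, s in zip(*stats["upper"]))
        lo = tuple(rng.normal(m, s) for m, s in zip(*stats["lower"]))
        if up[0] < -1e-3 and lo[0] > 1e-3 and up[2] > 0.5 and lo[2] < -0.5:
            return EyelidBoundary(up, lo)
    raise RuntimeError("could not sample a valid lid boundary")


def generate_coverage_mask(
    boundary: EyelidBoundary | None,
    azimuths_deg: np.ndarray,
    radii_mm: np.ndarray,
    device_radius_mm: float | None = None,
    slit_count: int = 6,
    slit_width_deg: float = 2.0,
    slit_depth_mm: float = 0.8,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Coverage footprint: palpebral aperture x device disc, with lash slits.

    ``boundary=None`` means no lid truncation (full-disc mask).  Raises if
    the aperture between the lid curves misses the coverage disc entirely.
    """
    az = np.asarray(azimuths_deg, float)
    r = np.asarray(radii_mm, float)
    if device_radius_mm is None:
        device_radius_mm = r[-1]
    x, y = polar_to_cartesian(az, r)
    rr = np.hypot(x, y)
    mask = rr <= device_radius_mm + 1e-12
    if boundary is None:
        return mask
    aperture = (y < boundary.upper_y(x)) & (y > boundary.lower_y(x))
    out = mask & aperture
    if not out.any():
        raise ValueError("lid curves leave no aperture inside the coverage disc")
    if out.all() or np.array_equal(out, mask):
        return out   # lids outside the disc: full-disc coverage
    if slit_count > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        # azimuths whose boundary is set by a lid (not the device rim)
        idx_per_az = [np.flatnonzero(out[i]) for i in range(az.size)]
        lid_az = [i for i, idx in enumerate(idx_per_az)
                  if idx.size and r[idx[-1]] < device_radius_mm - 1e-6]
        if lid_az:
            centres = rng.choice(az[lid_az], size=min(slit_count, len(lid_az)),
                                 replace=False)
            widths = rng.uniform(0.5, 1.0, size=len(centres)) * slit_width_deg
            for c, wdeg in zip(centres, widths):
                dang = np.abs((az - c + 180) % 360 - 180)
                sector = dang <= wdeg / 2
                for i in np.flatnonzero(sector):
                    idx = np.flatnonzero(out[i])
                    if idx.size == 0:
                        continue
                    r_edge = r[idx[-1]]
                    out[i] &= r < r_edge - slit_depth_mm
    return out


# ----------------------------------------------------------------------------
# Ortho-K effect in elevation space
# ----------------------------------------------------------------------------

def _bump(r: np.ndarray, centre: float, width: float) -> np.ndarray:
    """C1 compact-support cosine-squared bump on |r - centre| < width."""
    t = (r - centre) / width
    out = np.zeros_like(r)
    inside = np.abs(t) < 1.0
    out[inside] = np.cos(0.5 * np.pi * t[inside]) ** 2
    return out


def _effect_displacement_profile(effect: OrthokEffectSpec,
                                 mean_slope_sq: callable) -> tuple[np.ndarray, np.ndarray]:
    """Radial anterior-displacement profile delta z(r) realising the effect.

    The effect is specified as a tangential-power change; since curvature
    is (to leading order) the second radial derivative scaled by the slope
    factor g = (1 + z'^2)^(3/2), the displacement obeys
    delta'' = -(dP/337.5) * g.  Two auxiliary transition bumps close the
    profile (delta' and delta vanish at the outer support) so the surface
    is conserved exactly beyond annulus_radius + 2*transition_width.
    """
    a, tw = effect.annulus_radius, effect.transition_width
    r_end = effect.outer_support_mm
    r = np.linspace(0.0, r_end, 2001)
    g = (1.0 + mean_slope_sq(r)) ** 1.5

    # CFZ depression, the requested ASZ ring, and a wider steepening shell
    # on [a - tw, a + 2 tw] whose amplitude closes the profile
    # (delta'(r_end) = 0); the closure shell is what real RPC maps show as
    # the broad annular steepened zone balancing the central flattening
    shapes = [
        _bump(r, 0.0, max(a - tw, 0.5 * a)),          # CFZ
        _bump(r, a, tw),                              # ASZ core
        _bump(r, a + 0.5 * tw, 1.5 * tw),             # closure shell
    ]

    def slope_end(dd):
        return cumulative_trapezoid(dd, r, initial=0.0)[-1]

    cols = [slope_end(-s * g / KERATOMETRIC_CONSTANT) for s in shapes]
    c2 = -(effect.central_flattening * cols[0]
           + effect.annulus_steepening * cols[1]) / cols[2]
    amps = [effect.central_flattening, effect.annulus_steepening, c2]
    dd = sum(amp * (-s * g / KERATOMETRIC_CONSTANT) for amp, s in zip(amps, shapes))
    d1 = cumulative_trapezoid(dd, r, initial=0.0)
    dz = cumulative_trapezoid(d1, r, initial=0.0)
    # piston shift: delta(r_end) -> 0 exactly; delta'(r_end) = 0 by closure,
    # so the profile joins the untouched surface with C1 continuity
    dz -= dz[-1]
    return r, dz


def apply_orthok_effect(pre: TopographyRecord, effect: OrthokEffectSpec) -> TopographyRecord:
    """Impose the treatment effect on a pre-wear record (returns post-wear).

    The elevation change is C1, radially symmetric about the decentred
    effect centre, and identically zero beyond
    annulus_radius + 2*transition_width from that centre.
    """
    r_max = pre.radii_mm[-1]
    if effect.annulus_radius + effect.transition_width > r_max + 1e-9:
        raise ValueError("effect extends beyond the measured radius")
    if effect.central_flattening == 0 and effect.annulus_steepening == 0:
        return pre.copy()

    # mean meridional slope of the pre surface for the curvature scale factor
    zbar = np.nanmean(np.where(pre.coverage, pre.elevation, np.nan), axis=0)
    ok = np.isfinite(zbar)
    slope = np.gradient(zbar[ok], pre.radii_mm[ok])
    r_ok = pre.radii_mm[ok]

    def mean_slope_sq(r):
        return np.interp(r, r_ok, slope**2)

    rp, dz = _effect_displacement_profile(effect, mean_slope_sq)

    x, y = polar_to_cartesian(pre.azimuths_deg, pre.radii_mm)
    dx, dy = effect.decentration
    rd = np.hypot(x - dx, y - dy)
    delta = np.where(rd < rp[-1], np.interp(rd, rp, dz), 0.0)

    out = pre.copy()
    out.elevation = pre.elevation + delta
    return out


# ----------------------------------------------------------------------------
# Patient generation
# ----------------------------------------------------------------------------

def _clipped_normal(rng, mean, sd, lo, hi):
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def sample_metadata(spec: CohortSpec, index: int,
                    rng: np.random.Generator | None = None) -> PatientRecord:
    """Metadata draw for patient ``index`` (the head of its random stream)."""
    if rng is None:
        rng = _patient_rng(spec.seed, index)
    age = _clipped_normal(rng, *spec.age_years, 5.0, 60.0)
    iop = _clipped_normal(rng, *spec.iop_mmhg, 5.0, 40.0)
    cct = _clipped_normal(rng, *spec.cct_mm, 0.35, 0.75)
    eye = "right" if rng.random() < spec.right_eye_fraction else "left"
    return PatientRecord(id=f"SYN{spec.seed:04d}-{index:03d}", age=age,
                         iop=iop, cct=cct, eye=eye)


def generate_patient(spec: CohortSpec, index: int):
    """Deterministically generate patient ``index`` of a cohort.

    Returns ``(PatientRecord, TopographyRecord, LensDesign, OrthokEffectSpec)``;
    the effect spec is the ground truth for recovery tests (its true
    decentration is also written to the cohort manifest).
    """
    if not 0 <= index < spec.n:
        raise ValueError(f"index {index} outside cohort of size {spec.n}")
    rng = _patient_rng(spec.seed, index)
    patient = sample_metadata(spec, index, rng)

    k_flat = rng.normal(*spec.simk_flat_d)
    k_steep = max(rng.normal(*spec.simk_steep_d), k_flat)
    q_flat = _as_q(rng.normal(*spec.asphericity_flat), spec.asphericity_convention)
    q_steep = _as_q(rng.normal(*spec.asphericity_steep), spec.asphericity_convention)
    flat_angle = float(rng.normal(0.0, 15.0) % 180.0)

    az, r = default_polar_grid()
    elev = conicoid_elevation(az, r, k_flat, k_steep, flat_angle, q_flat, q_steep)
    lids = sample_eyelid_boundary(rng, patient.eye)
    cov = generate_coverage_mask(lids, az, r, slit_count=spec.slit_count,
                                 slit_width_deg=spec.slit_width_deg, rng=rng)
    record = TopographyRecord(
        np.where(cov, elev, np.nan), r, az, cov, eye=patient.eye,
        simk_flat_d=k_flat, simk_steep_d=k_steep,
        flat_angle_deg=flat_angle, steep_angle_deg=(flat_angle + 90.0) % 180.0,
    )

    effect = OrthokEffectSpec(
        central_flattening=min(rng.normal(*spec.central_flattening_d), -0.5),
        annulus_steepening=max(rng.normal(*spec.annulus_steepening_d), 0.25),
        annulus_radius=_clipped_normal(rng, *spec.annulus_radius_mm, 2.0, 3.6),
        decentration=tuple(rng.normal(0.0, spec.decentration_sd_mm, size=2)),
        transition_width=spec.transition_width_mm,
    )

    base_r = KERATOMETRIC_CONSTANT / (k_flat + effect.central_flattening)
    align_r = KERATOMETRIC_CONSTANT / k_flat
    lens = LensDesign(
        base_radius=round(base_r, 2),
        reverse_radius=round(base_r - 2.0, 2),
        alignment1_radius=round(align_r, 2),
        alignment2_radius=round(align_r + 0.2, 2),
    )
    return patient, record, lens, effect


def write_cohort_manifest(spec: CohortSpec, path) -> None:
    """Cohort manifest CSV: metadata, lens parameters, true decentration."""
    import pandas as pd

    rows = []
    for i in range(spec.n):
        p, rec, lens, eff = generate_patient(spec, i)
        rows.append({
            "id": p.id, "age": p.age, "iop": p.iop, "cct": p.cct, "eye": p.eye,
            "simk_flat_d": rec.simk_flat_d, "simk_steep_d": rec.simk_steep_d,
            "lens_base_radius": lens.base_radius,
            "lens_reverse_radius": lens.reverse_radius,
            "lens_diameter": lens.diameter,
            "true_decentration_x": eff.decentration[0],
            "true_decentration_y": eff.decentration[1],
            "central_flattening_d": eff.central_flattening,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# ----------------------------------------------------------------------------
# Correlated validation fields
# ----------------------------------------------------------------------------

def generate_correlated_field(rpc: GridMap, rho: float, seed: int,
                              noise_sigma_px: float = 6.0) -> GridMap:
    """Smooth random field with target zero-lag correlation ``rho`` to ``rpc``.

    field = rho * standardized(rpc) + sqrt(1 - rho^2) * smooth noise, with
    the noise projected orthogonal to the map over the valid region.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    m = rpc.mask
    v = rpc.values[m]
    if v.size < 2 or np.std(v) < 1e-12:
        raise ValueError("constant map: correlation target is undefined")
    z = np.zeros_like(rpc.values)
    z[m] = (v - v.mean()) / v.std()

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x0C0FFEE]))
    noise = gaussian_filter(rng.standard_normal(rpc.values.shape), noise_sigma_px)
    nv = noise[m]
    nv = nv - nv.mean()
    zv = z[m]
    nv = nv - (nv @ zv) / (zv @ zv) * zv          # exact orthogonality
    sd = nv.std()
    if sd < 1e-15:
        raise ValueError("degenerate noise field")
    noise_std = np.zeros_like(z)
    noise_std[m] = nv / sd

    out = rho * z + np.sqrt(max(1.0 - rho**2, 0.0)) * noise_std
    vals = np.where(m, out, np.nan)
    return GridMap(rpc.x_mm.copy(), rpc.y_mm.copy(), vals, m.copy(), units="")
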