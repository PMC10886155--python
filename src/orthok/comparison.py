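"""Map comparison: common-grid resampling, 2D NCC, SSIM, band areas.

All maps are resampled by triangulation-based cubic interpolation onto
the common Cartesian grid (x, y from -8 to 8 mm in 0.1 mm steps, 161 x
161) and normalised to [-1, 1] before comparison.

The normalised cross-correlation surface

    gamma(u, v) = sum[(f - f_uv_bar)(t_shifted - t_bar)] /
                  sqrt(sum(f - f_uv_bar)^2 * sum(t_shifted - t_bar)^2)

is computed over every displacement with local sums obtained from
precomputed running sums (FFT-based correlations of the zero-filled maps
and their validity masks, so invalid cells drop out of every sum).  The
central template-sized window is reported as the spatial coefficient
map; the full surface is retained for inspection.

SSIM combines local luminance, contrast and structure terms computed
with an 11 x 11 Gaussian window (sigma 1.5) on maps rescaled to [0, 1]:

    SSIM = l^alpha * c^beta * s^gamma,   l = (2 mx my + C1)/(mx^2 + my^2 + C1),
    c = (2 sx sy + C2)/(sx^2 + sy^2 + C2),  s = (sxy + C3)/(sx sy + C3)

with C1 = (0.01 L)^2, C2 = (0.03 L)^2, C3 = C2/2, exponents 1.

Coefficient bands: weak |g| < 0.4, moderate 0.4 <= |g| < 0.6, strong
|g| >= 0.6 (half-open at the band edges); band areas are reported as
percentages of the analysis mask using exact rational cell counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import ndimage
from scipy.interpolate import griddata
from scipy.signal import fftconvolve
from scipy.stats import ttest_ind

from .maps import GridMap, PolarMap, common_grid

__all__ = [
    "CommonGrid", "SsimParams", "ComparisonResult", "BAND_EDGES",
    "resample_to_grid", "normalize_map", "ncc_map", "ncc_zero_lag",
    "ssim_map", "classify_areas", "compare_fields", "cohort_summary",
]

BAND_EDGES = (0.4, 0.6)


@dataclass
class CommonGrid:
    """The shared analysis grid and its valid-cornea mask."""

    x_mm: np.ndarray
    y_mm: np.ndarray
    mask: np.ndarray

    @classmethod
    def default(cls, extent_mm: float = 8.0, step_mm: float = 0.1,
                analysis_radius_mm: float = 5.5) -> "CommonGrid":
        x, y = common_grid(extent_mm, step_mm)
        X, Y = np.meshgrid(x, y)
        return cls(x, y, np.hypot(X, Y) <= analysis_radius_mm)


def resample_to_grid(points_xy: np.ndarray, values: np.ndarray,
                     grid: CommonGrid) -> GridMap:
    """Triangulation-based cubic interpolation onto the common grid.

    Queries outside the convex hull of the source points are invalid, not
    extrapolated.
    """
    pts = np.asarray(points_xy, float)
    vals = np.asarray(values, float)
    ok = np.isfinite(vals) & np.all(np.isfinite(pts), axis=1)
    if ok.sum() < 3:
        raise ValueError("need at least 3 valid source points to triangulate")
    X, Y = np.meshgrid(grid.x_mm, grid.y_mm)
    Z = griddata(pts[ok], vals[ok], (X, Y), method="cubic")
    mask = np.isfinite(Z)
    return GridMap(grid.x_mm.copy(), grid.y_mm.copy(),
                   np.where(mask, Z, np.nan), mask)


def polar_to_grid(pmap: PolarMap, grid: CommonGrid) -> GridMap:
    x, y = pmap.xy()
    m = pmap.mask
    return resample_to_grid(np.column_stack([x[m], y[m]]), pmap.values[m], grid)


def normalize_map(gm: GridMap, analysis_mask: np.ndarray | None = None) -> GridMap:
    """Scale into [-1, 1] by the maximum absolute value over the mask."""
    m = gm.mask if analysis_mask is None else (gm.mask & analysis_mask)
    if not m.any():
        raise ValueError("no valid cells to normalise")
    peak = np.nanmax(np.abs(gm.values[m]))
    out = gm.copy()
    if peak == 0:
        warnings.warn("all-zero map: normalisation left values unchanged")
        return out
    out.values = gm.values / peak
    return out


# ----------------------------------------------------------------------------
# Normalised cross-correlation (running-sum formulation)
# ----------------------------------------------------------------------------

def _corr_full(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross-correlation sums over every displacement (full mode)."""
    return fftconvolve(a, b[::-1, ::-1], mode="full")


@dataclass
class CorrelationMap:
    """NCC result: central template-aligned window + full (u, v) surface."""

    map: GridMap
    full_surface: np.ndarray
    overlap: np.ndarray


def ncc_full_surface(template: np.ndarray, t_mask: np.ndarray,
                     image: np.ndarray, f_mask: np.ndarray,
                     min_overlap: int = 16):
    """Masked NCC surface gamma(u, v) for all displacements.

    Invalid cells are excluded from every local sum; positions whose
    overlap holds fewer than ``min_overlap`` valid cell pairs are NaN.
    """
    t0 = np.where(t_mask, template, 0.0)
    f0 = np.where(f_mask, image, 0.0)
    mt = t_mask.astype(float)
    mf = f_mask.astype(float)
    n = _corr_full(mf, mt)
    sf = _corr_full(f0, mt)
    st = _corr_full(mf, t0)
    sff = _corr_full(f0 * f0, mt)
    stt = _corr_full(mf, t0 * t0)
    sft = _corr_full(f0, t0)
    n = np.round(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = sft - sf * st / n
        var_f = np.clip(sff - sf**2 / n, 0.0, None)
        var_t = np.clip(stt - st**2 / n, 0.0, None)
        den = np.sqrt(var_f * var_t)
        gamma = num / den
    tiny = den <= 1e-10 * np.maximum(np.abs(sff).max(), 1.0) * 1e-6
    bad = (n < min_overlap) | ~np.isfinite(gamma) | tiny
    gamma = np.where(bad, np.nan, np.clip(gamma, -1.0, 1.0))
    return gamma, n


def ncc_map(template: GridMap, image: GridMap, min_overlap: int = 16) -> CorrelationMap:
    """Eq-style masked NCC of two common-grid maps.

    The template is the RPC map; the returned spatial map is the central
    template-sized window of the displacement surface (zero displacement
    at the map centre).
    """
    if template.values.shape != image.values.shape:
        raise ValueError("maps must share the common grid")
    tv = template.values[template.mask]
    if tv.size == 0 or np.nanstd(tv) < 1e-14:
        raise ValueError("zero-variance template")
    gamma, n = ncc_full_surface(template.values, template.mask,
                                image.values, image.mask, min_overlap)
    ny, nx = template.values.shape
    cy, cx = ny - 1, nx - 1            # zero displacement index in full surface
    y0, x0 = cy - ny // 2, cx - nx // 2
    win = gamma[y0:y0 + ny, x0:x0 + nx]
    gm = GridMap(template.x_mm.copy(), template.y_mm.copy(), win,
                 np.isfinite(win))
    return CorrelationMap(map=gm, full_surface=gamma, overlap=n)


def ncc_zero_lag(a: GridMap, b: GridMap) -> float:
    """Zero-displacement NCC coefficient (masked Pearson correlation)."""
    m = a.mask & b.mask
    av, bv = a.values[m], b.values[m]
    av = av - av.mean()
    bv = bv - bv.mean()
    return float(av @ bv / np.sqrt((av @ av) * (bv @ bv)))


# ----------------------------------------------------------------------------
# SSIM
# ----------------------------------------------------------------------------

@dataclass
class SsimParams:
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    L: float = 1.0                 # dynamic range after rescaling to [0, 1]
    k1: float = 0.01
    k2: float = 0.03
    win_size: int = 11
    sigma: float = 1.5

    @property
    def C1(self) -> float:
        return (self.k1 * self.L) ** 2

    @property
    def C2(self) -> float:
        return (self.k2 * self.L) ** 2

    @property
    def C3(self) -> float:
        return self.C2 / 2


def _gaussian_kernel(win: int, sigma: float) -> np.ndarray:
    r = win // 2
    x = np.arange(-r, r + 1)
    g = np.exp(-(x**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim_map(x: GridMap, y: GridMap, params: SsimParams | None = None) -> GridMap:
    """Pointwise SSIM of two normalised ([-1, 1]) common-grid maps.

    Maps are affinely rescaled to [0, 1] before the windowed statistics;
    invalid cells are filled with the valid mean for the filtering and
    masked out of the result.
    """
    params = params or SsimParams()
    if x.values.shape != y.values.shape:
        raise ValueError("maps must share the common grid")
    if params.win_size > min(x.values.shape):
        raise ValueError("window larger than map")
    mask = x.mask & y.mask
    k = _gaussian_kernel(params.win_size, params.sigma)

    def prep(gm):
        v = (gm.values + 1.0) / 2.0
        fill = np.nanmean(v[mask]) if mask.any() else 0.0
        return np.where(mask, v, fill)

    xv, yv = prep(x), prep(y)

    def filt(a):
        return ndimage.correlate(a, k, mode="reflect")

    mx, my = filt(xv), filt(yv)
    sxx = np.clip(filt(xv * xv) - mx * mx, 0.0, None)
    syy = np.clip(filt(yv * yv) - my * my, 0.0, None)
    sxy = filt(xv * yv) - mx * my
    sx, sy = np.sqrt(sxx), np.sqrt(syy)

    C1, C2, C3 = params.C1, params.C2, params.C3
    l = (2 * mx * my + C1) / (mx**2 + my**2 + C1)
    c = (2 * sx * sy + C2) / (sx**2 + sy**2 + C2)
    s = (sxy + C3) / (sx * sy + C3)
    if params.alpha == params.beta == params.gamma == 1.0:
        ss = l * c * s
    else:
        ss = (np.sign(l) * np.abs(l) ** params.alpha
              * np.abs(c) ** params.beta
              * np.sign(s) * np.abs(s) ** params.gamma)
    ss = np.clip(ss, -1.0, 1.0)
    return GridMap(x.x_mm.copy(), x.y_mm.copy(),
                   np.where(mask, ss, np.nan), mask)


# ----------------------------------------------------------------------------
# Band classification and cohort statistics
# ----------------------------------------------------------------------------

def classify_areas(coef: GridMap, analysis_mask: np.ndarray) -> dict:
    """Weak/moderate/strong band areas as exact percentages of the mask."""
    m = analysis_mask & coef.mask
    total = int(analysis_mask.sum())
    if total == 0:
        raise ValueError("empty analysis mask")
    g = np.abs(coef.values[m])
    if g.size and (np.nanmax(g) > 1 + 1e-12):
        raise ValueError("coefficients outside [-1, 1]")
    weak = int(np.sum(g < BAND_EDGES[0]))
    moderate = int(np.sum((g >= BAND_EDGES[0]) & (g < BAND_EDGES[1])))
    strong = int(np.sum(g >= BAND_EDGES[1]))
    other = total - weak - moderate - strong   # cells invalid in the coef map
    counts = {"weak": weak + other, "moderate": moderate, "strong": strong}
    pct = {k: float(Fraction(v * 100, total)) for k, v in counts.items()}
    return pct


@dataclass
class ComparisonResult:
    """Per-barometer NCC/SSIM maps and their band-area percentages."""

    ncc_maps: dict = field(default_factory=dict)
    ssim_maps: dict = field(default_factory=dict)
    ncc_bands: dict = field(default_factory=dict)
    ssim_bands: dict = field(default_factory=dict)

    @property
    def barometers(self) -> list:
        return sorted(self.ncc_bands)


def compare_fields(rpc: GridMap, fields: dict, grid: CommonGrid,
                   ssim_params: SsimParams | None = None) -> ComparisonResult:
    """NCC and SSIM of each (normalised) barometer map against the RPC map."""
    res = ComparisonResult()
    rpc_n = normalize_map(rpc, grid.mask)
    for name, fm in fields.items():
        fm_n = normalize_map(fm, grid.mask)
        cm = ncc_map(rpc_n, fm_n)
        sm = ssim_map(rpc_n, fm_n, ssim_params)
        res.ncc_maps[name] = cm
        res.ssim_maps[name] = sm
        res.ncc_bands[name] = classify_areas(cm.map, grid.mask)
        res.ssim_bands[name] = classify_areas(sm, grid.mask)
    return res


def _lilliefors_p(sample: np.ndarray) -> float:
    from statsmodels.stats.diagnostic import lilliefors
    if np.std(sample) < 1e-12:
        return float("nan")
    return float(lilliefors(sample, dist="norm")[1])


def cohort_summary(results: list) -> dict:
    """Cohort statistics of band-area percentages.

    Per barometer and band: mean +- SD (SD NaN for n = 1), a
    Lilliefors-corrected KS normality p-value, and pairwise two-sample
    t-tests between barometers on each band at the 95% confidence level.
    """
    if len(results) < 1:
        raise ValueError("need at least one comparison result")
    barometers = results[0].barometers
    for r in results:
        if r.barometers != barometers:
            raise ValueError("mismatched barometer sets across results")
    out = {"n": len(results), "ncc": {}, "ssim": {}, "t_tests": []}
    for metric in ("ncc", "ssim"):
        for b in barometers:
            for band in ("weak", "moderate", "strong"):
                vals = np.array([getattr(r, f"{metric}_bands")[b][band]
                                 for r in results])
                entry = {
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                }
                if len(vals) >= 4:
                    entry["ks_normality_p"] = _lilliefors_p(vals)
                out[metric].setdefault(b, {})[band] = entry
    if len(results) > 1:
        for metric in ("ncc", "ssim"):
            for band in ("weak", "moderate", "strong"):
                for i, b1 in enumerate(barometers):
                    for b2 in barometers[i + 1:]:
                        v1 = [getattr(r, f"{metric}_bands")[b1][band] for r in results]
                        v2 = [getattr(r, f"{metric}_bands")[b2][band] for r in results]
                        t, p = ttest_ind(v1, v2)
                        out["t_tests"].append({
                            "metric": metric, "band": band, "pair": (b1, b2),
                            "t": float(t), "p": float(p),
                            "significant_95": bool(p < 0.05),
                        })
    return out


def summary_table(summary: dict):
    """Barometer x band mean +- SD table as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for metric in ("ncc", "ssim"):
        for b, bands in summary[metric].items():
            for band, e in bands.items():
                rows.append({"metric": metric, "barometer": b, "band": band,
                             "mean_pct": e["mean"], "sd_pct": e["sd"]})
    return pd.DataFrame(rows)
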