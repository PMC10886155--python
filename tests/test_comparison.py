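import numpy as np
import pytest

from orthok.comparison import (CommonGrid, SsimParams, classify_areas,
                               cohort_summary, compare_fields, ncc_full_surface,
                               ncc_map, ncc_zero_lag, normalize_map,
                               resample_to_grid, ssim_map, ComparisonResult)
from orthok.maps import GridMap


def _grid_map(values, mask=None):
    n = values.shape[0]
    ax = np.linspace(-8, 8, n)
    mask = np.ones_like(values, bool) if mask is None else mask
    return GridMap(ax, ax, np.where(mask, values, np.nan), mask)


def _smooth_field(n=161, seed=0):
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    return gaussian_filter(rng.standard_normal((n, n)), 6)


# -- resampling ---------------------------------------------------------------

def test_resample_passthrough_on_grid_nodes():
    grid = CommonGrid.default()
    X, Y = np.meshgrid(grid.x_mm, grid.y_mm)
    vals = np.sin(X / 3) * np.cos(Y / 4)
    out = resample_to_grid(np.column_stack([X.ravel(), Y.ravel()]),
                           vals.ravel(), grid)
    assert np.nanmax(np.abs(out.values - vals)) < 1e-9


def test_resample_reproduces_linear_fields():
    rng = np.random.default_rng(0)
    pts = rng.uniform(-8, 8, size=(4000, 2))
    vals = 2 * pts[:, 0] + 3 * pts[:, 1] + 1
    grid = CommonGrid.default()
    out = resample_to_grid(pts, vals, grid)
    X, Y = np.meshgrid(grid.x_mm, grid.y_mm)
    interior = (np.abs(X) < 7) & (np.abs(Y) < 7) & out.mask
    # exact up to the interpolant's iterative gradient-estimation tolerance
    assert np.abs(out.values[interior] - (2 * X + 3 * Y + 1)[interior]).max() < 1e-6


def test_resample_does_not_extrapolate():
    pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1.0]])
    out = resample_to_grid(pts, np.ones(4), CommonGrid.default())
    assert not out.mask[0, 0]          # far corner outside the hull


def test_resample_needs_three_points():
    with pytest.raises(ValueError, match="3 valid source points"):
        resample_to_grid(np.array([[0, 0], [1, 1.0]]), np.ones(2),
                         CommonGrid.default())


# -- normalisation ------------------------------------------------------------

def test_normalize_scales_sign_preserving():
    gm = _grid_map(np.linspace(-5, 2.5, 161)[:, None].repeat(161, 1))
    out = normalize_map(gm)
    assert np.isclose(np.nanmax(np.abs(out.values)), 1.0)
    assert np.all(np.sign(out.values) == np.sign(gm.values))
    again = normalize_map(out)
    assert np.allclose(again.values, out.values)


def test_normalize_all_zero_warns():
    gm = _grid_map(np.zeros((21, 21)))
    with pytest.warns(UserWarning, match="all-zero"):
        out = normalize_map(gm)
    assert np.all(out.values == 0)


# -- NCC ----------------------------------------------------------------------

def _ncc_direct(t, mt, f, mf, min_overlap=16):
    Nt, Nf = t.shape[0], f.shape[0]
    out = np.full((Nf + Nt - 1, Nf + Nt - 1), np.nan)
    for u in range(-(Nt - 1), Nf):
        for v in range(-(Nt - 1), Nf):
            fs, ts = [], []
            for i in range(Nt):
                for j in range(Nt):
                    fi, fj = u + i, v + j
                    if 0 <= fi < Nf and 0 <= fj < Nf and mt[i, j] and mf[fi, fj]:
                        fs.append(f[fi, fj])
                        ts.append(t[i, j])
            if len(fs) >= min_overlap:
                a = np.array(fs) - np.mean(fs)
                b = np.array(ts) - np.mean(ts)
                den = np.sqrt((a @ a) * (b @ b))
                if den > 1e-12:
                    out[u + Nt - 1, v + Nt - 1] = (a @ b) / den
    return out


def test_ncc_identity_and_negation():
    vals = _smooth_field()
    gm = _grid_map(vals)
    res = ncc_map(gm, gm)
    c = vals.shape[0] // 2
    assert abs(res.map.values[c, c] - 1.0) < 1e-10
    neg = _grid_map(-vals)
    res2 = ncc_map(gm, neg)
    assert abs(res2.map.values[c, c] + 1.0) < 1e-10


def test_ncc_running_sums_match_direct_evaluation():
    rng = np.random.default_rng(1)
    worst = 0.0
    for _ in range(100):
        t = rng.normal(size=(9, 9))
        f = rng.normal(size=(9, 9))
        mt = rng.random((9, 9)) > 0.2
        mf = rng.random((9, 9)) > 0.2
        got, _ = ncc_full_surface(t, mt, f, mf, min_overlap=16)
        want = _ncc_direct(t, mt, f, mf)
        both = np.isfinite(got) & np.isfinite(want)
        worst = max(worst, np.abs(got[both] - want[both]).max())
    assert worst < 1e-10


def test_ncc_invariant_under_positive_affine_rescaling():
    a = _grid_map(_smooth_field(seed=3))
    b = _grid_map(_smooth_field(seed=4))
    base = ncc_map(a, b).map.values
    b2 = b.copy()
    b2.values = 2.5 * b.values + 0.7
    scaled = ncc_map(a, b2).map.values
    both = np.isfinite(base) & np.isfinite(scaled)
    assert np.abs(base[both] - scaled[both]).max() < 1e-9


def test_ncc_rejects_zero_variance_template():
    with pytest.raises(ValueError, match="zero-variance"):
        ncc_map(_grid_map(np.ones((21, 21))), _grid_map(np.ones((21, 21))))


# -- SSIM ---------------------------------------------------------------------

def test_ssim_self_similarity_is_one():
    gm = _grid_map(np.clip(_smooth_field() * 3, -1, 1))
    out = ssim_map(gm, gm)
    assert np.nanmin(out.values) > 1 - 1e-12


def test_ssim_is_symmetric():
    a = _grid_map(np.clip(_smooth_field(seed=5) * 3, -1, 1))
    b = _grid_map(np.clip(_smooth_field(seed=6) * 3, -1, 1))
    assert np.allclose(ssim_map(a, b).values, ssim_map(b, a).values,
                       equal_nan=True)


def test_ssim_constant_offset_hand_evaluation():
    """11x11 constant map vs the same + 0.1: only luminance differs."""
    x = _grid_map(np.zeros((21, 21)))
    y = _grid_map(np.full((21, 21), 0.1))
    out = ssim_map(x, y)
    # after rescaling to [0, 1]: mu_x = 0.5, mu_y = 0.55, sigmas = 0
    p = SsimParams()
    mx, my = 0.5, 0.55
    l = (2 * mx * my + p.C1) / (mx**2 + my**2 + p.C1)
    assert np.allclose(out.values, l, atol=1e-12)


def test_ssim_matches_independent_reference():
    from skimage.metrics import structural_similarity

    rng = np.random.default_rng(9)
    worst = 0.0
    for _ in range(20):
        x = rng.random((64, 64))
        y = np.clip(x + 0.2 * rng.normal(size=(64, 64)), 0, 1)
        gx = GridMap(np.arange(64.0), np.arange(64.0), x * 2 - 1,
                     np.ones((64, 64), bool))
        gy = GridMap(np.arange(64.0), np.arange(64.0), y * 2 - 1,
                     np.ones((64, 64), bool))
        ours = ssim_map(gx, gy).values
        _, ref = structural_similarity(x, y, gaussian_weights=True, sigma=1.5,
                                       use_sample_covariance=False,
                                       data_range=1.0, full=True)
        worst = max(worst, np.abs(ours - ref).max())
    assert worst < 1e-10


def test_ssim_window_larger_than_map_rejected():
    small = _grid_map(np.zeros((5, 5)))
    with pytest.raises(ValueError, match="window larger"):
        ssim_map(small, small)


# -- bands and cohort statistics ---------------------------------------------

@pytest.mark.parametrize("value, band", [(0.5, "moderate"), (0.7, "strong"),
                                         (-0.39, "weak"), (0.4, "moderate"),
                                         (0.6, "strong")])
def test_band_classification_edges(value, band):
    gm = _grid_map(np.full((21, 21), value))
    pct = classify_areas(gm, np.ones((21, 21), bool))
    assert pct[band] == 100.0


def test_band_percentages_sum_to_100_exactly():
    rng = np.random.default_rng(2)
    gm = _grid_map(np.clip(rng.normal(0, 0.5, (161, 161)), -1, 1))
    mask = np.hypot(*np.meshgrid(gm.x_mm, gm.y_mm)) <= 5.5
    pct = classify_areas(gm, mask)
    assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)


def test_empty_mask_rejected():
    gm = _grid_map(np.zeros((21, 21)))
    with pytest.raises(ValueError, match="empty"):
        classify_areas(gm, np.zeros((21, 21), bool))


def _fake_result(vals):
    r = ComparisonResult()
    for b, v in vals.items():
        r.ncc_bands[b] = v
        r.ssim_bands[b] = v
    return r


def test_cohort_summary_statistics():
    rng = np.random.default_rng(0)
    results = []
    for _ in range(6):
        w = rng.uniform(80, 95)
        m = rng.uniform(2, 10)
        results.append(_fake_result({
            "mises": {"weak": w, "moderate": m, "strong": 100 - w - m},
            "pressure": {"weak": w - 1, "moderate": m + 1, "strong": 100 - w - m},
        }))
    s = cohort_summary(results)
    assert s["n"] == 6
    assert set(s["ncc"]) == {"mises", "pressure"}
    assert s["ncc"]["mises"]["weak"]["sd"] > 0
    assert len(s["t_tests"]) > 0


def test_identical_barometers_never_reject():
    results = [_fake_result({
        "a": {"weak": 90.0, "moderate": 6.0, "strong": 4.0},
        "b": {"weak": 90.0, "moderate": 6.0, "strong": 4.0},
    }) for _ in range(5)]
    s = cohort_summary(results)
    assert all(not t["significant_95"] for t in s["t_tests"])


def test_single_result_has_undefined_sd():
    s = cohort_summary([_fake_result({"a": {"weak": 90.0, "moderate": 6.0,
                                            "strong": 4.0}})])
    assert np.isnan(s["ncc"]["a"]["weak"]["sd"])
    assert s["t_tests"] == []


def test_mismatched_barometer_sets_rejected():
    r1 = _fake_result({"a": {"weak": 90.0, "moderate": 6.0, "strong": 4.0}})
    r2 = _fake_result({"b": {"weak": 90.0, "moderate": 6.0, "strong": 4.0}})
    with pytest.raises(ValueError, match="mismatched"):
        cohort_summary([r1, r2])


def test_ks_normality_monte_carlo():
    from orthok.comparison import _lilliefors_p

    rng = np.random.default_rng(77)
    accept = sum(_lilliefors_p(rng.normal(size=200)) > 0.05 for _ in range(100))
    assert accept >= 90


def test_correlated_field_ncc_round_trip():
    from orthok.synthetic import generate_correlated_field

    base = _grid_map(_smooth_field(seed=11))
    mask = np.hypot(*np.meshgrid(base.x_mm, base.y_mm)) <= 5.5
    rpc = GridMap(base.x_mm, base.y_mm, np.where(mask, base.values, np.nan), mask)
    for rho in (-0.9, -0.5, 0.0, 0.5, 0.9):
        fld = generate_correlated_field(rpc, rho, seed=13)
        assert abs(ncc_zero_lag(rpc, fld) - rho) <= 0.05
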