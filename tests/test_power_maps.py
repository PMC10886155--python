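import numpy as np
import pytest

from orthok.maps import PolarMap
from orthok.power_maps import (PowerMapConfig, detect_zones, rpc_map,
                               smooth_map, tangential_curvature_map,
                               tangential_power_map)
from orthok.synthetic import OrthokEffectSpec, apply_orthok_effect
from orthok.topography import TopographyRecord, default_polar_grid
from tests.conftest import sphere_record


def _power_map(record, cfg=None):
    return tangential_power_map(tangential_curvature_map(record, cfg), cfg)


def test_sphere_tangential_radius(sphere75):
    curv = tangential_curvature_map(sphere75)
    assert curv.mask.all()
    assert np.abs(curv.values - 7.5).max() < 1e-4


def test_paraboloid_closed_form():
    az, r = default_polar_grid()
    Rp = 7.8
    elev = -(r**2 / (2 * Rp))[None, :].repeat(az.size, axis=0)
    rec = TopographyRecord(elev, r, az, np.ones_like(elev, dtype=bool))
    curv = tangential_curvature_map(rec)
    truth = Rp * (1 + (r / Rp) ** 2) ** 1.5
    assert np.abs(curv.values - truth[None, :]).max() < 1e-6


def test_short_profiles_marked_invalid_without_raising():
    az, r = default_polar_grid(n_az=8, n_r=20)
    cov = np.zeros((8, 20), dtype=bool)
    cov[0, :2] = True          # 2 valid points: too short
    cov[1, 5:9] = True         # 4 valid points: usable run
    elev = np.where(cov, -(r**2 / 16)[None, :], np.nan)
    rec = TopographyRecord(elev, r, az, cov)
    curv = tangential_curvature_map(rec)
    assert not curv.mask[0].any()
    assert curv.mask[1, 5:9].all()


@pytest.mark.parametrize("rt_mm, power_d", [(7.5, 45.0), (6.75, 50.0)])
def test_reduced_gaussian_optics(rt_mm, power_d, sphere75):
    az, r = default_polar_grid(n_az=4, n_r=5)
    vals = np.full((4, 5), rt_mm)
    curv = PolarMap(az, r, vals, np.ones_like(vals, bool), units="mm")
    power = tangential_power_map(curv)
    assert np.allclose(power.values, power_d, atol=1e-9)


def test_degenerate_index_gives_zero_power():
    az, r = default_polar_grid(n_az=4, n_r=5)
    curv = PolarMap(az, r, np.full((4, 5), 7.5), np.ones((4, 5), bool))
    cfg = PowerMapConfig(nh=1.0)
    power = tangential_power_map(curv, cfg)
    assert np.allclose(power.values, 0.0)


def test_nonpositive_radius_marked_invalid():
    az, r = default_polar_grid(n_az=4, n_r=5)
    vals = np.full((4, 5), 7.5)
    vals[0, 0] = -1.0
    power = tangential_power_map(PolarMap(az, r, vals, np.ones((4, 5), bool)))
    assert not power.mask[0, 0] and power.mask[1:].all()


def test_smoothing_zero_factor_is_identity(sphere75):
    power = _power_map(sphere75)
    out = smooth_map(power, smoothing_factor=0.0)
    assert np.nanmax(np.abs(out.values - power.values)) < 1e-9


def test_smoothing_preserves_constants():
    az, r = default_polar_grid(n_az=40, n_r=60)
    vals = np.full((40, 60), 44.0)
    mask = np.ones_like(vals, bool)
    mask[3, 7] = False
    pm = PolarMap(az, r, np.where(mask, vals, np.nan), mask)
    out = smooth_map(pm)
    assert np.nanmax(np.abs(out.values[mask] - 44.0)) < 1e-9


def test_smoothing_reduces_noise_rms(sphere75):
    clean = _power_map(sphere75)
    wins = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        noisy = clean.copy()
        noisy.values = clean.values + rng.normal(0.0, 0.5, clean.values.shape)
        sm = smooth_map(noisy)
        rms_in = np.sqrt(np.nanmean((noisy.values - clean.values) ** 2))
        rms_out = np.sqrt(np.nanmean((sm.values - clean.values) ** 2))
        wins += rms_out < rms_in
    assert wins == 50


def test_smoothing_is_linear_in_non_robust_mode(sphere75):
    a = _power_map(sphere75)
    rng = np.random.default_rng(1)
    b = a.copy()
    b.values = rng.normal(size=a.values.shape)
    ab = a.copy()
    ab.values = a.values + b.values
    lhs = smooth_map(ab).values
    rhs = smooth_map(a).values + smooth_map(b).values
    scale = np.nanmax(np.abs(ab.values))
    assert np.nanmax(np.abs(lhs - rhs)) < 1e-7 * scale


def test_rpc_identity_uniform_and_antisymmetry(sphere75):
    p = _power_map(sphere75)
    zero = rpc_map(p, p)
    assert np.nanmax(np.abs(zero.values)) == 0.0
    pre = p.copy()
    pre.values = np.full_like(p.values, 44.0)
    post = p.copy()
    post.values = np.full_like(p.values, 41.0)
    d = rpc_map(pre, post)
    assert np.allclose(d.values[d.mask], -3.0)
    assert np.allclose(rpc_map(post, pre).values[d.mask], 3.0)


def test_rpc_grid_mismatch_raises(sphere75):
    p = _power_map(sphere75)
    az, r = default_polar_grid(n_az=10, n_r=12)
    other = PolarMap(az, r, np.zeros((10, 12)), np.ones((10, 12), bool))
    with pytest.raises(ValueError, match="different grids"):
        rpc_map(p, other)


def _rpc_for_effect(record, effect):
    post = apply_orthok_effect(record, effect)
    pre_p = smooth_map(_power_map(record))
    post_p = smooth_map(_power_map(post))
    return rpc_map(pre_p, post_p)


def test_symmetric_effect_centres_at_origin(sphere75):
    rpc = _rpc_for_effect(sphere75, OrthokEffectSpec(central_flattening=-3.0))
    za = detect_zones(rpc)
    assert za.found
    assert np.hypot(*za.decentration) < 0.05


def test_all_positive_rpc_reports_no_treatment_zone(sphere75):
    p = _power_map(sphere75)
    pos = p.copy()
    pos.values = np.abs(p.values) + 1.0
    rpc = rpc_map(p, pos)
    za = detect_zones(rpc)
    assert not za.found


def test_zone_detection_equivariance(sphere75):
    base = OrthokEffectSpec(central_flattening=-3.0, decentration=(0.0, 0.0))
    za0 = detect_zones(_rpc_for_effect(sphere75, base))
    shift = OrthokEffectSpec(central_flattening=-3.0, decentration=(0.6, -0.4))
    za1 = detect_zones(_rpc_for_effect(sphere75, shift))
    dx = za1.decentration[0] - za0.decentration[0]
    dy = za1.decentration[1] - za0.decentration[1]
    assert abs(dx - 0.6) < 0.1 and abs(dy + 0.4) < 0.1
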