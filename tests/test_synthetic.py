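import numpy as np
import pytest

from orthok.eyelid import EyelidBoundary
from orthok.maps import GridMap
from orthok.synthetic import (CohortSpec, OrthokEffectSpec, apply_orthok_effect,
                              generate_correlated_field, generate_coverage_mask,
                              generate_patient, sample_metadata,
                              write_cohort_manifest)
from orthok.topography import default_polar_grid
from orthok.comparison import ncc_zero_lag


def test_same_seed_index_is_bit_identical():
    spec = CohortSpec(n=3, seed=11)
    p1, r1, l1, e1 = generate_patient(spec, 1)
    p2, r2, l2, e2 = generate_patient(spec, 1)
    assert p1 == p2
    assert np.array_equal(r1.elevation, r2.elevation, equal_nan=True)
    assert np.array_equal(r1.coverage, r2.coverage)
    assert l1 == l2 and e1.decentration == e2.decentration
    p3, *_ = generate_patient(CohortSpec(n=3, seed=12), 1)
    assert p3.age != p1.age


def test_zero_sd_pins_metadata_at_means():
    spec = CohortSpec(n=5, seed=0, age_years=(14.1, 0.0), iop_mmhg=(15.0, 0.0),
                      cct_mm=(0.554, 0.0))
    for i in range(5):
        p = sample_metadata(spec, i)
        assert p.age == 14.1 and p.iop == 15.0 and p.cct == 0.554


def test_cct_sample_mean_matches_population():
    spec = CohortSpec(n=1000, seed=7)
    cct = np.array([sample_metadata(spec, i).cct for i in range(1000)])
    se = 0.033 / np.sqrt(1000)
    assert abs(cct.mean() - 0.554) < 3 * se


@pytest.mark.parametrize("bad", [
    dict(n=0), dict(age_years=(14.1, -1.0)), dict(asphericity_convention="x"),
])
def test_invalid_cohort_specs_rejected(bad):
    with pytest.raises(ValueError):
        CohortSpec(**bad)


def test_zero_effect_is_identity(sphere75):
    eff = OrthokEffectSpec(central_flattening=0.0, annulus_steepening=0.0)
    post = apply_orthok_effect(sphere75, eff)
    assert np.array_equal(post.elevation, sphere75.elevation)


def test_effect_conserves_surface_outside_support(sphere75):
    eff = OrthokEffectSpec(central_flattening=-3.0, decentration=(0.4, 0.2))
    post = apply_orthok_effect(sphere75, eff)
    x = sphere75.radii_mm[None, :] * np.cos(np.deg2rad(sphere75.azimuths_deg))[:, None]
    y = sphere75.radii_mm[None, :] * np.sin(np.deg2rad(sphere75.azimuths_deg))[:, None]
    outside = np.hypot(x - 0.4, y - 0.2) > eff.outer_support_mm
    delta = np.abs(post.elevation - sphere75.elevation)[outside]
    assert delta.max() < 1e-4 * 1e-3   # < 0.1 nm, i.e. well under 0.1 um


def test_effect_is_smooth(sphere75):
    eff = OrthokEffectSpec(central_flattening=-3.0)
    post = apply_orthok_effect(sphere75, eff)
    delta = post.elevation[0] - sphere75.elevation[0]
    slope = np.gradient(delta, sphere75.radii_mm)
    jumps = np.abs(np.diff(slope))
    assert jumps.max() < 5e-4          # C1: slope steps vanish with the grid


def test_effect_beyond_measured_radius_rejected(sphere75):
    with pytest.raises(ValueError, match="measured radius"):
        apply_orthok_effect(sphere75, OrthokEffectSpec(annulus_radius=4.8))


def test_central_flattening_hits_power_target(sphere75):
    from orthok.power_maps import (rpc_map, smooth_map,
                                   tangential_curvature_map,
                                   tangential_power_map)

    post = apply_orthok_effect(sphere75, OrthokEffectSpec(central_flattening=-3.0))
    def pmap(rec):
        return smooth_map(tangential_power_map(tangential_curvature_map(rec)))
    rpc = rpc_map(pmap(sphere75), pmap(post))
    centre = float(np.nanmean(rpc.values[:, :5]))
    assert -4.0 < centre < -2.0


def test_no_lid_gives_full_disc():
    az, r = default_polar_grid()
    mask = generate_coverage_mask(None, az, r)
    assert mask.all()
    far = EyelidBoundary((-0.01, 0.0, 40.0), (0.01, 0.0, -40.0))
    mask = generate_coverage_mask(far, az, r, slit_count=0)
    assert mask.all()


def test_zero_slits_is_exact_analytic_region():
    az, r = default_polar_grid()
    lids = EyelidBoundary((-0.0832, -0.0262, 3.5809), (0.0842, 0.0163, -3.9734))
    mask = generate_coverage_mask(lids, az, r, slit_count=0)
    th = np.deg2rad(az)[:, None]
    x, y = r[None, :] * np.cos(th), r[None, :] * np.sin(th)
    expect = (y < lids.upper_y(x)) & (y > lids.lower_y(x)) & (np.hypot(x, y) <= r[-1] + 1e-12)
    assert np.array_equal(mask, expect)


def test_slits_are_seeded_and_near_lid_edges():
    az, r = default_polar_grid()
    lids = EyelidBoundary((-0.0832, -0.0262, 3.5809), (0.0842, 0.0163, -3.9734))
    m0 = generate_coverage_mask(lids, az, r, slit_count=0)
    rng = np.random.default_rng(5)
    m1 = generate_coverage_mask(lids, az, r, slit_count=6,
                                rng=np.random.default_rng(5))
    m2 = generate_coverage_mask(lids, az, r, slit_count=6,
                                rng=np.random.default_rng(5))
    assert np.array_equal(m1, m2)
    assert (m0 & ~m1).sum() > 0          # slits removed samples
    assert not (~m0 & m1).any()          # and only removed


def test_aperture_missing_disc_raises():
    az, _ = default_polar_grid()
    # aperture pinches closed for |x| > 1, entirely inside the 2 mm hole
    lids = EyelidBoundary((-0.5, 0.0, 0.5), (0.5, 0.0, -0.5))
    with pytest.raises(ValueError, match="no aperture"):
        generate_coverage_mask(lids, az, np.linspace(2.0, 4.98, 100))


def _rpc_like_map():
    x, _ = np.linspace(-8, 8, 161), None
    ax = np.linspace(-8, 8, 161)
    X, Y = np.meshgrid(ax, ax)
    m = np.hypot(X, Y) <= 5.5
    base = -3 * np.exp(-(X**2 + Y**2) / 4) + 1.2 * np.exp(-((np.hypot(X, Y) - 2.8) / 0.8) ** 2)
    return GridMap(ax, ax, np.where(m, base, np.nan), m)


@pytest.mark.parametrize("rho", [1.0, -1.0])
def test_correlated_field_exact_extremes(rho):
    rpc = _rpc_like_map()
    fld = generate_correlated_field(rpc, rho, seed=3)
    assert abs(ncc_zero_lag(rpc, fld) - rho) < 1e-6


def test_correlated_field_monte_carlo_mean():
    rpc = _rpc_like_map()
    vals = [ncc_zero_lag(rpc, generate_correlated_field(rpc, 0.5, seed=s))
            for s in range(50)]
    assert abs(np.mean(vals) - 0.5) < 0.03


def test_correlated_field_rejects_constant_map():
    ax = np.linspace(-8, 8, 161)
    m = np.ones((161, 161), bool)
    rpc = GridMap(ax, ax, np.ones((161, 161)), m)
    with pytest.raises(ValueError, match="constant"):
        generate_correlated_field(rpc, 0.5, seed=1)


def test_generated_surfaces_are_star_shaped():
    from orthok.topography import extend_surface

    spec = CohortSpec(n=2, seed=21)
    for i in range(2):
        _, rec, _, _ = generate_patient(spec, i)
        radial = extend_surface(rec).to_radial()
        pts = rec.points()[::97]
        assert np.abs(radial.signed_gap(pts)).max() < 2e-3


def test_cohort_manifest(tmp_path):
    import pandas as pd

    spec = CohortSpec(n=3, seed=2)
    write_cohort_manifest(spec, tmp_path / "manifest.csv")
    df = pd.read_csv(tmp_path / "manifest.csv")
    assert len(df) == 3
    for col in ("id", "age", "iop", "cct", "eye", "lens_base_radius",
                "true_decentration_x", "true_decentration_y"):
        assert col in df.columns
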