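import numpy as np
import pytest

from orthok.topography import (TopographyFormatError, TopographyRecord,
                               cartesian_to_polar, default_polar_grid,
                               extend_surface, polar_to_cartesian,
                               read_topography, to_right_eye_frame,
                               write_topography, zernike_fit)
from tests.conftest import sphere_record


def _gappy_record():
    az, r = default_polar_grid()
    rng = np.random.default_rng(3)
    elev = -(7.7 - np.sqrt(7.7**2 - r**2))[None, :].repeat(az.size, axis=0)
    cov = rng.random(elev.shape) > 0.1
    return TopographyRecord(np.where(cov, elev, np.nan), r, az, cov,
                            eye="left", exam_date="2023-05-04",
                            simk_flat_d=43.1, simk_steep_d=44.2,
                            flat_angle_deg=12.0, steep_angle_deg=102.0)


def test_write_read_roundtrip_is_lossless(tmp_path):
    rec = _gappy_record()
    path = tmp_path / "case.topo"
    write_topography(rec, path)
    back = read_topography(path)
    assert np.array_equal(rec.elevation[rec.coverage], back.elevation[back.coverage])
    assert np.array_equal(rec.coverage, back.coverage)
    assert np.array_equal(rec.radii_mm, back.radii_mm)
    assert np.array_equal(rec.azimuths_deg, back.azimuths_deg)
    assert back.eye == "left" and back.exam_date == "2023-05-04"
    assert back.simk_flat_d == 43.1 and back.steep_angle_deg == 102.0


def test_default_grid_extents(tmp_path):
    rec = sphere_record()
    path = tmp_path / "g.topo"
    write_topography(rec, path)
    back = read_topography(path)
    assert back.n_az == 300 and back.n_r == 333


@pytest.mark.parametrize("mutate, message", [
    (lambda lines: lines[: lines.index("COVERAGE")], "missing COVERAGE"),
    (lambda lines: [ln.replace("ELEVATION", "ELEVATIO") for ln in lines],
     "missing ELEVATION"),
])
def test_truncated_file_names_missing_section(tmp_path, mutate, message):
    rec = sphere_record()
    path = tmp_path / "t.topo"
    write_topography(rec, path)
    lines = path.read_text().splitlines()
    path.write_text("\n".join(mutate(lines)) + "\n")
    with pytest.raises(TopographyFormatError, match=message):
        read_topography(path)


def test_unparseable_number_diagnostic(tmp_path):
    rec = sphere_record()
    path = tmp_path / "u.topo"
    write_topography(rec, path)
    lines = path.read_text().splitlines()
    i = lines.index("RADII") + 1
    lines[i] = lines[i].replace(lines[i].split()[5], "oops", 1)
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(TopographyFormatError, match="unparseable number in RADII"):
        read_topography(path)


def test_non_monotone_radii_rejected():
    az, r = default_polar_grid()
    r = r.copy()
    r[5] = r[4]
    elev = np.zeros((az.size, r.size))
    with pytest.raises(TopographyFormatError, match="strictly increasing"):
        TopographyRecord(elev, r, az, np.ones_like(elev, dtype=bool))


def test_dimension_mismatch_rejected():
    az, r = default_polar_grid()
    with pytest.raises(TopographyFormatError, match="elevation block"):
        TopographyRecord(np.zeros((10, 10)), r, az, np.ones((10, 10), bool))


def test_polar_cartesian_roundtrip():
    az, r = default_polar_grid()
    x, y = polar_to_cartesian(az, r)
    az2, r2 = cartesian_to_polar(x, y)
    r_err = np.abs(r2 - r[None, :]).max()
    az_err = np.abs((az2[:, 1:] - az[:, None]) % 360).max()
    assert r_err < 1e-9
    assert min(az_err, 360 - az_err) < 1e-9


def test_left_eye_mirroring_flips_x():
    rec = _gappy_record()
    mirrored = to_right_eye_frame(rec)
    x, _ = polar_to_cartesian(rec.azimuths_deg, rec.radii_mm)
    # pick a covered sample and find its mirror partner
    i, j = 40, 200
    target = (180.0 - rec.azimuths_deg[i]) % 360.0
    i2 = int(np.argmin(np.abs(mirrored.azimuths_deg - target)))
    assert mirrored.elevation[i2, j] == rec.elevation[i, j] or (
        np.isnan(mirrored.elevation[i2, j]) and np.isnan(rec.elevation[i, j]))
    # right-eye records pass through unchanged
    rec_r = sphere_record()
    same = to_right_eye_frame(rec_r)
    assert np.array_equal(same.elevation, rec_r.elevation)


def test_plane_extends_to_plane():
    az, r = default_polar_grid()
    elev = np.zeros((az.size, r.size))
    rec = TopographyRecord(elev, r, az, np.ones_like(elev, dtype=bool))
    ext = extend_surface(rec, scleral_radius_mm=50.0)
    inner = ext.radii_mm <= 5.5
    assert np.abs(ext.elevation[:, inner]).max() < 1e-9


def test_measured_samples_kept_verbatim():
    rec = _gappy_record()
    ext = extend_surface(rec)
    meas = ext.elevation[:, : rec.n_r]
    assert np.array_equal(meas[rec.coverage], rec.elevation[rec.coverage])


def test_sphere_annulus_error_below_cubic_fit_residual(sphere78):
    """Order-3 extrapolation error stays within the cubic LSQ residual.

    The oracle is an independent least-squares fit of the same sphere with
    all monomials x^i y^j of total order <= 3 (the same function space as
    the Zernike basis).
    """
    R = 7.8
    rec = sphere78
    ext = extend_surface(rec)
    rz = ext.radii_mm
    zone = (rz > rec.radii_mm[-1]) & (rz <= 5.5)
    true = -(R - np.sqrt(R**2 - rz[zone] ** 2))
    ours = np.abs(ext.elevation[:, zone] - true[None, :]).max()

    pts = rec.points()
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    cols = [x**i * y**j for i in range(4) for j in range(4 - i)]
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    az = rec.azimuths_deg
    th = np.deg2rad(az)[:, None]
    xa = rz[zone][None, :] * np.cos(th)
    ya = rz[zone][None, :] * np.sin(th)
    Aq = np.column_stack([(xa**i * ya**j).ravel() for i in range(4) for j in range(4 - i)])
    oracle = np.abs((Aq @ coef).reshape(xa.shape) - true[None, :]).max()
    assert ours <= oracle * 1.05


def test_extension_reaches_model_rim(toric_record):
    ext = extend_surface(toric_record)
    assert ext.radii_mm[-1] >= 8.0
    assert set(np.unique(ext.provenance)) <= {0, 1, 2}
    assert (ext.provenance[:, ext.radii_mm > 5.5] == 2).all()


def test_extend_is_idempotent_within_fit_radius(sphere78):
    ext = extend_surface(sphere78)
    keep = ext.radii_mm <= 4.98
    rec2 = TopographyRecord(ext.elevation[:, keep], ext.radii_mm[keep],
                            ext.azimuths_deg,
                            np.ones((ext.azimuths_deg.size, keep.sum()), bool))
    ext2 = extend_surface(rec2)
    inner = ext2.radii_mm <= 5.5
    ref = np.interp(ext2.radii_mm[inner], ext.radii_mm, ext.elevation[0])
    assert np.abs(ext2.elevation[0, inner] - ref).max() < 5e-3
    assert np.array_equal(ext2.elevation[:, keep], ext.elevation[:, keep])


def test_too_few_points_refuses_extrapolation():
    az, r = default_polar_grid()
    cov = np.zeros((az.size, r.size), bool)
    cov[:2, :10] = True
    elev = np.where(cov, 0.0, np.nan)
    rec = TopographyRecord(elev, r, az, cov)
    with pytest.raises(ValueError, match="Zernike"):
        extend_surface(rec)
    with pytest.raises(ValueError, match="valid points"):
        zernike_fit(rec.points(), 5.5)


def test_radial_surface_star_shape_and_closest_points(toric_radial):
    pts = sphere_record(7.7).points()[:: 531]
    # points on a different surface project to finite feet; points taken
    # from the surface itself are their own closest points
    on_surface = toric_radial.point(np.array([10.0, 80.0, 200.0]),
                                    np.array([0.2, 0.4, 0.6]))
    feet = toric_radial.closest_points(on_surface)
    assert np.abs(feet - on_surface).max() < 1e-6
    gaps = toric_radial.signed_gap(on_surface)
    assert np.abs(gaps).max() < 1e-6


def test_exports_write_text_artifacts(tmp_path, sphere78):
    ext = extend_surface(sphere78)
    ext.to_xyz_csv(tmp_path / "cloud.csv")
    ext.to_ply(tmp_path / "cloud.ply")
    head = (tmp_path / "cloud.csv").read_text().splitlines()
    assert head[0] == "x_mm,y_mm,z_mm,provenance"
    assert "measured" in head[1]
    ply = (tmp_path / "cloud.ply").read_text().splitlines()
    assert ply[0] == "ply"
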