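import numpy as np
import pytest

from orthok.meshing import default_lens_design
from orthok.topography import TopographyRecord, default_polar_grid, extend_surface


def sphere_record(R: float = 7.5) -> TopographyRecord:
    az, r = default_polar_grid()
    elev = -(R - np.sqrt(R**2 - r**2))[None, :].repeat(az.size, axis=0)
    return TopographyRecord(elev, r, az, np.ones_like(elev, dtype=bool),
                            simk_flat_d=337.5 / R, simk_steep_d=337.5 / R)


@pytest.fixture(scope="session")
def sphere75():
    return sphere_record(7.5)


@pytest.fixture(scope="session")
def sphere78():
    return sphere_record(7.8)


@pytest.fixture(scope="session")
def toric_record():
    from orthok.synthetic import conicoid_elevation

    az, r = default_polar_grid()
    elev = conicoid_elevation(az, r, 42.6, 44.0, 0.0, -0.66, -0.40)
    return TopographyRecord(elev, r, az, np.ones_like(elev, dtype=bool),
                            simk_flat_d=42.6, simk_steep_d=44.0)


@pytest.fixture(scope="session")
def toric_radial(toric_record):
    return extend_surface(toric_record).to_radial()


@pytest.fixture(scope="session")
def lens_design():
    return default_lens_design()


@pytest.fixture(scope="session")
def lens_mesh(lens_design):
    from orthok.meshing import build_lens_mesh

    return build_lens_mesh(lens_design)


@pytest.fixture(scope="session")
def congruent_surface(lens_design):
    """Anterior surface congruent with the lens back (seating ground truth)."""
    from orthok.meshing import build_lens_profile

    prof = build_lens_profile(lens_design)
    az, r = default_polar_grid(n_r=333, r_max=lens_design.diameter / 2 - 0.02)
    zb = prof.back_at(r)
    zb = zb - zb[0]
    rec = TopographyRecord(zb[None, :].repeat(az.size, axis=0), r, az,
                           np.ones((az.size, r.size), dtype=bool))
    return extend_surface(rec).to_radial()
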