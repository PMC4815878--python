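"""Shared fixtures: a small detector, canonical shapes, and the built-in
shape database. Heavy synthetic datasets are session-scoped so several
tests can share one simulation."""

import numpy as np
import pytest

from vsaxs import profiles as P
from vsaxs import shapedb as S
from vsaxs import simulate as sim


@pytest.fixture(scope="session")
def geo64():
    """64 px detector covering the same q range as the documented default
    (lambda 0.2 nm, D 4 m): q up to ~0.25 nm^-1 at the edge."""
    c = 31.5
    return sim.DetectorGeometry(wavelength_nm=0.2, distance_mm=4000.0,
                                pixel_mm=1.0, n_fast=64, n_slow=64,
                                beam_center=(c, c))


@pytest.fixture(scope="session")
def geo128():
    c = 63.5
    return sim.DetectorGeometry(wavelength_nm=0.2, distance_mm=4000.0,
                                pixel_mm=0.5, n_fast=128, n_slow=128,
                                beam_center=(c, c))


@pytest.fixture(scope="session")
def sphere10():
    """Coarse 10 nm sphere for pattern-level tests (exact Debye path)."""
    return sim.make_shape("sphere", radius=10.0, spacing=1.1)


@pytest.fixture(scope="session")
def prolate_nanorice():
    """Bead model of a 135 x 68 nm prolate particle."""
    return sim.make_shape("prolate", semi_axes=(67.5, 34.0), spacing=8.0)


@pytest.fixture(scope="session")
def dumbbell91():
    """Two touching 91 nm spheres."""
    return sim.make_shape("dumbbell", radius=91.0, separation=182.0,
                          spacing=16.0)


@pytest.fixture(scope="session")
def preset_db():
    """The built-in 12-model database (5 shape kinds)."""
    return S.build_database(S.default_shape_set(), s_max=50.0, n_s=512)


@pytest.fixture(scope="session")
def q_bins64(geo64):
    return P.default_q_bins(geo64, n_bins=150)


@pytest.fixture(scope="session")
def prolate_profiles(prolate_nanorice, geo64, q_bins64):
    """500 Poisson-noised single-pattern profiles of the prolate particle."""
    pats, _ = sim.simulate_dataset(prolate_nanorice, geo64, 500, 5000.0,
                                   seed=21)
    return [P.azimuthal_integrate(p, q_bins=q_bins64) for p in pats]


@pytest.fixture(scope="session")
def dumbbell_profiles(dumbbell91, geo64, q_bins64):
    """500 Poisson-noised single-pattern profiles of the dumbbell."""
    pats, _ = sim.simulate_dataset(dumbbell91, geo64, 500, 5000.0, seed=22)
    return [P.azimuthal_integrate(p, q_bins=q_bins64) for p in pats]
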