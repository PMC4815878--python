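"""Shape construction, orientation sampling, Ewald-sphere geometry and
pattern simulation."""

import numpy as np
import pytest

from vsaxs import models as M
from vsaxs import profiles as P
from vsaxs import simulate as sim
from vsaxs.errors import InvalidInputError


# ---------------------------------------------------------------------------
# make_shape
# ---------------------------------------------------------------------------

class TestMakeShape:
    def test_sphere_bead_count_matches_lattice_enumeration(self):
        # oracle: enumerate integer lattice points with |x| <= R
        R, sp = 10.0, 1.0
        n = int(R / sp)
        count = sum(1 for i in range(-n, n + 1) for j in range(-n, n + 1)
                    for k in range(-n, n + 1)
                    if (i * i + j * j + k * k) * sp * sp <= R * R + 1e-12)
        m = sim.make_shape("sphere", radius=R, spacing=sp)
        assert m.n_beads == count
        # volume matching keeps every bead inside ~R
        assert np.linalg.norm(m.centers, axis=1).max() <= R * 1.01

    def test_dumbbell_mirror_symmetric_and_centered(self):
        m = sim.make_shape("dumbbell", radius=45.5, separation=91.0, spacing=6.0)
        assert np.allclose(m.centroid, 0.0, atol=1e-9)
        # mirror through the yz plane maps the bead set onto itself
        mirrored = m.centers * np.array([-1.0, 1.0, 1.0])
        a = set(map(tuple, np.round(m.centers, 6)))
        b = set(map(tuple, np.round(mirrored, 6)))
        assert a == b

    def test_prolate_long_axis_extent(self):
        sp = 2.0
        m = sim.make_shape("prolate", semi_axes=(67.5, 34.0), spacing=sp)
        # physical extent: bead-center span plus one bead diameter
        extent = (m.centers[:, 0].max() - m.centers[:, 0].min()
                  + 2 * m.bead_radius)
        assert abs(extent - 135.0) <= sp  # within one lattice spacing

    def test_cube_fill(self):
        m = sim.make_shape("cube", edge=8.0, spacing=1.0)
        assert m.n_beads == 9**3

    @pytest.mark.parametrize("kwargs", [
        dict(kind="sphere", radius=-1.0),
        dict(kind="prolate", semi_axes=(1.0, 2.0)),      # a < b
        dict(kind="dumbbell", radius=0.0, separation=1.0),
        dict(kind="cube", edge=-3.0),
        dict(kind="nonagon"),
    ])
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(InvalidInputError):
            sim.make_shape(**kwargs)

    def test_absurd_dumbbell_separation_warns_not_errors(self):
        with pytest.warns(UserWarning):
            m = sim.make_shape("dumbbell", radius=1.0, separation=25.0,
                               spacing=0.4)
        assert m.n_beads > 0


# ---------------------------------------------------------------------------
# orientations
# ---------------------------------------------------------------------------

class TestOrientations:
    def test_seeded_stream_reproducible(self):
        a = sim.random_orientations(np.random.default_rng(5), 10)
        b = sim.random_orientations(np.random.default_rng(5), 10)
        assert np.array_equal(a, b)

    def test_unit_norm(self):
        q = sim.random_orientations(np.random.default_rng(0), 1000)
        assert np.allclose(np.linalg.norm(q, axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("sampler", [
        lambda n: sim.random_orientations(np.random.default_rng(3), n),
        sim.uniform_orientation_set,
    ])
    def test_mean_rotation_matrix_vanishes(self, sampler):
        # Haar-uniform rotations average to the zero matrix
        n = 10_000
        quats = sampler(n)
        mean = np.zeros((3, 3))
        for q in quats:
            mean += sim.quaternion_to_matrix(q)
        mean /= n
        assert np.abs(mean).max() < 3.0 / np.sqrt(n)


# ---------------------------------------------------------------------------
# pixel q vectors
# ---------------------------------------------------------------------------

class TestPixelQ:
    def test_beam_center_pixel_is_q_zero(self):
        geo = sim.DetectorGeometry(0.2, 100.0, 0.1, 21, 21, (10, 10))
        assert np.allclose(sim.pixel_q_vector(geo, (10, 10)), 0.0)

    def test_trigonometric_oracle(self):
        # lambda = 0.2 nm, D = 100 mm, radial offset 7.0 mm
        geo = sim.DetectorGeometry(0.2, 100.0, 0.7, 21, 21, (10, 10))
        q = sim.pixel_q_vector(geo, (10, 20))  # 10 px * 0.7 mm = 7 mm along x
        alpha = np.arctan(0.070)
        expected = (4 * np.pi / 0.2) * np.sin(alpha / 2)
        assert np.isclose(np.linalg.norm(q), expected, rtol=1e-12)

    def test_friedel_partner_has_negated_inplane_components(self):
        geo = sim.DetectorGeometry(0.15, 500.0, 0.5, 33, 33, (16, 16))
        q1 = sim.pixel_q_vector(geo, (4, 25))
        q2 = sim.pixel_q_vector(geo, (2 * 16 - 4, 2 * 16 - 25))
        assert np.allclose(q1[:2], -q2[:2], atol=1e-12)
        assert np.isclose(np.linalg.norm(q1), np.linalg.norm(q2))

    def test_magnitude_consistent_with_vectors(self, geo64):
        qv = geo64.pixel_q_vectors()
        qm = geo64.pixel_q_magnitudes()
        assert np.allclose(np.linalg.norm(qv, axis=-1), qm, atol=1e-12)


# ---------------------------------------------------------------------------
# pattern simulation
# ---------------------------------------------------------------------------

class TestSimulatePattern:
    def test_zero_fluence_gives_zero_counts(self, sphere10, geo64):
        rng = np.random.default_rng(0)
        pat = sim.simulate_pattern(sphere10, geo64,
                                   sim.random_orientation(rng), 0.0, rng=rng)
        assert pat.counts[pat.valid].sum() == 0

    def test_forward_scattering_equals_fluence(self, geo64):
        # geometry with the beam center exactly on a pixel: q = 0 there
        geo = sim.DetectorGeometry(0.2, 4000.0, 1.0, 33, 33, (16, 16))
        m = sim.make_shape("dumbbell", radius=5.0, separation=8.0, spacing=1.0)
        pat = sim.simulate_pattern(m, geo,
                                   sim.random_orientation(np.random.default_rng(1)),
                                   123.0, poisson=False)
        assert np.isclose(pat.counts[16, 16], 123.0, rtol=1e-9)

    def test_sphere_intensity_orientation_invariant(self, sphere10, geo64):
        rng = np.random.default_rng(2)
        ref = sim.simulate_pattern(sphere10, geo64, np.array([1.0, 0, 0, 0]),
                                   1.0, poisson=False)
        pix = rng.integers(0, 64, size=(20, 2))
        for _ in range(3):
            pat = sim.simulate_pattern(sphere10, geo64,
                                       sim.random_orientation(rng), 1.0,
                                       poisson=False)
            a = pat.counts[pix[:, 0], pix[:, 1]]
            b = ref.counts[pix[:, 0], pix[:, 1]]
            # single-precision phase sums bound the attainable agreement
            assert np.allclose(a, b, rtol=5e-3, atol=1e-6)

    def test_friedel_symmetry_of_noiseless_pattern(self):
        # on-grid beam center: reflection maps pixel grid onto itself
        geo = sim.DetectorGeometry(0.2, 4000.0, 1.0, 33, 33, (16, 16))
        m = sim.make_shape("prolate", semi_axes=(40.0, 20.0), spacing=5.0)
        pat = sim.simulate_pattern(m, geo,
                                   sim.random_orientation(np.random.default_rng(4)),
                                   1.0, poisson=False)
        I = pat.counts
        # symmetric up to single-precision phase noise and the residual
        # Ewald curvature (the partner pixel keeps +q_z), which matters
        # only where the intensity is a tiny fraction of the peak
        assert np.allclose(I, I[::-1, ::-1], rtol=1e-2, atol=1e-3 * I.max())

    def test_poisson_counts_conserved_in_expectation(self, sphere10, geo64):
        rng = np.random.default_rng(9)
        quat = sim.random_orientation(rng)
        noiseless = sim.simulate_pattern(sphere10, geo64, quat, 500.0,
                                         poisson=False).counts
        n_rep = 300
        acc = np.zeros_like(noiseless)
        for _ in range(n_rep):
            acc += sim.simulate_pattern(sphere10, geo64, quat, 500.0,
                                        rng=rng).counts
        mean = acc / n_rep
        se = np.sqrt(np.maximum(noiseless, 1e-12) / n_rep)
        z = np.abs(mean - noiseless) / np.maximum(se, 1e-12)
        # 4-sigma outliers should be at the few-per-ten-thousand level
        assert (z > 4).mean() < 5e-3

    def test_empty_model_rejected(self, geo64):
        with pytest.raises(InvalidInputError):
            sim.BeadModel(np.empty((0, 3)), 1.0)


class TestOrientationAveraging:
    def test_merged_profiles_converge_to_debye(self, prolate_nanorice, geo64,
                                               q_bins64):
        """Summed intensity profiles over quasi-uniform orientations form the
        model's SAXS profile (the spherically averaged Debye curve)."""
        m = prolate_nanorice
        quats = sim.uniform_orientation_set(2000)
        singles = [P.azimuthal_integrate(
            sim.simulate_pattern(m, geo64, qt, 1.0, poisson=False),
            q_bins=q_bins64) for qt in quats]
        cum = P.accumulate(singles)
        v = cum.valid
        # discretization-aware oracle: within-bin pixel mean of the Debye curve
        qmag = geo64.pixel_q_magnitudes()[geo64.mask]
        idx = np.digitize(qmag, q_bins64) - 1
        inside = (idx >= 0) & (idx < len(q_bins64) - 1)
        Ipix = M.debye_profile(m, qmag[inside], histogram_bins=8000)
        nb = len(q_bins64) - 1
        npx = np.bincount(idx[inside], minlength=nb)
        oracle = np.bincount(idx[inside], weights=Ipix,
                             minlength=nb) / np.maximum(npx, 1)
        Ie = cum.I[v] / cum.n_patterns * m.weights.sum() ** 2
        Io = oracle[v]
        imin = np.argmin(Io[:int(0.7 * len(Io))])  # first minimum
        rel = np.abs(Ie - Io) / Io
        assert rel[:imin].max() < 0.02


# ---------------------------------------------------------------------------
# dataset generation and HDF5 round trip
# ---------------------------------------------------------------------------

class TestSimulateDataset:
    def test_zero_rate_flags_nothing(self, geo64):
        m = sim.make_shape("sphere", radius=20.0, spacing=4.0)
        _, man = sim.simulate_dataset(m, geo64, 20, 100.0, seed=0)
        assert man.false_positive.sum() == 0

    def test_false_positive_count_in_binomial_interval(self, geo64):
        m = sim.make_shape("sphere", radius=20.0, spacing=5.0)
        fp = sim.make_shape("sphere", radius=50.0, spacing=12.0)
        _, man = sim.simulate_dataset(m, geo64, 1000, 0.0,
                                      false_positive_rate=0.1,
                                      false_positive_model=fp, seed=3)
        assert 73 <= man.false_positive.sum() <= 128  # binomial 99% interval

    def test_center_jitter_recorded_and_bounded(self, geo64):
        m = sim.make_shape("sphere", radius=20.0, spacing=5.0)
        _, man = sim.simulate_dataset(m, geo64, 30, 10.0,
                                      center_jitter_px=2.0, seed=4)
        assert np.abs(man.center_offset).max() <= 2.0
        assert np.abs(man.center_offset).max() > 0

    def test_hdf5_round_trip_bit_exact(self, geo64, tmp_path):
        m = sim.make_shape("sphere", radius=20.0, spacing=5.0)
        pats, man = sim.simulate_dataset(m, geo64, 5, 200.0,
                                         center_jitter_px=1.0, seed=5)
        path = tmp_path / "pats.h5"
        sim.save_patterns(path, pats, man)
        pats2, man2 = sim.load_patterns(path)
        assert len(pats2) == 5
        for a, b in zip(pats, pats2):
            assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(man.orientations, man2.orientations)
        assert np.array_equal(man.false_positive, man2.false_positive)
        assert np.array_equal(man.center_offset, man2.center_offset)
        assert man2.seed == 5

    def test_bad_inputs(self, geo64):
        m = sim.make_shape("sphere", radius=20.0, spacing=5.0)
        with pytest.raises(InvalidInputError):
            sim.simulate_dataset(m, geo64, 0, 1.0)
        with pytest.raises(InvalidInputError):
            sim.simulate_dataset(m, geo64, 5, 1.0, false_positive_rate=1.5)
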