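import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circpop import spiking
from circpop.decoders import (
    GridSpec,
    MLObjective,
    circular_error,
    ml_decode,
    ml_decode_conj,
    ml_decode_gaussian_nc,
    ml_decode_pure,
    pv_decode,
)
from circpop.tuning import Population, build_population


def naive_loglik_1d(phi, counts, prefs, kappa, R, T):
    """Independent reference implementation of the per-dimension objective."""
    return np.sum(
        counts * kappa * np.cos(phi - prefs)
        - T * R * np.exp(kappa * (np.cos(phi - prefs) - 1.0))
    )


def brute_force_1d(counts, prefs, kappa, R, T, step_deg=0.1):
    grid = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    vals = [naive_loglik_1d(p, counts, prefs, kappa, R, T) for p in grid]
    return grid[int(np.argmax(vals))]


def naive_loglik_2d(phi, theta, counts, pref_az, pref_pi, kappa, R, T):
    return np.sum(
        counts * kappa * (np.cos(phi - pref_az) + np.cos(theta - pref_pi))
        - T * R * np.exp(kappa * (np.cos(phi - pref_az) + np.cos(theta - pref_pi) - 2.0))
    )


class TestCircularError:
    def test_exact_match(self):
        e, s = circular_error([1.0, 2.0], [1.0, 2.0])
        np.testing.assert_allclose(e, 0.0)
        assert s == 0.0

    def test_wraparound(self):
        e, s = circular_error(np.deg2rad([350.0]), np.deg2rad([10.0]))
        assert e[0] == pytest.approx(-20.0)
        e, _ = circular_error(np.deg2rad([10.0]), np.deg2rad([350.0]))
        assert e[0] == pytest.approx(20.0)

    def test_scalar_combination(self):
        _, s = circular_error(np.deg2rad([90.0, 90.0]), np.deg2rad([0.0, 0.0]))
        assert s == pytest.approx(np.sqrt(2) * 90.0, abs=0.01)

    @given(st.floats(0, 2 * np.pi), st.floats(0, 2 * np.pi))
    @settings(max_examples=50)
    def test_bounded_by_180(self, a, b):
        e, _ = circular_error([a], [b])
        assert abs(e[0]) <= 180.0 + 1e-9


class TestMLPure:
    def test_noiseless_consistency(self, rng):
        pop = build_population(2000, "pure", D=2, kappa=9.11, rng=rng)
        stim = np.array([1.3, 4.2])
        counts = np.round(pop.rates(stim) * 50.0).astype(int)  # near-expected
        mat = spiking.SpikeCountMatrix(counts[None, :], stim, 50.0, "independent")
        res = ml_decode_pure(mat, pop)
        assert res.scalar_error_deg[0] < 1.0

    def test_single_neuron_single_spike(self):
        pref = 0.8
        pop = Population(
            preferred=np.array([[pref, 0.0]]),
            kappa=np.full((1, 2), 9.11),
            tuned=np.array([[True, False]]),
            peak_rate=np.array([1.0]),
            baseline_rate=np.zeros(1),
            kind="pure",
            D=2,
        )
        mat = spiking.SpikeCountMatrix(np.array([[1]]), np.array([0.8, 0.0]), 0.1, "independent")
        res = ml_decode(mat, pop)
        # the lone tuned dimension estimates at the preferred direction;
        # brute-force confirmation
        bf = brute_force_1d(np.array([1]), np.array([pref]), 9.11, 1.0, 0.1)
        assert res.estimates[0, 0] == pytest.approx(pref, abs=np.deg2rad(0.2))
        assert bf == pytest.approx(pref, abs=np.deg2rad(0.2))
        # untuned dimension is degenerate
        assert res.degenerate[0, 1]

    def test_against_brute_force(self, rng):
        pop = build_population(20, "pure", D=2, kappa=2.37, rng=rng)
        T = 0.8
        errs = []
        for _ in range(25):
            stim = rng.uniform(0, 2 * np.pi, 2)
            mat = spiking.sample_independent(pop, stim, T, 1, rng=rng)
            res = ml_decode_pure(mat, pop)
            for d in range(2):
                idx = np.flatnonzero(pop.tuned[:, d])
                if mat.counts[0, idx].sum() == 0:
                    continue
                bf = brute_force_1d(
                    mat.counts[0, idx], pop.preferred[idx, d], 2.37, 1.0, T
                )
                diff, _ = circular_error([res.estimates[0, d]], [bf])
                errs.append(abs(diff[0]))
        assert errs and max(errs) < 0.2  # within brute-force resolution

    def test_zero_spike_subpopulation_degenerate(self, rng):
        pop = build_population(4, "pure", D=2, kappa=9.11, rng=rng)
        counts = np.zeros((1, 4), dtype=int)
        counts[0, 0] = 3  # azimuth cells fire, pitch silent
        mat = spiking.SpikeCountMatrix(counts, np.zeros(2), 0.1, "independent")
        res = ml_decode_pure(mat, pop)
        assert not res.degenerate[0, 0]
        assert res.degenerate[0, 1]
        assert res.errors_deg[0, 1] == pytest.approx(180.0)

    def test_requires_pure(self, rng):
        pop = build_population(10, "conjunctive", D=2, rng=rng)
        mat = spiking.sample_independent(pop, [0, 0], 1.0, 1, rng=rng)
        with pytest.raises(ValueError):
            ml_decode_pure(mat, pop)


class TestMLConj:
    def test_against_brute_force(self, rng):
        pop = build_population(12, "conjunctive", D=2, kappa=2.37,
                               scheme="explicit", R_pure=1.0, rng=rng)
        T = 1.0
        grid = np.deg2rad(np.arange(0.0, 360.0, 1.0))
        for _ in range(6):
            stim = rng.uniform(0, 2 * np.pi, 2)
            mat = spiking.sample_independent(pop, stim, T, 1, rng=rng)
            if mat.counts.sum() == 0:
                continue
            res = ml_decode_conj(mat, pop)
            # 1 deg brute force over the full torus
            best, bval = None, -np.inf
            for p in grid:
                vals = [
                    naive_loglik_2d(
                        p, t, mat.counts[0], pop.preferred[:, 0],
                        pop.preferred[:, 1], 2.37, 1.0, T,
                    )
                    for t in grid
                ]
                k = int(np.argmax(vals))
                if vals[k] > bval:
                    bval, best = vals[k], (p, grid[k])
            diff, scal = circular_error(res.estimates[0], np.array(best))
            assert scal < 3.0  # within grid + refinement tolerance

    def test_symmetric_two_neuron_midpoint(self):
        pop = Population(
            preferred=np.array([[0.0, 1.0], [np.pi / 2, 1.0]]),
            kappa=np.full((2, 2), 2.37),
            tuned=np.ones((2, 2), dtype=bool),
            peak_rate=np.array([1.0, 1.0]),
            baseline_rate=np.zeros(2),
            kind="conjunctive",
            D=2,
        )
        mat = spiking.SpikeCountMatrix(
            np.array([[3, 3]]), np.array([np.pi / 4, 1.0]), 1.0, "independent"
        )
        res = ml_decode_conj(mat, pop)
        assert res.estimates[0, 0] == pytest.approx(np.pi / 4, abs=0.02)
        assert res.estimates[0, 1] == pytest.approx(1.0, abs=0.02)

    def test_zero_spikes_degenerate(self, rng):
        pop = build_population(10, "conjunctive", D=2, rng=rng)
        mat = spiking.SpikeCountMatrix(
            np.zeros((1, 10), dtype=int), np.zeros(2), 0.01, "independent"
        )
        res = ml_decode_conj(mat, pop)
        assert res.degenerate[0].all()
        assert res.scalar_error_deg[0] == pytest.approx(np.sqrt(2) * 180.0)

    def test_cr_saturation_at_large_NT(self, rng):
        from circpop.fisher import fisher_summary

        pop = build_population(1000, "conjunctive", D=2, kappa=9.11, rng=rng)
        fs = fisher_summary(1000, 10.0, 9.11)
        errs = []
        obj = MLObjective(pop, 10.0)
        for _ in range(150):
            stim = rng.uniform(0, 2 * np.pi, 2)
            mat = spiking.sample_independent(pop, stim, 10.0, 1, rng=rng)
            errs.append(ml_decode(mat, pop, objective=obj).scalar_error_deg[0])
        # Rayleigh mean = sqrt(pi)/2 * RMS; RMS bounded by sqrt(2)/sqrt(J)
        expected = np.sqrt(np.pi) / 2 * np.sqrt(2) * fs.cr_bound_conj_deg
        assert np.mean(errs) == pytest.approx(expected, rel=0.10)


class TestPV:
    def test_single_neuron(self, rng):
        pop = build_population(10, "pure", D=2, kappa=9.11, rng=rng)
        counts = np.zeros((1, 10), dtype=int)
        counts[0, 2] = 5
        mat = spiking.SpikeCountMatrix(counts, np.zeros(2), 1.0, "independent")
        res = pv_decode(mat, pop)
        d = pop.group[2]
        assert res.estimates[0, d] == pytest.approx(pop.preferred[2, d])

    def test_two_equal_counts_bisect(self):
        pop = Population(
            preferred=np.array([[0.0, 0.0], [np.pi / 2, 0.0]]),
            kappa=np.full((2, 2), 9.11),
            tuned=np.array([[True, False], [True, False]]),
            peak_rate=np.ones(2),
            baseline_rate=np.zeros(2),
            kind="pure",
            D=2,
        )
        mat = spiking.SpikeCountMatrix(
            np.array([[4, 4]]), np.array([np.pi / 4, 0.0]), 1.0, "independent"
        )
        res = pv_decode(mat, pop)
        assert res.estimates[0, 0] == pytest.approx(np.pi / 4)

    def test_zero_resultant_degenerate(self):
        pop = Population(
            preferred=np.array([[0.0, 0.0], [np.pi, 0.0]]),
            kappa=np.full((2, 2), 9.11),
            tuned=np.array([[True, False], [True, False]]),
            peak_rate=np.ones(2),
            baseline_rate=np.zeros(2),
            kind="pure",
            D=2,
        )
        mat = spiking.SpikeCountMatrix(
            np.array([[2, 2]]), np.zeros(2), 1.0, "independent"
        )
        res = pv_decode(mat, pop)
        assert res.degenerate[0, 0]
        assert res.errors_deg[0, 0] == pytest.approx(180.0)

    def test_pv_approaches_ml_with_N(self, rng):
        meds = []
        for N in (50, 500, 5000):
            pop = build_population(N, "pure", D=2, kappa=9.11, rng=rng)
            diffs = []
            obj = MLObjective(pop, 1.0)
            for _ in range(40):
                stim = rng.uniform(0, 2 * np.pi, 2)
                mat = spiking.sample_independent(pop, stim, 1.0, 1, rng=rng)
                ml = ml_decode(mat, pop, objective=obj)
                pv = pv_decode(mat, pop)
                ok = ~(ml.degenerate[0] | pv.degenerate[0])
                if ok.all():
                    d, _ = circular_error(pv.estimates[0], ml.estimates[0])
                    diffs.append(np.abs(d).mean())
            meds.append(np.median(diffs))
        assert meds[0] > meds[2]
        assert meds[2] < 1.0


class TestGaussianNC:
    def test_identity_matches_naive_ml(self, rng):
        # high-rate regime where the Gaussian approximation is accurate
        pop = build_population(40, "pure", D=2, kappa=2.37, R_pure=20.0, rng=rng)
        eye = spiking.CorrelationStructure(np.zeros((40, 40)), np.eye(40))
        stim = rng.uniform(0, 2 * np.pi, 2)
        mat = spiking.sample_independent(pop, stim, 5.0, 3, rng=rng)
        g = ml_decode_gaussian_nc(mat, pop, eye)
        m = ml_decode(mat, pop)
        d, _ = circular_error(g.estimates, m.estimates)
        assert np.abs(d).max() < 5.0

    def test_no_spikes_degenerate(self, rng):
        pop = build_population(10, "pure", D=2, kappa=2.37, rng=rng)
        eye = spiking.CorrelationStructure(np.zeros((10, 10)), np.eye(10))
        mat = spiking.SpikeCountMatrix(
            np.zeros((1, 10), dtype=int), np.zeros(2), 0.1, "independent"
        )
        res = ml_decode_gaussian_nc(mat, pop, eye)
        assert res.degenerate[0].all()

    def test_beats_naive_on_correlated_data(self, rng):
        # directional comparison at moderate size
        pop = build_population(60, "pure", D=2, kappa=2.37, R_pure=10.0, rng=rng)
        structure = spiking.correlation_from_distance(pop)
        errs_nc, errs_naive = [], []
        for _ in range(30):
            stim = rng.uniform(0, 2 * np.pi, 2)
            mat = spiking.sample_correlated(pop, stim, 2.0, 1, rng=rng,
                                            structure=structure)
            errs_nc.append(
                ml_decode_gaussian_nc(mat, pop, structure).scalar_error_deg[0]
            )
            errs_naive.append(ml_decode(mat, pop).scalar_error_deg[0])
        assert np.mean(errs_nc) <= np.mean(errs_naive) * 1.25


class TestInvariances:
    def test_rotation_invariance(self, rng):
        # rotating stimulus and preferred directions together leaves the
        # error distribution unchanged trial by trial (same seed)
        pop = build_population(100, "pure", D=2, kappa=9.11, seed=21)
        shift = 1.234
        rotated = Population(
            preferred=(pop.preferred + shift) % (2 * np.pi),
            kappa=pop.kappa,
            tuned=pop.tuned,
            peak_rate=pop.peak_rate,
            baseline_rate=pop.baseline_rate,
            kind=pop.kind,
            D=pop.D,
        )
        stim = np.array([0.7, 2.9])
        m1 = spiking.sample_independent(pop, stim, 1.0, 5, seed=4)
        m2 = spiking.SpikeCountMatrix(m1.counts, stim + shift, 1.0, "independent")
        r1 = ml_decode(m1, pop)
        r2 = ml_decode(m2, rotated)
        np.testing.assert_allclose(
            r1.scalar_error_deg, r2.scalar_error_deg, atol=0.05
        )

    def test_mean_error_below_random_guess(self, rng):
        pop = build_population(50, "pure", D=2, kappa=9.11, rng=rng)
        errs = []
        obj = MLObjective(pop, 0.001)
        for _ in range(60):
            stim = rng.uniform(0, 2 * np.pi, 2)
            mat = spiking.sample_independent(pop, stim, 0.001, 1, rng=rng)
            errs.append(ml_decode(mat, pop, objective=obj).scalar_error_deg[0])
        assert np.mean(errs) <= 180.0 * np.sqrt(2)
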