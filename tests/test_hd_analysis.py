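import numpy as np
import pytest
from scipy import special

from circpop.hd_analysis import (
    Session,
    ShuffleConfig,
    classify_cells,
    rayleigh_vector,
    shuffle_significance,
    transition_analysis,
    tuning_curve,
    tuning_width,
    velocity_bins_adaptive,
    velocity_labels_two_bin,
)
from circpop.hd_analysis import TuningCurveEstimate
from circpop.kinematics import angular_velocities
from circpop.synthetic import BehaviorSpec, CellSpec, generate_session


def make_session(cells, duration=900.0, seed=0):
    spec = BehaviorSpec(seed=seed)
    sess, truth = generate_session(spec, cells, duration_s=duration, seed=seed + 1)
    _, _, v = angular_velocities(sess.azimuth_deg, sess.pitch_deg, 1 / sess.dt)
    labels = velocity_labels_two_bin(np.concatenate([[np.nan], v]))
    return sess, labels, truth


@pytest.fixture(scope="module")
def tuned_session():
    cells = [
        CellSpec("flat", "untuned", peak_rate_hz=1.5),
        CellSpec("az", "pure_azimuth", preferred_azimuth_deg=120.0, peak_rate_hz=1.5),
        CellSpec("pi", "pure_pitch", preferred_pitch_deg=10.0, peak_rate_hz=1.5),
    ]
    return make_session(cells, duration=900.0, seed=3)


class TestTuningCurve:
    def test_flat_cell_flat_curve(self, tuned_session):
        sess, labels, _ = tuned_session
        curve = tuning_curve(sess, "flat", labels, "low", "azimuth")
        ok = np.isfinite(curve.rate_hz)
        mean = np.nanmean(curve.rate_hz)
        assert mean == pytest.approx(1.5, rel=0.15)
        # coefficient of variation small for a homogeneous cell
        assert np.nanstd(curve.rate_hz) / mean < 0.6

    def test_pure_cell_peak_location(self, tuned_session):
        sess, labels, _ = tuned_session
        curve = tuning_curve(sess, "az", labels, "low", "azimuth")
        peak = curve.bin_centers_deg[np.nanargmax(curve.rate_hz)]
        assert abs((peak - 120.0 + 180) % 360 - 180) <= 6.0  # within one bin

    def test_spike_conservation(self, tuned_session):
        sess, labels, _ = tuned_session
        curve = tuning_curve(sess, "az", labels, "low", "azimuth")
        frames = sess.spike_frames("az")
        in_low = (labels == "low")[frames]
        assert curve.spikes.sum() == in_low.sum()
        # total spikes = sum rate * occupancy over unmasked bins
        ok = np.isfinite(curve.rate_hz)
        recon = np.sum(curve.rate_hz[ok] * curve.occupancy_s[ok])
        assert recon == pytest.approx(curve.spikes[ok].sum())

    def test_empty_bin_raises(self, tuned_session):
        sess, labels, _ = tuned_session
        with pytest.raises(ValueError, match="inclusion"):
            tuning_curve(sess, "az", labels, "nonexistent", "azimuth")

    def test_occupancy_conservation(self, tuned_session):
        sess, labels, _ = tuned_session
        curve = tuning_curve(sess, "az", labels, "low", "azimuth")
        assert curve.occupancy_s.sum() == pytest.approx(
            (labels == "low").sum() * sess.dt
        )


class TestRayleighVector:
    def _curve(self, rates):
        n = len(rates)
        return TuningCurveEstimate(
            bin_centers_deg=(np.arange(n) + 0.5) * (360.0 / n),
            rate_hz=np.asarray(rates, dtype=float),
            occupancy_s=np.ones(n),
            spikes=np.asarray(rates, dtype=float),
            dimension="azimuth",
            velocity_bin="low",
        )

    def test_flat_curve_zero(self):
        assert rayleigh_vector(self._curve(np.ones(60))) == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_one(self):
        r = np.zeros(60)
        r[10] = 5.0
        assert rayleigh_vector(self._curve(r)) == pytest.approx(1.0)

    def test_von_mises_closed_form(self):
        # resultant of a von-Mises rate profile = I1(kappa)/I0(kappa)
        kappa = 9.11
        centers = (np.arange(360) + 0.5) * 1.0
        rates = np.exp(kappa * (np.cos(np.deg2rad(centers - 180.0)) - 1.0))
        curve = self._curve(rates)
        expected = special.i1(kappa) / special.i0(kappa)
        assert rayleigh_vector(curve) == pytest.approx(expected, rel=1e-4)


class TestTuningWidth:
    def _curve(self, rates):
        n = len(rates)
        return TuningCurveEstimate(
            (np.arange(n) + 0.5) * (360.0 / n),
            np.asarray(rates, dtype=float),
            np.ones(n),
            np.asarray(rates, dtype=float),
            "azimuth",
            "low",
        )

    def test_von_mises_45(self):
        from circpop.tuning import kappa_from_width

        kappa = kappa_from_width(45.0)
        centers = (np.arange(60) + 0.5) * 6.0
        rates = np.exp(kappa * (np.cos(np.deg2rad(centers - 181.0)) - 1.0))
        assert tuning_width(self._curve(rates)) == pytest.approx(45.0, abs=6.0)

    def test_step_curve(self):
        r = np.zeros(60)
        r[10:20] = 2.0
        assert tuning_width(self._curve(r)) == pytest.approx(60.0)

    def test_flat_curve_flagged(self):
        assert np.isnan(tuning_width(self._curve(np.ones(60))))

    def test_wraps_across_zero(self):
        r = np.zeros(60)
        r[:5] = 2.0
        r[-5:] = 2.0
        assert tuning_width(self._curve(r)) == pytest.approx(60.0)


class TestShuffleSignificance:
    def test_tuned_cell_significant(self, tuned_session):
        sess, labels, _ = tuned_session
        res = shuffle_significance(
            sess, "az", labels, "low", "azimuth",
            ShuffleConfig(n_shuffles=300), seed=0,
        )
        assert res["significant"]
        assert res["p_value"] < 0.01

    def test_untuned_cell_not_significant(self, tuned_session):
        sess, labels, _ = tuned_session
        res = shuffle_significance(
            sess, "flat", labels, "low", "azimuth",
            ShuffleConfig(n_shuffles=300), seed=0,
        )
        assert not res["significant"]

    def test_shuffle_warning_below_100(self, tuned_session):
        sess, labels, _ = tuned_session
        with pytest.warns(UserWarning, match="shuffles"):
            shuffle_significance(
                sess, "flat", labels, "low", "azimuth",
                ShuffleConfig(n_shuffles=50), seed=0,
            )

    def test_type_i_calibration(self):
        # ~1% nominal rate across many untuned cells (binomial CI)
        cells = [CellSpec(f"u{i}", "untuned", peak_rate_hz=1.0) for i in range(60)]
        sess, labels, _ = make_session(cells, duration=600.0, seed=11)
        cfg = ShuffleConfig(n_shuffles=200)
        rng = np.random.default_rng(0)
        hits = sum(
            shuffle_significance(sess, c.cell_id, labels, "low", "azimuth", cfg, rng=rng)[
                "significant"
            ]
            for c in cells
        )
        # Binomial(60, 0.01): P(X > 4) < 1e-3
        assert hits <= 4


class TestClassification:
    def test_recovery_and_exclusions(self):
        rng = np.random.default_rng(5)
        cells = [
            CellSpec("az", "pure_azimuth", preferred_azimuth_deg=200.0, peak_rate_hz=1.0),
            CellSpec("conj", "conjunctive", preferred_azimuth_deg=50.0,
                     preferred_pitch_deg=350.0, peak_rate_hz=3.4),
            CellSpec("silent", "untuned", peak_rate_hz=0.01),
        ]
        sess, labels, _ = make_session(cells, duration=1200.0, seed=8)
        df = classify_cells(
            sess, labels, shuffle_config=ShuffleConfig(n_shuffles=300), seed=1
        )
        by = df.set_index(["cell", "velocity_bin"])
        assert by.loc[("az", "low"), "label"] == "pure_azimuth"
        assert by.loc[("conj", "low"), "label"] == "conjunctive"
        assert not by.loc[("silent", "low"), "included"]
        assert by.loc[("silent", "low"), "reason"] == "spikes_below_minimum"

    def test_determinism(self):
        cells = [CellSpec("az", "pure_azimuth", preferred_azimuth_deg=10.0)]
        sess, labels, _ = make_session(cells, duration=600.0, seed=2)
        a = classify_cells(sess, labels, shuffle_config=ShuffleConfig(n_shuffles=150), seed=9)
        b = classify_cells(sess, labels, shuffle_config=ShuffleConfig(n_shuffles=150), seed=9)
        assert a.equals(b)

    def test_gated_cell_changes_label(self):
        cells = [
            CellSpec("g", "pure_azimuth", preferred_azimuth_deg=80.0,
                     preferred_pitch_deg=0.0, peak_rate_hz=3.4,
                     gate_label="conjunctive", gate_threshold_deg_s=10.0)
        ]
        sess, labels, _ = make_session(cells, duration=1500.0, seed=4)
        df = classify_cells(sess, labels, shuffle_config=ShuffleConfig(n_shuffles=300), seed=0)
        by = df.set_index("velocity_bin")["label"]
        assert by["low"] == "pure_azimuth"
        assert by["high"] == "conjunctive"


class TestAdaptiveBins:
    def test_equal_occupancy_quartiles(self):
        rng = np.random.default_rng(0)
        v = rng.exponential(10.0, size=10_000)
        bins = velocity_bins_adaptive(v, n_bins=4)
        assert len(bins) == 4
        for lo, hi in bins:
            frac = np.mean((v >= lo) & (v < hi))
            assert frac == pytest.approx(0.25, abs=0.01)

    def test_sliding_windows(self):
        rng = np.random.default_rng(0)
        v = rng.exponential(10.0, size=5_000)
        wins = velocity_bins_adaptive(v, sliding_step=1.0, width_quantile=0.25)
        assert len(wins) > 3
        assert wins[0][0] == pytest.approx(float(v.min()))


class TestTransitions:
    def test_identity_table(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "cell": ["a", "a", "b", "b"],
                "velocity_bin": ["low", "high", "low", "high"],
                "label": ["pure_azimuth", "pure_azimuth", "conjunctive", "conjunctive"],
                "included": [True] * 4,
            }
        )
        counts, pct = transition_analysis(df)
        assert counts.loc["pure", "pure"] == 1
        assert counts.loc["conjunctive", "conjunctive"] == 1
        assert pct["pure"].sum() == pytest.approx(100.0)

    def test_percentages_sum_100(self):
        import pandas as pd

        rows = []
        labels = ["untuned", "pure_azimuth", "pure_pitch", "conjunctive"]
        rng = np.random.default_rng(1)
        for i in range(30):
            for vb in ("low", "high"):
                rows.append(
                    {
                        "cell": f"c{i}",
                        "velocity_bin": vb,
                        "label": labels[rng.integers(4)],
                        "included": True,
                    }
                )
        counts, pct = transition_analysis(pd.DataFrame(rows))
        for col in pct.columns:
            if counts[col].sum() > 0:
                assert pct[col].sum() == pytest.approx(100.0)
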