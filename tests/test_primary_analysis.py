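import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kinetrace import (
    InsufficientDataError,
    RegistryError,
    Store,
    analyze_primary,
    roi_linear,
    roi_stats,
    run_pipeline,
)
from kinetrace.trace_model import TraceSegment


def segment(arg, val, unit="uM", kind="time"):
    return TraceSegment(
        "O2", np.asarray(arg, float), np.asarray(val, float), unit, kind
    )


def normal_equations(x, y):
    """Independent closed-form OLS oracle (explicit sums)."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx, sxy = sum(xi * xi for xi in x), sum(xi * yi for xi, yi in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


class TestRoiStats:
    def test_hand_computed_example(self):
        res = roi_stats(segment([0, 1, 2], [2, 4, 9]))
        assert res.stats["mean"] == pytest.approx(5.0)
        assert res.stats["median"] == pytest.approx(4.0)
        assert res.stats["sd"] == pytest.approx(math.sqrt(13))

    def test_single_value_sd_absent(self):
        res = roi_stats(segment([0], [7]))
        assert res.stats["mean"] == 7 and res.stats["median"] == 7
        assert "sd" not in res.stats

    def test_constant_segment_sd_zero(self):
        assert roi_stats(segment([0, 1, 2], [5, 5, 5])).stats["sd"] == 0.0

    def test_empty_segment_rejected(self):
        with pytest.raises(InsufficientDataError):
            roi_stats(segment([], []))


class TestRoiLinear:
    def test_exact_line(self):
        res = roi_linear(segment([0, 1, 2], [10, 8, 6]))
        assert res.stats["slope"] == pytest.approx(-2.0)
        assert res.stats["intercept"] == pytest.approx(10.0)
        assert res.stats["r2"] == pytest.approx(1.0)
        assert res.stats["rate"] == pytest.approx(120.0)
        assert res.units["rate"] == "nmol/ml/min"

    def test_constant_values_r2_absent(self):
        res = roi_linear(segment([0, 1, 2], [5, 5, 5]))
        assert res.stats["slope"] == 0.0
        assert res.stats["rate"] == 0.0
        assert "r2" not in res.stats

    def test_degenerate_design_rejected(self):
        with pytest.raises(InsufficientDataError):
            roi_linear(segment([3, 3, 3], [1, 2, 3]))
        with pytest.raises(InsufficientDataError):
            roi_linear(segment([1], [1]))

    def test_space_argument_gets_no_rate(self):
        res = roi_linear(segment([0, 1, 2], [10, 8, 6], kind="space"))
        assert "rate" not in res.stats

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 200)
        x = np.sort(rng.uniform(0, 500, n))
        y = rng.normal(100, 5, n) - rng.uniform(0, 0.2) * x
        res = roi_linear(segment(x, y))
        slope, intercept = normal_equations(list(x), list(y))
        assert res.stats["slope"] == pytest.approx(slope, rel=1e-10)
        assert res.stats["intercept"] == pytest.approx(intercept, rel=1e-10)

    @given(
        shift=st.floats(-1e3, 1e3),
        scale=st.floats(0.01, 100),
    )
    def test_affine_equivariance(self, shift, scale):
        """Shifting time changes only the intercept; scaling values scales
        slope and intercept linearly."""
        rng = np.random.default_rng(12345)
        x = np.sort(rng.uniform(0, 100, 40))
        y = 50 - 0.3 * x + rng.normal(0, 1, 40)
        base = roi_linear(segment(x, y)).stats
        shifted = roi_linear(segment(x + shift, y)).stats
        assert shifted["slope"] == pytest.approx(base["slope"], rel=1e-6, abs=1e-9)
        scaled = roi_linear(segment(x, y * scale)).stats
        assert scaled["slope"] == pytest.approx(base["slope"] * scale, rel=1e-6)
        assert scaled["intercept"] == pytest.approx(base["intercept"] * scale, rel=1e-6)

    def test_ols_slope_unbiased_across_replicates(self):
        """Mean recovered slope over 200 noisy replicates lies within 2
        standard errors of the truth."""
        true_slope = -55.0 / 60.0
        slopes = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = np.arange(0.0, 270.0)
            y = 500.0 + true_slope * x + rng.normal(0, 0.5, x.size)
            slopes.append(roi_linear(segment(x, y)).stats["slope"])
        mean, se = np.mean(slopes), np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(mean - true_slope) < 2 * se


class TestAnalyzePrimary:
    def test_noise_free_pipeline_recovers_true_rates(self, analyzed_store, clean_experiment):
        store, experiment_id = analyzed_store
        _, truth = clean_experiment
        df = store.query_export(
            "SELECT r.lo, l.rate FROM roi r JOIN roi_linear l ON l.roi_id = r.roi_id "
            "ORDER BY r.lo"
        )
        assert len(df) == len(truth.rates)
        for rate, expected in zip(df["rate"], truth.rates):
            assert rate == pytest.approx(expected, rel=1e-6)

    def test_rerun_is_idempotent(self, analyzed_store, raw_file):
        store, experiment_id = analyzed_store
        before = store.table("roi_linear")
        report = run_pipeline(raw_file, store)
        assert report.ok and report.stages["import"]["duplicate"]
        after = store.table("roi_linear")
        assert before.equals(after)

    def test_unregistered_analysis_id(self):
        import kinetrace as kt
        from kinetrace.roi_engine import ROI

        data, _ = kt.simulate_respirometry(kt.SyntheticProtocol())
        roi = ROI(None, data.experiment_id, 30, 290, analysis_id="nonexistent")
        with pytest.raises(RegistryError, match="nonexistent"):
            analyze_primary(data, [roi])

    def test_failed_roi_does_not_abort_others(self, store):
        import kinetrace as kt
        from kinetrace.roi_engine import ROI

        data, _ = kt.simulate_respirometry(kt.SyntheticProtocol())
        store.import_experiment(data)
        good = kt.save_rois(store, [kt.create_roi(data, 30, 290)])[0]
        # window past the last sample: empty segment, insufficient data
        bad = kt.save_rois(
            store, [ROI(None, data.experiment_id, 1799.5, 1799.9)]
        )[0]
        results = analyze_primary(data, [bad, good], store=store)
        statuses = {r.roi_id: r.status for r in results}
        assert statuses[good.roi_id] == "ok"
        assert statuses[bad.roi_id].startswith("failed")
        df = store.table("roi_linear")
        assert set(df["roi_id"]) == {good.roi_id, bad.roi_id}
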