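import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idionet.preprocess import (
    MOMENTARY_ITEMS,
    SeverityResult,
    build_severity_groups,
    composite_symptoms,
    detrend,
    reverse_score,
    score_ids_sr,
    severity_category,
    stationarity_screen,
)
from idionet.series import StudyDesign, SymptomSeries
from idionet.simulate import MissingnessSpec, TrueGVAR, simulate_series


def ids_items(total: int) -> list:
    """A 30-item response whose scored total equals ``total`` (0-84).

    Fills the 26 single items first (max 78), then the appetite/weight pairs;
    the unused pair member stays None as the instrument intends.
    """
    single = [i for i in range(1, 31) if i not in (11, 12, 13, 14)]
    items: list = [None] * 30
    remaining = total
    for i in single:
        v = min(3, remaining)
        items[i - 1] = v
        remaining -= v
    for i in (11, 13):
        v = min(3, remaining)
        items[i - 1] = v
        remaining -= v
    assert remaining == 0
    return items


class TestIDSSRScoring:
    def test_all_zero_is_no_depression(self):
        items: list = [0] * 30
        items[11] = items[13] = None  # unanswered pair members (items 12, 14)
        r = score_ids_sr(items)
        assert r.total == 0 and r.category == "none"

    @pytest.mark.parametrize(
        "total,category",
        [(0, "none"), (13, "none"), (14, "mild"), (21, "mild"),
         (22, "moderate"), (30, "moderate"), (31, "severe"), (38, "severe"),
         (39, "very severe"), (84, "very severe")],
    )
    def test_published_severity_bands(self, total, category):
        assert score_ids_sr(ids_items(total)).total == total
        assert severity_category(total) == category

    def test_bands_partition_all_possible_totals(self):
        cats = [severity_category(t) for t in range(85)]
        # contiguous, no gaps, ordered none -> very severe
        order = ["none", "mild", "moderate", "severe", "very severe"]
        assert [c for c in dict.fromkeys(cats)] == order
        assert len(cats) == 85

    def test_pair_items_score_the_larger_member(self):
        items = ids_items(0)
        items[10], items[11] = 1, 3  # both appetite items answered
        assert score_ids_sr(items).total == 3

    def test_input_validation(self):
        with pytest.raises(ValueError, match="expected 30"):
            score_ids_sr([0] * 29)
        bad = ids_items(5)
        bad[0] = 4
        with pytest.raises(ValueError, match="not in 0-3"):
            score_ids_sr(bad)
        gone = ids_items(5)
        gone[4] = None
        with pytest.raises(ValueError, match="missing"):
            score_ids_sr(gone)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(0, 3), min_size=26, max_size=26),
        st.integers(0, 25),
    )
    def test_scoring_is_monotone_in_any_item(self, singles, which):
        """Raising a scored item never lowers the total."""
        single_idx = [i for i in range(1, 31) if i not in (11, 12, 13, 14)]
        items: list = [None] * 30
        for i, v in zip(single_idx, singles):
            items[i - 1] = v
        items[10] = items[12] = 0
        base = score_ids_sr(items).total
        j = single_idx[which] - 1
        items[j] = min(3, items[j] + 1)
        assert score_ids_sr(items).total >= base


class TestSeverityGroups:
    @staticmethod
    def _results(totals):
        return [
            SeverityResult(f"p{i}", t, severity_category(t))
            for i, t in enumerate(totals)
        ]

    def test_five_participants_sharing_31_form_one_group(self):
        g = build_severity_groups(self._results([31] * 5))
        assert g.n_groups == 1 and g.group_sizes == {31: 5}
        assert g.excluded == []

    def test_all_unique_totals_means_no_groups(self):
        g = build_severity_groups(self._results([10, 20]))
        assert g.n_groups == 0 and len(g.excluded) == 2

    def test_mixed_totals_hand_enumeration(self):
        g = build_severity_groups(self._results([15, 15, 22, 22, 22, 40]))
        assert g.group_sizes == {15: 2, 22: 3}
        assert len(g.excluded) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_severity_groups([])


def _item_frame(design: StudyDesign, **overrides) -> pd.DataFrame:
    df = pd.DataFrame(
        {item: np.full(design.max_assessments, 50.0) for item in MOMENTARY_ITEMS}
    )
    for k, v in overrides.items():
        df[k] = v
    return df


class TestComposites:
    design = StudyDesign(n_days=2, beeps_per_day=5)

    def test_reverse_scoring_in_depressed_mood(self):
        df = _item_frame(self.design, down=80.0, cheerful=20.0)
        s = composite_symptoms(df, design=self.design)
        mood = s.values[:, list(s.columns).index("depressed_mood")]
        assert np.allclose(mood, 80.0)

    def test_midpoint_is_fixed_under_reversal(self):
        s = composite_symptoms(_item_frame(self.design), design=self.design)
        assert np.allclose(s.values, 50.0)

    def test_fully_calm_scores_zero_restlessness(self):
        df = _item_frame(self.design, calm=100.0, stressed=0.0, relaxed=100.0)
        s = composite_symptoms(df, design=self.design)
        rest = s.values[:, list(s.columns).index("restlessness")]
        assert np.allclose(rest, 0.0)

    def test_partial_indicators_use_available_mean(self):
        df = _item_frame(self.design)
        df.loc[0, "down"] = np.nan  # cheerful=50 remains -> mood 50
        df.loc[1, ["down", "cheerful"]] = np.nan  # all gone -> missing
        s = composite_symptoms(df, design=self.design)
        j = list(s.columns).index("depressed_mood")
        assert s.values[0, j] == 50.0
        assert np.isnan(s.values[1, j])

    def test_item_reversal_is_involutive(self):
        x = np.array([0.0, 12.5, 50.0, 99.0, 100.0])
        assert np.allclose(reverse_score(reverse_score(x)), x)

    def test_out_of_range_item_rejected(self):
        df = _item_frame(self.design, down=101.0)
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            composite_symptoms(df, design=self.design)


class TestDetrend:
    def _series(self, values):
        T, p = values.shape
        design = StudyDesign(n_days=T // 5, beeps_per_day=5)
        cols = tuple(f"v{i+1}" for i in range(p))
        return SymptomSeries("x", values, cols, design)

    def test_pure_cubic_is_removed_exactly(self):
        t = np.arange(1, 141, dtype=float)
        vals = np.column_stack([t**3, 2 + 0.5 * t - 0.01 * t**2])
        det = detrend(self._series(vals))
        assert np.nanmax(np.abs(det.values)) < 1e-6

    def test_white_noise_keeps_its_shape_minus_mean(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((140, 2))
        det = detrend(self._series(vals))
        # refitting the trend basis on the residuals finds nothing
        t = np.arange(1, 141, dtype=float)
        z = (t - t.mean()) / t.std()
        X = np.column_stack([np.ones_like(z), z, z**2, z**3])
        beta, *_ = np.linalg.lstsq(X, det.values, rcond=None)
        assert np.max(np.abs(beta)) < 1e-8

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((140, 3)) + np.arange(140)[:, None] * 0.02
        vals[rng.random(140) < 0.2] = np.nan
        once = detrend(self._series(vals))
        twice = detrend(once)
        assert np.allclose(once.values, twice.values, atol=1e-8, equal_nan=True)

    def test_missing_entries_stay_missing(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal((140, 2))
        vals[::7] = np.nan
        det = detrend(self._series(vals))
        assert np.array_equal(np.isnan(det.values), np.isnan(vals))

    def test_too_few_observed_points_rejected(self):
        vals = np.full((140, 1), np.nan)
        vals[:5, 0] = 1.0
        with pytest.raises(ValueError, match="observed points"):
            detrend(self._series(vals))


class TestStationarityScreen:
    def _detrended(self, x):
        T = len(x)
        design = StudyDesign(n_days=T // 5, beeps_per_day=5)
        return detrend(SymptomSeries("x", x[:, None], ("v1",), design))

    def test_stationary_ar1_passes_nearly_always(self):
        rng = np.random.default_rng(0)
        passes = 0
        n = 200
        for _ in range(n):
            e = rng.standard_normal(140)
            x = np.empty(140)
            x[0] = e[0]
            for t in range(1, 140):
                x[t] = 0.3 * x[t - 1] + e[t]
            passes += stationarity_screen(self._detrended(x)).passed
        assert passes / n > 0.95

    def test_random_walk_fails_with_high_probability(self):
        from idionet.series import DetrendedSeries

        design = StudyDesign(n_days=28, beeps_per_day=5)
        rng = np.random.default_rng(1)
        fails = 0
        n = 200
        for _ in range(n):
            x = np.cumsum(rng.standard_normal(140))
            ds = DetrendedSeries("x", x[:, None], ("v1",), design)
            fails += not stationarity_screen(ds).passed
        assert fails / n > 0.8

    def test_constant_series_fails_with_zero_variance_reason(self):
        rep = stationarity_screen(self._detrended(np.full(140, 3.0)))
        assert not rep.passed
        assert rep.verdicts[0].reason == "zero variance"

    def test_multivariate_any_fail_rule(self, truth6):
        s = simulate_series(truth6, missing=MissingnessSpec(0.0), seed=3)
        rep = stationarity_screen(detrend(s))
        assert rep.passed and rep.failing_variables == []
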