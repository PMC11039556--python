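"""From raw inputs to analysis-ready series.

Covers four steps: scoring the baseline Inventory of Depressive
Symptomatology Self-Report (IDS-SR) and forming severity-matched groups;
compositing momentary visual-analogue items into the six symptom variables
(with reverse scoring); removing linear/quadratic/cubic time trends; and
screening each detrended variable for stationarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import SYMPTOM_NAMES, DetrendedSeries, StudyDesign, SymptomSeries

# ---------------------------------------------------------------------------
# IDS-SR scoring
# ---------------------------------------------------------------------------

N_IDS_ITEMS = 30
# The instrument asks respondents to answer either the "decrease" or the
# "increase" member of the appetite pair (items 11/12) and the weight pair
# (items 13/14); 28 items are scored, so the total ranges 0-84.
APPETITE_PAIR = (11, 12)
WEIGHT_PAIR = (13, 14)

SEVERITY_BANDS = (
    (0, 13, "none"),
    (14, 21, "mild"),
    (22, 30, "moderate"),
    (31, 38, "severe"),
    (39, 84, "very severe"),
)


@dataclass(frozen=True)
class SeverityResult:
    participant_id: str
    total: int
    category: str


def severity_category(total: int) -> str:
    """Map an IDS-SR total (0-84) to its severity band."""
    if not 0 <= total <= 84:
        raise ValueError(f"IDS-SR total {total} outside 0-84")
    for lo, hi, name in SEVERITY_BANDS:
        if lo <= total <= hi:
            return name
    raise AssertionError("severity bands must cover 0-84")  # pragma: no cover


def score_ids_sr(items, participant_id: str = "") -> SeverityResult:
    """Score a 30-item IDS-SR response (items 0-3) to a 0-84 total.

    ``items`` holds the 30 responses in instrument order (1-based items 1-30).
    The unanswered member of the appetite and weight pairs may be NaN/None;
    when both members are answered the larger is scored.
    """
    vals = [math.nan if v is None else float(v) for v in items]
    if len(vals) != N_IDS_ITEMS:
        raise ValueError(f"expected {N_IDS_ITEMS} items, got {len(vals)}")
    pair_idx = set(APPETITE_PAIR) | set(WEIGHT_PAIR)
    total = 0.0
    for i, v in enumerate(vals, start=1):
        if math.isnan(v):
            if i in pair_idx:
                continue
            raise ValueError(f"item {i} is missing")
        if v not in (0.0, 1.0, 2.0, 3.0):
            raise ValueError(f"item {i} value {v} not in 0-3")
        if i not in pair_idx:
            total += v
    for pair in (APPETITE_PAIR, WEIGHT_PAIR):
        scored = [vals[i - 1] for i in pair if not math.isnan(vals[i - 1])]
        if not scored:
            raise ValueError(f"both items of pair {pair} are missing")
        total += max(scored)
    total = int(total)
    return SeverityResult(participant_id, total, severity_category(total))


@dataclass
class SeverityGrouping:
    """Severity-matched groups plus participants excluded for unique totals."""

    groups: dict[int, list[str]]
    excluded: list[str]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def group_sizes(self) -> dict[int, int]:
        return {total: len(m) for total, m in self.groups.items()}


def build_severity_groups(results: list[SeverityResult]) -> SeverityGrouping:
    """Group participants sharing an identical IDS-SR total (>= 2 members).

    Participants whose total is unique in the sample do not meet the matching
    eligibility criterion and are returned as excluded, never silently
    dropped.
    """
    if not results:
        raise ValueError("no severity results supplied")
    by_total: dict[int, list[str]] = {}
    for r in results:
        by_total.setdefault(r.total, []).append(r.participant_id)
    groups = {t: ids for t, ids in sorted(by_total.items()) if len(ids) >= 2}
    excluded = [pid for t, ids in by_total.items() if len(ids) < 2 for pid in ids]
    return SeverityGrouping(groups=groups, excluded=excluded)


# ---------------------------------------------------------------------------
# Momentary item -> symptom composites
# ---------------------------------------------------------------------------

#: symptom -> list of (item name, reversed?) indicators; composites are means
#: of the available indicators on the 0-100 VAS scale
COMPOSITE_MAP: dict[str, tuple[tuple[str, bool], ...]] = {
    "anhedonia": (("indifferent", False), ("listless", False), ("enthusiastic", True)),
    "depressed_mood": (("down", False), ("cheerful", True)),
    "appetite_change": (("appetite_deviation", False),),
    "restlessness": (("calm", True), ("stressed", False), ("relaxed", True)),
    "irritability": (("irritated", False),),
    "lethargy": (("tired", False), ("energetic", True)),
}

MOMENTARY_ITEMS = tuple(
    item for spec in COMPOSITE_MAP.values() for item, _ in spec
)


def reverse_score(x):
    """Reverse a 0-100 VAS item: x -> 100 - x (involutive)."""
    return 100.0 - np.asarray(x, dtype=float)


def composite_symptoms(
    items: pd.DataFrame,
    participant_id: str = "",
    design: StudyDesign | None = None,
) -> SymptomSeries:
    """Build the six symptom composites from raw momentary items.

    ``items`` has one row per beep (grid order) and one column per item in
    :data:`MOMENTARY_ITEMS`; values are 0-100 or NaN. Reversed indicators are
    mapped ``x -> 100 - x``; each composite is the mean of its available
    indicators and is missing only when all its indicators are missing.
    """
    design = design or StudyDesign()
    if len(items) != design.max_assessments:
        raise ValueError(
            f"expected {design.max_assessments} beep rows, got {len(items)}"
        )
    missing_cols = [c for c, _ in {i: None for i in MOMENTARY_ITEMS}.items()
                    if c not in items.columns]
    if missing_cols:
        raise ValueError(f"missing item columns: {missing_cols}")
    arr = items[list(dict.fromkeys(MOMENTARY_ITEMS))].to_numpy(dtype=float)
    finite = np.isfinite(arr)
    if np.any((arr[finite] < 0) | (arr[finite] > 100)):
        raise ValueError("item values must lie in [0, 100]")
    out = np.full((len(items), len(SYMPTOM_NAMES)), np.nan)
    for j, name in enumerate(SYMPTOM_NAMES):
        cols = []
        for item, rev in COMPOSITE_MAP[name]:
            col = items[item].to_numpy(dtype=float)
            cols.append(reverse_score(col) if rev else col)
        stacked = np.column_stack(cols)
        with np.errstate(invalid="ignore"):
            out[:, j] = np.nanmean(stacked, axis=1)
    return SymptomSeries(
        participant_id=participant_id, values=out, columns=SYMPTOM_NAMES,
        design=design,
    )


# ---------------------------------------------------------------------------
# Detrending
# ---------------------------------------------------------------------------

MIN_POINTS_FOR_DETREND = 8


def _time_basis(t: np.ndarray, degree: int) -> np.ndarray:
    """Centered-and-scaled polynomial design matrix with intercept."""
    z = (t - t.mean()) / t.std()
    return np.column_stack([np.ones_like(z)] + [z**k for k in range(1, degree + 1)])


def detrend(series: SymptomSeries, degree: int = 3) -> DetrendedSeries:
    """Remove polynomial time trends from every variable.

    Per variable, an OLS fit of the observed values on the centered-and-scaled
    beep index and its powers up to ``degree`` (cubic by default) is
    subtracted; missing entries stay missing. All variables are detrended
    unconditionally — the trend investigation is diagnostic, not a gate.
    """
    Y = series.values
    T, p = Y.shape
    t_all = np.arange(1, T + 1, dtype=float)
    resid = np.full_like(Y, np.nan)
    coefs = np.zeros((p, degree + 1))
    for j in range(p):
        obs = np.isfinite(Y[:, j])
        n_obs = int(obs.sum())
        if n_obs < MIN_POINTS_FOR_DETREND:
            raise ValueError(
                f"variable {series.columns[j]!r} has {n_obs} observed points; "
                f"need >= {MIN_POINTS_FOR_DETREND} for a degree-{degree} fit"
            )
        X = _time_basis(t_all[obs], degree)
        beta, *_ = np.linalg.lstsq(X, Y[obs, j], rcond=None)
        resid[obs, j] = Y[obs, j] - X @ beta
        coefs[j] = beta
    return DetrendedSeries(
        participant_id=series.participant_id,
        values=resid,
        columns=series.columns,
        design=series.design,
        trend_coefficients=coefs,
    )


# ---------------------------------------------------------------------------
# Stationarity screening
# ---------------------------------------------------------------------------


@dataclass
class StationarityVerdict:
    variable: str
    passed: bool
    p_value: float | None
    reason: str = ""


@dataclass
class StationarityReport:
    participant_id: str
    verdicts: list[StationarityVerdict]

    @property
    def passed(self) -> bool:
        return all(v.passed for v in self.verdicts)

    @property
    def failing_variables(self) -> list[str]:
        return [v.variable for v in self.verdicts if not v.passed]


def stationarity_screen(
    series: DetrendedSeries, alpha: float = 0.05
) -> StationarityReport:
    """Augmented Dickey-Fuller screen of every detrended variable.

    A variable passes when the unit-root null is rejected at ``alpha``
    (p < alpha). The overall series fails if any variable fails; failing
    participants should be flagged for exclusion, never silently dropped.
    Gaps are closed by concatenating the observed values, which pairs each
    observation with the nearest preceding one.
    """
    from statsmodels.tsa.stattools import adfuller

    verdicts = []
    for j, name in enumerate(series.columns):
        x = series.values[:, j]
        x = x[np.isfinite(x)]
        if x.size < 10:
            verdicts.append(
                StationarityVerdict(name, False, None, "too few observations")
            )
            continue
        if np.var(x) < 1e-12:
            verdicts.append(StationarityVerdict(name, False, None, "zero variance"))
            continue
        pval = float(adfuller(x, regression="c", autolag="AIC")[1])
        verdicts.append(
            StationarityVerdict(name, pval < alpha, pval,
                                "" if pval < alpha else "unit root not rejected")
        )
    return StationarityReport(series.participant_id, verdicts)


def preprocess_series(series: SymptomSeries, degree: int = 3):
    """Detrend and screen one series; returns (DetrendedSeries, report)."""
    det = detrend(series, degree=degree)
    return det, stationarity_screen(det)
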