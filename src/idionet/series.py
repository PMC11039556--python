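"""Study design and per-participant time-series containers.

The sampling scheme is a fixed beep grid: ``beeps_per_day`` prompts per day,
equally spaced, over ``n_days`` days. A participant's data live on this grid
as a ``T x p`` array with ``NaN`` marking missing assessments, where
``T = n_days * beeps_per_day`` and ``p`` is the number of symptom variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: canonical momentary depressive-symptom composites, in fixed order
SYMPTOM_NAMES: tuple[str, ...] = (
    "anhedonia",
    "depressed_mood",
    "appetite_change",
    "restlessness",
    "irritability",
    "lethargy",
)


@dataclass(frozen=True)
class StudyDesign:
    """Fixed-grid EMA sampling scheme (default: 5 beeps/day for 28 days)."""

    n_days: int = 28
    beeps_per_day: int = 5
    inter_beep_hours: float = 3.0

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.beeps_per_day < 1:
            raise ValueError("n_days and beeps_per_day must be >= 1")
        if self.inter_beep_hours <= 0:
            raise ValueError("inter_beep_hours must be positive")

    @property
    def max_assessments(self) -> int:
        """Maximum possible assessments per person (grid length)."""
        return self.n_days * self.beeps_per_day

    def grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (day, beep, t) arrays for the full grid, all 1-based."""
        t = np.arange(1, self.max_assessments + 1)
        day = (t - 1) // self.beeps_per_day + 1
        beep = (t - 1) % self.beeps_per_day + 1
        return day, beep, t


@dataclass
class SymptomSeries:
    """One participant's symptom composites on the beep grid.

    ``values`` is ``(T, p)`` with ``NaN`` for missing assessments. Raw VAS
    composites live on a 0-100 scale; simulated latent-scale series may take
    any real values.
    """

    participant_id: str
    values: np.ndarray
    columns: tuple[str, ...] = SYMPTOM_NAMES
    design: StudyDesign = field(default_factory=StudyDesign)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (T, p) array")
        if self.values.shape[1] != len(self.columns):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.columns)} names"
            )
        if self.values.shape[0] != self.design.max_assessments:
            raise ValueError(
                f"series has {self.values.shape[0]} rows; design grid has "
                f"{self.design.max_assessments}"
            )

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    @property
    def n_beeps(self) -> int:
        return self.values.shape[0]

    @property
    def observed_mask(self) -> np.ndarray:
        """Boolean (T, p) mask of observed entries."""
        return np.isfinite(self.values)

    @property
    def n_completed(self) -> int:
        """Number of beeps with at least one observed value."""
        return int(self.observed_mask.any(axis=1).sum())


@dataclass
class DetrendedSeries(SymptomSeries):
    """A :class:`SymptomSeries` on the residual scale after polynomial
    detrending; retains the per-variable fitted trend coefficients.

    ``trend_coefficients`` is ``(p, degree + 1)``: intercept then the
    coefficients of the centered-and-scaled time basis ``z, z^2, ...``.
    """

    trend_coefficients: np.ndarray | None = None

    def with_values(self, values: np.ndarray) -> "DetrendedSeries":
        return replace(self, values=values)
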