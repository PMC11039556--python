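"""Synthetic EMA studies with known ground-truth dynamics.

The original momentary-assessment data are not publicly available, so every
downstream stage is exercised on simulated studies: each participant's series
is drawn from a person-specific stationary VAR(1),

    y_t = mu + B (y_{t-1} - mu) + eps_t,    eps_t ~ N(0, K^{-1}),

on the fixed 140-slot beep grid (5 beeps/day x 28 days), with whole-beep
missing-completely-at-random dropout calibrated to the observed mean
completion of 115/140 beeps (rate 0.18), optional polynomial time trends, and
severity groups of participants sharing one baseline IDS-SR total score.

Null studies give every member of a severity group the *same* true model —
the scenario in which a network-invariance test should detect nothing — while
alternative studies perturb each member's temporal matrix away from the group
template to create genuine individual differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kalman import spectral_radius, stationary_covariance
from .series import SYMPTOM_NAMES, StudyDesign, SymptomSeries

DEFAULT_TEMPORAL_DENSITY = 0.3
DEFAULT_MAX_ABS_EDGE = 0.4
DEFAULT_PRECISION_DENSITY = 0.3
DEFAULT_BEEP_MISSING_PROB = 0.18
BURN_IN = 100

#: IDS-SR totals observed in samples of currently depressed outpatients
SEVERITY_SCORE_RANGE = (15, 51)

#: default probabilities of group sizes 2..6 (mean ~3.2, matching 73
#: participants across 23 severity groups)
GROUP_SIZE_WEIGHTS = (0.35, 0.35, 0.15, 0.10, 0.05)


@dataclass(frozen=True)
class MissingnessSpec:
    """Whole-beep MCAR dropout: each beep is missing with fixed probability."""

    beep_missing_prob: float = DEFAULT_BEEP_MISSING_PROB
    mechanism: str = "MCAR"

    def __post_init__(self) -> None:
        if not 0.0 <= self.beep_missing_prob <= 1.0:
            raise ValueError("beep_missing_prob must be in [0, 1]")
        if self.mechanism != "MCAR":
            raise ValueError("only the MCAR mechanism is supported")


@dataclass(frozen=True)
class TrendSpec:
    """Per-variable polynomial trend in the beep index, added after the VAR.

    ``linear``, ``quadratic`` and ``cubic`` are length-p arrays of
    coefficients in VAS units per beep-index power; all-zero means no trend.
    """

    linear: np.ndarray | None = None
    quadratic: np.ndarray | None = None
    cubic: np.ndarray | None = None

    def evaluate(self, t: np.ndarray, p: int) -> np.ndarray:
        """Trend matrix (T, p) at 1-based beep indices ``t``."""
        out = np.zeros((len(t), p))
        for coef, power in ((self.linear, 1), (self.quadratic, 2), (self.cubic, 3)):
            if coef is not None:
                coef = np.asarray(coef, dtype=float)
                if not np.all(np.isfinite(coef)):
                    raise ValueError("trend coefficients must be finite")
                out += np.outer(t.astype(float) ** power, coef)
        return out


@dataclass
class TrueGVAR:
    """Ground-truth person-specific model: means, temporal matrix, precision."""

    mu: np.ndarray
    B: np.ndarray
    K: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        p = self.mu.shape[0]
        if self.B.shape != (p, p) or self.K.shape != (p, p):
            raise ValueError("mu, B, K dimensions disagree")
        if spectral_radius(self.B) >= 1.0:
            raise ValueError("temporal matrix must have spectral radius < 1")
        np.linalg.cholesky(self.K)  # raises if not SPD

    @property
    def p(self) -> int:
        return self.mu.shape[0]

    @property
    def Sigma(self) -> np.ndarray:
        S = np.linalg.inv(self.K)
        return 0.5 * (S + S.T)


@dataclass
class SimulatedStudy:
    """A full synthetic study: series, truths, severity scores and groups."""

    series: dict[str, SymptomSeries]
    truths: dict[str, TrueGVAR]
    severity: dict[str, int]
    groups: dict[int, list[str]] = field(default_factory=dict)
    design: StudyDesign = field(default_factory=StudyDesign)
    seed: int | None = None

    @property
    def participant_ids(self) -> list[str]:
        return list(self.series)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_stable_temporal_matrix(
    p: int = 6,
    density: float = DEFAULT_TEMPORAL_DENSITY,
    max_abs: float = DEFAULT_MAX_ABS_EDGE,
    seed=None,
    max_retries: int = 100,
) -> np.ndarray:
    """Random sparse temporal matrix with spectral radius < 1.

    Roughly ``density * p**2`` cells (diagonal included) get values uniform on
    ``[-max_abs, max_abs]``; unstable draws are retried, and a final draw is
    rescaled below radius 1 if retries run out.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    if max_abs <= 0:
        raise ValueError("max_abs must be positive")
    rng = _rng(seed)
    n_edges = int(round(density * p * p))
    for attempt in range(max_retries):
        B = np.zeros((p, p))
        if n_edges > 0:
            idx = rng.choice(p * p, size=n_edges, replace=False)
            vals = rng.uniform(-max_abs, max_abs, size=n_edges)
            B.flat[idx] = vals
        rho = spectral_radius(B)
        if rho < 0.95:
            return B
    # could not draw a stable support; shrink the last draw
    B *= 0.9 / rho
    if spectral_radius(B) >= 1.0:  # pragma: no cover - defensive
        raise RuntimeError(
            f"could not generate a stable matrix after {max_retries} retries "
            f"(density={density}, max_abs={max_abs})"
        )
    return B


def generate_precision_matrix(
    p: int = 6,
    density: float = DEFAULT_PRECISION_DENSITY,
    seed=None,
    min_abs: float = 0.2,
    max_abs: float = 0.5,
) -> np.ndarray:
    """Random sparse SPD precision matrix via diagonal dominance.

    About ``density`` of the off-diagonal pairs carry values with magnitude
    in ``[min_abs, max_abs]``; the diagonal exceeds each row's absolute
    off-diagonal sum, guaranteeing positive definiteness.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    rng = _rng(seed)
    K = np.zeros((p, p))
    iu, ju = np.triu_indices(p, k=1)
    n_pairs = len(iu)
    n_edges = int(round(density * n_pairs))
    if n_edges > 0:
        which = rng.choice(n_pairs, size=n_edges, replace=False)
        mags = rng.uniform(min_abs, max_abs, size=n_edges)
        signs = rng.choice([-1.0, 1.0], size=n_edges)
        K[iu[which], ju[which]] = mags * signs
        K = K + K.T
    np.fill_diagonal(K, 1.0 + np.sum(np.abs(K), axis=1))
    return K


def simulate_series(
    model: TrueGVAR,
    design: StudyDesign | None = None,
    trend: TrendSpec | None = None,
    missing: MissingnessSpec | None = None,
    seed=None,
    participant_id: str = "sim",
    burn_in: int = BURN_IN,
    vas_mode: bool = False,
    columns: tuple[str, ...] | None = None,
) -> SymptomSeries:
    """Simulate one participant's series on the beep grid.

    The VAR recursion is burned in for ``burn_in`` steps so the retained
    series starts near the stationary distribution; the polynomial trend is
    added afterwards, then whole beeps are dropped MCAR. ``vas_mode`` clips
    the result to the 0-100 visual-analogue scale (off by default: the latent
    Gaussian scale is what the likelihood theory assumes).
    """
    design = design or StudyDesign()
    missing = missing or MissingnessSpec(0.0)
    rng = _rng(seed)
    p = model.p
    T = design.max_assessments
    L = np.linalg.cholesky(model.Sigma)
    total = burn_in + T
    eps = rng.standard_normal((total, p)) @ L.T
    y = np.empty((total, p))
    prev = np.zeros(p)  # deviations from mu
    for t in range(total):
        prev = model.B @ prev + eps[t]
        y[t] = prev
    y = y[burn_in:] + model.mu
    if trend is not None:
        t_idx = np.arange(1, T + 1)
        y = y + trend.evaluate(t_idx, p)
    if vas_mode:
        y = np.clip(y, 0.0, 100.0)
    if missing.beep_missing_prob > 0:
        drop = rng.random(T) < missing.beep_missing_prob
        y[drop] = np.nan
    cols = columns or (SYMPTOM_NAMES if p == 6 else tuple(f"v{i+1}" for i in range(p)))
    return SymptomSeries(
        participant_id=participant_id, values=y, columns=cols, design=design
    )


def _draw_group_template(rng: np.random.Generator, p: int) -> TrueGVAR:
    B = generate_stable_temporal_matrix(p, seed=rng)
    K = generate_precision_matrix(p, seed=rng)
    mu = rng.uniform(30.0, 70.0, size=p)
    return TrueGVAR(mu=mu, B=B, K=K)


def _perturb_template(
    template: TrueGVAR,
    effect_size: float,
    n_edges: int,
    rng: np.random.Generator,
) -> TrueGVAR:
    """Member-specific model: template plus +/-effect_size on random B cells."""
    if effect_size == 0.0:
        return template
    p = template.p
    B = template.B.copy()
    idx = rng.choice(p * p, size=min(n_edges, p * p), replace=False)
    signs = rng.choice([-1.0, 1.0], size=len(idx))
    B.flat[idx] += signs * effect_size
    rho = spectral_radius(B)
    if rho >= 0.95:
        B *= 0.9 / rho
    return TrueGVAR(mu=template.mu, B=B, K=template.K)


def _build_study(
    n_groups: int,
    group_sizes,
    design: StudyDesign,
    missing: MissingnessSpec,
    seed: int,
    effect_size: float,
    n_perturbed_edges: int,
    p: int,
) -> SimulatedStudy:
    rng = np.random.default_rng(seed)
    if group_sizes is None:
        # sizes 2-6 skewed toward pairs, matching the observed mean group
        # size of about 3.2 (73 participants across 23 groups)
        group_sizes = rng.choice(
            [2, 3, 4, 5, 6], size=n_groups, p=GROUP_SIZE_WEIGHTS
        ).tolist()
    group_sizes = [int(s) for s in group_sizes]
    if len(group_sizes) != n_groups:
        raise ValueError("group_sizes length must equal n_groups")
    if any(s < 2 for s in group_sizes):
        raise ValueError("every severity group needs >= 2 members")
    lo, hi = SEVERITY_SCORE_RANGE
    if n_groups > hi - lo + 1:
        lo, hi = 0, 84
    if n_groups > hi - lo + 1:
        raise ValueError("more groups than distinct severity totals available")
    totals = rng.choice(np.arange(lo, hi + 1), size=n_groups, replace=False)

    series: dict[str, SymptomSeries] = {}
    truths: dict[str, TrueGVAR] = {}
    severity: dict[str, int] = {}
    groups: dict[int, list[str]] = {}
    pid = 0
    for g, (size, total) in enumerate(zip(group_sizes, totals)):
        template = _draw_group_template(rng, p)
        members = []
        for _ in range(size):
            pid += 1
            name = f"p{pid:03d}"
            truth = _perturb_template(template, effect_size, n_perturbed_edges, rng)
            series[name] = simulate_series(
                truth, design, None, missing, seed=rng, participant_id=name
            )
            truths[name] = truth
            severity[name] = int(total)
            members.append(name)
        groups[int(total)] = members
    return SimulatedStudy(
        series=series,
        truths=truths,
        severity=severity,
        groups=groups,
        design=design,
        seed=seed,
    )


def build_null_study(
    n_groups: int = 23,
    group_sizes=None,
    design: StudyDesign | None = None,
    missing: MissingnessSpec | None = None,
    seed: int = 0,
    p: int = 6,
) -> SimulatedStudy:
    """Study in which all members of each severity group share one true model.

    This is the null scenario for the invariance test: any detected
    individual difference within a group is a false detection.
    """
    return _build_study(
        n_groups,
        group_sizes,
        design or StudyDesign(),
        missing if missing is not None else MissingnessSpec(),
        seed,
        effect_size=0.0,
        n_perturbed_edges=0,
        p=p,
    )


def build_alternative_study(
    effect_size: float,
    n_groups: int = 23,
    group_sizes=None,
    design: StudyDesign | None = None,
    missing: MissingnessSpec | None = None,
    seed: int = 0,
    n_perturbed_edges: int = 4,
    p: int = 6,
) -> SimulatedStudy:
    """Study with genuine within-group differences: each member's temporal
    matrix is the group template plus ``+/-effect_size`` on a random subset of
    cells (restabilized by rescaling when needed)."""
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    return _build_study(
        n_groups,
        group_sizes,
        design or StudyDesign(),
        missing if missing is not None else MissingnessSpec(),
        seed,
        effect_size=effect_size,
        n_perturbed_edges=n_perturbed_edges,
        p=p,
    )


def stationary_cov_of(model: TrueGVAR) -> np.ndarray:
    """Stationary covariance of the model's VAR(1) process."""
    return stationary_covariance(model.B, model.Sigma)
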