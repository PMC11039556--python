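"""Study-level summaries of the invariance tests.

Three quantities: the proportion of participants with differential symptom
dynamics (every member of a heterogeneous-flagged group counts), a percentile
confidence interval from a bootstrap that resamples *severity groups* with
replacement, and the false-detection rate of the whole pipeline under a
simulated null in which no individual differences exist by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .invariance import INITResult, SeverityGroup, init_test
from .preprocess import detrend
from .series import StudyDesign
from .simulate import MissingnessSpec, SimulatedStudy, build_null_study

DEFAULT_N_BOOT = 10_000


@dataclass
class ProportionEstimate:
    """Proportion of participants in heterogeneous-flagged groups."""

    n_flagged: int
    n_total: int
    proportion: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int | None = None
    seed: int | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        s = f"{self.n_flagged}/{self.n_total} = {self.proportion:.3f}"
        if self.ci_low is not None:
            s += f" (95% CI {self.ci_low:.3f}-{self.ci_high:.3f})"
        return s


def proportion_differential(results: list[INITResult]) -> ProportionEstimate:
    """Point estimate: flagged members over all matched participants.

    Every member of a group whose free model won on AIC counts as displaying
    differential dynamics; the denominator is the total matched sample.
    """
    if not results:
        raise ValueError("no INIT results supplied")
    n_flagged = sum(r.size for r in results if r.heterogeneous)
    n_total = sum(r.size for r in results)
    return ProportionEstimate(
        n_flagged=n_flagged,
        n_total=n_total,
        proportion=round(n_flagged / n_total, 3),
    )


def bootstrap_ci(
    results: list[INITResult],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> ProportionEstimate:
    """Group-resampling percentile bootstrap for the proportion.

    Each replicate redraws the original number of severity groups with
    replacement (groups, not individuals, are the resampling unit) and
    recomputes the proportion from the resampled flags and sizes; the CI is
    the 2.5th/97.5th percentile of the replicate distribution.
    """
    if len(results) < 2:
        raise ValueError("bootstrap needs >= 2 groups")
    point = proportion_differential(results)
    flags = np.array([r.heterogeneous for r in results], dtype=float)
    sizes = np.array([r.size for r in results], dtype=float)
    G = len(results)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, G, size=(n_boot, G))
    num = (flags[idx] * sizes[idx]).sum(axis=1)
    den = sizes[idx].sum(axis=1)
    props = num / den
    lo, hi = np.percentile(props, [2.5, 97.5])
    return ProportionEstimate(
        n_flagged=point.n_flagged,
        n_total=point.n_total,
        proportion=point.proportion,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
    )


def bootstrap_replicates(
    results: list[INITResult], n_boot: int, seed: int = 0
) -> np.ndarray:
    """The raw replicate proportions behind :func:`bootstrap_ci`."""
    flags = np.array([r.heterogeneous for r in results], dtype=float)
    sizes = np.array([r.size for r in results], dtype=float)
    G = len(results)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, G, size=(n_boot, G))
    return (flags[idx] * sizes[idx]).sum(axis=1) / sizes[idx].sum(axis=1)


# ---------------------------------------------------------------------------
# Null-scenario false-detection simulation
# ---------------------------------------------------------------------------


@dataclass
class RepRecord:
    rep: int
    seed: int
    proportion: float
    n_flagged: int
    n_total: int
    n_failed_groups: int
    failed_groups: list[int] = field(default_factory=list)


@dataclass
class NullSimResult:
    """False-detection rate of the pipeline under a true-null study."""

    reps: int
    per_rep: list[RepRecord]
    mean_rate: float
    mc_se: float
    config: dict
    seed: int

    @property
    def per_rep_rates(self) -> np.ndarray:
        return np.array([r.proportion for r in self.per_rep])


def _rep_seed(master_seed: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(rep,))


def run_study_init(study: SimulatedStudy, **init_kwargs) -> tuple[list[INITResult], list[int]]:
    """Detrend every member and run the invariance test per severity group.

    Returns the per-group results plus the severity ids of groups whose fits
    failed (reported, never silently dropped).
    """
    results: list[INITResult] = []
    failed: list[int] = []
    for total, member_ids in study.groups.items():
        members = {pid: detrend(study.series[pid]) for pid in member_ids}
        group = SeverityGroup(severity=total, members=members)
        try:
            results.append(init_test(group, keep_fits=False, **init_kwargs))
        except Exception:  # noqa: BLE001 - failures are counted, not fatal
            failed.append(total)
    return results, failed


def run_null_simulation(
    n_groups: int = 23,
    group_sizes=None,
    design: StudyDesign | None = None,
    missing: MissingnessSpec | None = None,
    reps: int = 20,
    seed: int = 0,
    p: int = 6,
) -> NullSimResult:
    """Estimate the pipeline's false-detection rate under a simulated null.

    Per replicate: build a null study (every group's members share one true
    model), preprocess, run the invariance test per group, and compute the
    proportion of participants in flagged groups. Groups that fail to fit are
    excluded from numerator and denominator and counted. Each replicate's
    seed derives deterministically from the master seed, so extending
    ``reps`` leaves earlier replicates unchanged.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    design = design or StudyDesign()
    missing = missing if missing is not None else MissingnessSpec()
    records: list[RepRecord] = []
    for rep in range(reps):
        ss = _rep_seed(seed, rep)
        rep_seed = int(ss.generate_state(1)[0] % (2**31))
        study = build_null_study(
            n_groups=n_groups,
            group_sizes=group_sizes,
            design=design,
            missing=missing,
            seed=rep_seed,
            p=p,
        )
        results, failed = run_study_init(study)
        if results:
            est = proportion_differential(results)
            prop, n_fl, n_tot = est.proportion, est.n_flagged, est.n_total
        else:
            prop, n_fl, n_tot = np.nan, 0, 0
        records.append(
            RepRecord(
                rep=rep,
                seed=rep_seed,
                proportion=prop,
                n_flagged=n_fl,
                n_total=n_tot,
                n_failed_groups=len(failed),
                failed_groups=failed,
            )
        )
    rates = np.array([r.proportion for r in records], dtype=float)
    rates = rates[np.isfinite(rates)]
    mean_rate = float(rates.mean()) if rates.size else float("nan")
    mc_se = float(rates.std(ddof=1) / np.sqrt(rates.size)) if rates.size > 1 else float("nan")
    return NullSimResult(
        reps=reps,
        per_rep=records,
        mean_rate=mean_rate,
        mc_se=mc_se,
        config={
            "n_groups": n_groups,
            "group_sizes": group_sizes,
            "n_days": design.n_days,
            "beeps_per_day": design.beeps_per_day,
            "beep_missing_prob": missing.beep_missing_prob,
            "p": p,
        },
        seed=seed,
    )
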