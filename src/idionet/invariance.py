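"""Individual Network Invariance Test (INIT).

For a group of participants matched on baseline symptom severity, two models
are compared by AIC:

* the *heterogeneous* (free) model — every member gets their own GVAR, so the
  pooled log-likelihood is the sum of independent person-specific fits;
* the *homogeneous* (constrained) model — one temporal matrix B and one
  innovation precision K shared by all members, with person-specific means
  (the networks describe deviations from each person's own average, so means
  stay free in both models).

The group is flagged as showing differential dynamics when the heterogeneous
model's AIC is strictly lower; an exact tie resolves to homogeneous, keeping
the test conservative (type II errors are preferred over type I).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gvar import (
    Convergence,
    GVARModel,
    _check_identifiable,
    _init_prior,
    _initial_params,
    _residual_cov,
    _spd_floor,
    _values,
    fit_gvar_ml,
)
from .kalman import kalman_smoother, spectral_radius
from .series import DetrendedSeries


@dataclass
class SeverityGroup:
    """Participants sharing one IDS-SR total, with their detrended series."""

    severity: int
    members: dict[str, DetrendedSeries]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(
                "a severity group needs >= 2 members (matching on severity "
                "with at least one other participant is the eligibility "
                "criterion)"
            )

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def member_ids(self) -> list[str]:
        return list(self.members)


@dataclass
class FreeGroupFit:
    loglik: float
    n_params: int
    models: dict[str, GVARModel]


@dataclass
class ConstrainedGroupFit:
    loglik: float
    n_params: int
    B: np.ndarray
    K: np.ndarray
    mu: dict[str, np.ndarray]
    convergence: Convergence


@dataclass
class INITResult:
    """Outcome of one invariance test."""

    group_id: int
    size: int
    member_ids: list[str]
    loglik_free: float
    loglik_constrained: float
    n_params_free: int
    n_params_constrained: int
    aic_het: float
    aic_hom: float
    heterogeneous: bool
    free_fit: FreeGroupFit | None = field(default=None, repr=False)
    constrained_fit: ConstrainedGroupFit | None = field(default=None, repr=False)


def fit_group_free(group: SeverityGroup, **fit_kwargs) -> FreeGroupFit:
    """Heterogeneous model: independent person-specific fits, pooled."""
    models: dict[str, GVARModel] = {}
    for pid, series in group.members.items():
        try:
            models[pid] = fit_gvar_ml(series, **fit_kwargs)
        except Exception as exc:
            raise RuntimeError(f"member {pid!r} failed to fit: {exc}") from exc
    loglik = float(sum(m.loglik for m in models.values()))
    n_params = int(sum(m.n_params for m in models.values()))
    return FreeGroupFit(loglik=loglik, n_params=n_params, models=models)


def fit_group_constrained(
    group: SeverityGroup,
    tol: float = 1e-6,
    max_iter: int = 500,
    init_from: FreeGroupFit | None = None,
) -> ConstrainedGroupFit:
    """Homogeneous model: shared (B, K), person-specific means, joint FIML.

    The EM E-step runs the Kalman smoother once per member at the current
    shared parameters; the M-step pools the members' transition statistics
    (each member contributing its own intercept) into one regression update.
    """
    series = [group.members[pid] for pid in group.member_ids]
    Ys = [_values(s) for s in series]
    p = Ys[0].shape[1]
    for pid, Y in zip(group.member_ids, Ys):
        if Y.shape[1] != p:
            raise ValueError(f"member {pid!r} has a different variable count")
        _check_identifiable(Y)

    # initialization: average of free-fit estimates when available, else
    # averaged lag-pair least squares
    if init_from is not None:
        models = [init_from.models[pid] for pid in group.member_ids]
        B = np.mean([m.B for m in models], axis=0)
        Sigma = np.mean([m.Sigma for m in models], axis=0)
        cs = [(np.eye(p) - B) @ m.mu for m in models]
    else:
        inits = [_initial_params(Y) for Y in Ys]
        B = np.mean([b for _, b, _ in inits], axis=0)
        Sigma = np.mean([s for _, _, s in inits], axis=0)
        cs = [c for c, _, _ in inits]
    if spectral_radius(B) >= 0.95:
        B = B * (0.9 / spectral_radius(B))
    Sigma = _spd_floor(Sigma, rel=1e-8)

    ll_prev = -np.inf
    delta = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        smooths = []
        ll = 0.0
        for Y, c in zip(Ys, cs):
            m0, P0 = _init_prior(c, B, Sigma)
            sm = kalman_smoother(Y, c, B, Sigma, m0, P0, conditional=True)
            smooths.append(sm)
            ll += sm.loglik
        delta = abs(ll - ll_prev) / max(1.0, abs(ll))
        ll_prev = ll
        if delta < tol:
            converged = True
            break
        # pooled M-step: shared B from within-member-centered stats
        num = np.zeros((p, p))
        den = np.zeros((p, p))
        for sm in smooths:
            n = sm.n_trans
            num += sm.S_yx - np.outer(sm.S_y, sm.S_x) / n
            den += sm.S_xx - np.outer(sm.S_x, sm.S_x) / n
        B = np.linalg.solve(den.T, num.T).T
        cs = [(sm.S_y - B @ sm.S_x) / sm.n_trans for sm in smooths]
        resids = _residual_cov(smooths, [B] * len(smooths), cs)
        n_total = sum(sm.n_trans for sm in smooths)
        Sigma = sum(r * sm.n_trans for r, sm in zip(resids, smooths)) / n_total
        Sigma = _spd_floor(Sigma)

    if not converged:
        raise RuntimeError(
            f"constrained EM did not converge in {max_iter} iterations "
            f"(relative loglik change {delta:.2e})"
        )
    if spectral_radius(B) >= 1.0:
        warnings.warn("shared temporal matrix is non-stationary", stacklevel=2)
    m = group.size
    mus = {
        pid: np.linalg.solve(np.eye(p) - B, c)
        if spectral_radius(B) < 1.0
        else c
        for pid, c in zip(group.member_ids, cs)
    }
    K = np.linalg.inv(Sigma)
    return ConstrainedGroupFit(
        loglik=ll_prev,
        n_params=p * p + p * (p + 1) // 2 + p * m,
        B=B,
        K=0.5 * (K + K.T),
        mu=mus,
        convergence=Convergence(True, it, delta),
    )


def init_test(
    group: SeverityGroup,
    tol: float = 1e-6,
    max_iter: int = 500,
    keep_fits: bool = True,
) -> INITResult:
    """Run the invariance test on one severity-matched group.

    AIC = 2 * n_params - 2 * loglik for each model; the group is flagged
    heterogeneous iff the free model's AIC is strictly lower.
    """
    free = fit_group_free(group, tol=tol, max_iter=max_iter)
    constrained = fit_group_constrained(
        group, tol=tol, max_iter=max_iter, init_from=free
    )
    aic_het = 2.0 * free.n_params - 2.0 * free.loglik
    aic_hom = 2.0 * constrained.n_params - 2.0 * constrained.loglik
    return INITResult(
        group_id=group.severity,
        size=group.size,
        member_ids=group.member_ids,
        loglik_free=free.loglik,
        loglik_constrained=constrained.loglik,
        n_params_free=free.n_params,
        n_params_constrained=constrained.n_params,
        aic_het=aic_het,
        aic_hom=aic_hom,
        heterogeneous=bool(aic_het < aic_hom),
        free_fit=free if keep_fits else None,
        constrained_fit=constrained if keep_fits else None,
    )
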