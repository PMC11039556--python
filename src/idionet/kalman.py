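"""State-space kernel for Gaussian lag-1 VAR with missing observations.

The model is

    y_t = c + B y_{t-1} + eps_t,        eps_t ~ N(0, Sigma),
    y_1 ~ N(m0, P0),

with the p-variate state observed directly (no measurement noise). Missing
entries — a whole beep or individual variables — are marginalized by the
filter, so every observed value contributes to the likelihood (full
information maximum likelihood; no listwise deletion).

Two likelihood conventions are exposed:

* ``conditional=False`` (exact): the first time point contributes its density
  under the initial distribution, normally the stationary law of the process.
* ``conditional=True``: contributions start at t=2; the first point only
  informs the filter. With complete data this is the classical conditional
  likelihood of a VAR(1) given its first observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

_LOG2PI = float(np.log(2.0 * np.pi))


def spectral_radius(B: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(B))))


def stationary_covariance(B: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Solve the discrete Lyapunov equation P = B P B' + Sigma.

    Requires spectral radius of B strictly below 1.
    """
    if spectral_radius(B) >= 1.0:
        raise ValueError(
            "temporal matrix has spectral radius >= 1; "
            "no stationary covariance exists"
        )
    P = linalg.solve_discrete_lyapunov(B, Sigma)
    return 0.5 * (P + P.T)


@dataclass
class SmootherResult:
    """Smoothed first and second moments plus transition sufficient stats."""

    loglik: float
    means: np.ndarray          # (T, p) E[y_t | all observed data]
    covs: np.ndarray           # (T, p, p)
    # sums over transitions t = 2..T (1-based):
    S_yy: np.ndarray           # sum E[y_t y_t']
    S_yx: np.ndarray           # sum E[y_t y_{t-1}']
    S_xx: np.ndarray           # sum E[y_{t-1} y_{t-1}']
    S_y: np.ndarray            # sum E[y_t]
    S_x: np.ndarray            # sum E[y_{t-1}]
    n_trans: int


def _filter_pass(
    Y: np.ndarray,
    c: np.ndarray,
    B: np.ndarray,
    Sigma: np.ndarray,
    m0: np.ndarray,
    P0: np.ndarray,
    conditional: bool,
    store: bool,
):
    T, p = Y.shape
    obs = np.isfinite(Y)
    m = m0.copy()
    P = P0.copy()
    loglik = 0.0
    if store:
        m_filt = np.empty((T, p))
        P_filt = np.empty((T, p, p))
        m_pred = np.empty((T, p))
        P_pred = np.empty((T, p, p))
    for t in range(T):
        if store:
            m_pred[t] = m
            P_pred[t] = P
        o = obs[t]
        if o.any():
            yo = Y[t, o]
            mo = m[o]
            S = P[np.ix_(o, o)]
            # S is SPD: P carries at least one Sigma of process noise except
            # possibly at t=0, where P0 is the (SPD) initial covariance.
            L, low = linalg.cho_factor(S, lower=True)
            innov = yo - mo
            alpha = linalg.cho_solve((L, low), innov)
            k = int(o.sum())
            if not (conditional and t == 0):
                loglik -= 0.5 * (
                    k * _LOG2PI
                    + 2.0 * np.sum(np.log(np.diag(L)))
                    + float(innov @ alpha)
                )
            PH = P[:, o]
            m = m + PH @ alpha
            P = P - PH @ linalg.cho_solve((L, low), PH.T)
            P = 0.5 * (P + P.T)
        if store:
            m_filt[t] = m
            P_filt[t] = P
        if t < T - 1:
            m = c + B @ m
            P = B @ P @ B.T + Sigma
            P = 0.5 * (P + P.T)
    if store:
        return loglik, m_filt, P_filt, m_pred, P_pred
    return loglik


def kalman_loglik(
    Y: np.ndarray,
    c: np.ndarray,
    B: np.ndarray,
    Sigma: np.ndarray,
    m0: np.ndarray,
    P0: np.ndarray,
    conditional: bool = False,
) -> float:
    """Gaussian log-likelihood of the observed entries of ``Y``."""
    return _filter_pass(Y, c, B, Sigma, m0, P0, conditional, store=False)


def kalman_smoother(
    Y: np.ndarray,
    c: np.ndarray,
    B: np.ndarray,
    Sigma: np.ndarray,
    m0: np.ndarray,
    P0: np.ndarray,
    conditional: bool = True,
) -> SmootherResult:
    """Rauch–Tung–Striebel smoother with lag-one cross-covariances.

    Returns the smoothed moments of every grid slot together with the
    transition sufficient statistics needed by the EM M-step.
    """
    T, p = Y.shape
    loglik, m_filt, P_filt, m_pred, P_pred = _filter_pass(
        Y, c, B, Sigma, m0, P0, conditional, store=True
    )
    m_sm = np.empty((T, p))
    P_sm = np.empty((T, p, p))
    m_sm[-1] = m_filt[-1]
    P_sm[-1] = P_filt[-1]
    S_yy = np.zeros((p, p))
    S_yx = np.zeros((p, p))
    S_xx = np.zeros((p, p))
    S_y = np.zeros(p)
    S_x = np.zeros(p)
    for t in range(T - 2, -1, -1):
        # smoother gain J_t = P_t|t B' inv(P_{t+1|t}); P_{t+1|t} >= Sigma SPD
        J = linalg.cho_solve(
            linalg.cho_factor(P_pred[t + 1], lower=True),
            (P_filt[t] @ B.T).T,
        ).T
        m_sm[t] = m_filt[t] + J @ (m_sm[t + 1] - m_pred[t + 1])
        P_sm[t] = P_filt[t] + J @ (P_sm[t + 1] - P_pred[t + 1]) @ J.T
        P_sm[t] = 0.5 * (P_sm[t] + P_sm[t].T)
        C = P_sm[t + 1] @ J.T  # Cov(y_{t+1}, y_t | data)
        S_yy += P_sm[t + 1] + np.outer(m_sm[t + 1], m_sm[t + 1])
        S_yx += C + np.outer(m_sm[t + 1], m_sm[t])
        S_xx += P_sm[t] + np.outer(m_sm[t], m_sm[t])
        S_y += m_sm[t + 1]
        S_x += m_sm[t]
    return SmootherResult(
        loglik=loglik,
        means=m_sm,
        covs=P_sm,
        S_yy=0.5 * (S_yy + S_yy.T),
        S_yx=S_yx,
        S_xx=0.5 * (S_xx + S_xx.T),
        S_y=S_y,
        S_x=S_x,
        n_trans=T - 1,
    )
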