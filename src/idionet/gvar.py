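"""Person-specific graphical VAR estimation.

A graphical VAR (GVAR) summarizes one person's symptom dynamics with two
networks: the *temporal* network ``B`` (lag-1 regression coefficients — the
conditional effect of each variable on every variable one beep later) and the
*contemporaneous* network ``Omega`` (partial correlations of the innovations,
derived from the residual precision matrix ``K``).

Estimation here is full-information maximum likelihood. Missing beeps are
marginalized by the state-space filter in :mod:`idionet.kalman`; the fit is
an EM algorithm whose E-step is the Kalman smoother and whose M-step is the
closed-form seemingly-unrelated-regression update, so the objective is
monotone non-decreasing across iterations by construction. With complete data
the M-step is the exact conditional maximum-likelihood estimator (lag-pair
regression plus residual-precision MLE) and EM terminates at it immediately.

The fitted log-likelihood is the conditional likelihood given the first grid
slot (contributions from t >= 2); :func:`loglik_gvar` also evaluates the
exact likelihood with the first point scored under the stationary law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .kalman import (
    kalman_loglik,
    kalman_smoother,
    spectral_radius,
    stationary_covariance,
)
from .series import SymptomSeries

MIN_COMPLETED = 30          # hard floor for any fit
RECOMMENDED_COMPLETED = 75  # below this, estimates are warned as unstable


class SingularInformationError(ValueError):
    """Raised when the data cannot identify the model (e.g. constant column)."""


@dataclass
class Convergence:
    converged: bool
    n_iter: int
    final_delta: float  # relative loglik change at the last iteration
    message: str = ""


@dataclass
class GVARModel:
    """Fitted person-specific GVAR.

    ``B[i, j]`` is the effect of variable ``j`` at the previous beep on
    variable ``i`` now, partialled on all other lagged variables. ``K`` is
    the innovation precision; ``Omega`` its partial-correlation standardization.
    """

    mu: np.ndarray
    B: np.ndarray
    K: np.ndarray
    Omega: np.ndarray = field(init=False)
    loglik: float = np.nan
    n_params: int = 0
    convergence: Convergence | None = None
    columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        self.Omega = pcc_from_precision(self.K)

    @property
    def p(self) -> int:
        return self.mu.shape[0]

    @property
    def Sigma(self) -> np.ndarray:
        """Innovation covariance, the inverse of ``K``."""
        S = np.linalg.inv(self.K)
        return 0.5 * (S + S.T)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


def n_free_params(p: int) -> int:
    """Free parameters of an unregularized GVAR: means + B + precision."""
    return p + p * p + p * (p + 1) // 2


def pcc_from_precision(K: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix from a precision matrix.

    omega_ij = -k_ij / sqrt(k_ii k_jj) off the diagonal; unit diagonal.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("K must be symmetric")
    try:
        linalg.cho_factor(K)
    except linalg.LinAlgError as exc:
        raise ValueError("K must be positive definite") from exc
    d = np.sqrt(np.diag(K))
    Omega = -K / np.outer(d, d)
    np.fill_diagonal(Omega, 1.0)
    return 0.5 * (Omega + Omega.T)


def _values(series) -> np.ndarray:
    if isinstance(series, SymptomSeries):
        return series.values
    return np.asarray(series, dtype=float)


def _check_identifiable(Y: np.ndarray) -> None:
    obs = np.isfinite(Y)
    for j in range(Y.shape[1]):
        col = Y[obs[:, j], j]
        if col.size < 3 or np.var(col) < 1e-12:
            raise SingularInformationError(
                f"variable {j} is constant or nearly unobserved; "
                "the innovation precision is not identifiable"
            )


def _initial_params(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lag-pair least squares on mean-imputed data, stabilized."""
    T, p = Y.shape
    col_mean = np.nanmean(Y, axis=0)
    Z = np.where(np.isfinite(Y), Y, col_mean)
    X = np.column_stack([np.ones(T - 1), Z[:-1]])
    coef, *_ = np.linalg.lstsq(X, Z[1:], rcond=None)
    c = coef[0]
    B = coef[1:].T
    rho = spectral_radius(B)
    if rho >= 0.95:
        B = B * (0.9 / rho)
        c = col_mean - B @ col_mean
    resid = Z[1:] - X @ np.column_stack([c, B.T]).T
    Sigma = resid.T @ resid / max(T - 1 - (p + 1), 1)
    Sigma = 0.5 * (Sigma + Sigma.T)
    # ridge to guarantee a usable SPD start
    ev = np.linalg.eigvalsh(Sigma)
    floor = max(1e-6, 1e-4 * float(ev.max()))
    if ev.min() < floor:
        Sigma += (floor - ev.min()) * np.eye(p)
    return c, B, Sigma


def _init_prior(
    c: np.ndarray, B: np.ndarray, Sigma: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Initial state law: stationary if stable, else a diffuse fallback."""
    rho = spectral_radius(B)
    p = len(c)
    if rho < 0.999:
        mu = np.linalg.solve(np.eye(p) - B, c)
        P0 = stationary_covariance(B, Sigma)
        return mu, P0
    mu = c  # no stationary mean exists; weakly informative fallback
    return mu, Sigma * 100.0


def _spd_floor(Sigma: np.ndarray, rel: float = 1e-10) -> np.ndarray:
    Sigma = 0.5 * (Sigma + Sigma.T)
    ev = np.linalg.eigvalsh(Sigma)
    floor = rel * max(float(ev.max()), 1e-12)
    if ev.min() < floor:
        Sigma = Sigma + (floor - ev.min()) * np.eye(Sigma.shape[0])
    return Sigma


def fit_gvar_ml(
    series,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> GVARModel:
    """Fit an unregularized GVAR by FIML (EM with Kalman-smoother E-step).

    Parameters
    ----------
    series
        A :class:`~idionet.series.SymptomSeries` (typically detrended) or a
        raw ``(T, p)`` array with ``NaN`` for missing values.
    tol
        Convergence tolerance on the relative conditional log-likelihood
        change between EM iterations.
    max_iter
        Maximum EM iterations; exceeding it raises ``RuntimeError``.
    """
    Y = _values(series)
    columns = series.columns if isinstance(series, SymptomSeries) else ()
    T, p = Y.shape
    n_completed = int(np.isfinite(Y).any(axis=1).sum())
    if n_completed < MIN_COMPLETED:
        raise ValueError(
            f"only {n_completed} completed assessments; need >= {MIN_COMPLETED}"
        )
    if n_completed < RECOMMENDED_COMPLETED:
        warnings.warn(
            f"{n_completed} completed assessments is below the recommended "
            f"{RECOMMENDED_COMPLETED}; estimates may be unstable",
            stacklevel=2,
        )
    _check_identifiable(Y)

    c, B, Sigma = _initial_params(Y)
    ll_prev = -np.inf
    delta = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        m0, P0 = _init_prior(c, B, Sigma)
        sm = kalman_smoother(Y, c, B, Sigma, m0, P0, conditional=True)
        delta = abs(sm.loglik - ll_prev) / max(1.0, abs(sm.loglik))
        ll_prev = sm.loglik
        if delta < tol:
            converged = True
            break
        c, B, Sigma = _mstep_single(sm)
        Sigma = _spd_floor(Sigma)

    if not converged:
        raise RuntimeError(
            f"EM did not converge in {max_iter} iterations "
            f"(relative loglik change {delta:.2e})"
        )
    if spectral_radius(B) >= 1.0:
        warnings.warn(
            "fitted temporal matrix has spectral radius >= 1 "
            "(non-stationary estimate)",
            stacklevel=2,
        )
    mu = np.linalg.solve(np.eye(p) - B, c)
    K = np.linalg.inv(Sigma)
    model = GVARModel(
        mu=mu,
        B=B,
        K=0.5 * (K + K.T),
        loglik=ll_prev,
        n_params=n_free_params(p),
        convergence=Convergence(True, it, delta),
        columns=tuple(columns),
    )
    return model


def _mstep_single(sm) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = sm.n_trans
    Sxx_c = sm.S_xx - np.outer(sm.S_x, sm.S_x) / n
    Syx_c = sm.S_yx - np.outer(sm.S_y, sm.S_x) / n
    B = np.linalg.solve(Sxx_c.T, Syx_c.T).T
    c = (sm.S_y - B @ sm.S_x) / n
    Sigma = _residual_cov([sm], [B] * 1, [c])[0]
    return c, B, Sigma


def _residual_cov(smooths, Bs, cs) -> list[np.ndarray]:
    """Expected residual covariance per member at shared/own (B, c)."""
    out = []
    for sm, B, c in zip(smooths, Bs, cs):
        n = sm.n_trans
        S = (
            sm.S_yy
            - np.outer(sm.S_y, c)
            - np.outer(c, sm.S_y)
            + n * np.outer(c, c)
            - sm.S_yx @ B.T
            - B @ sm.S_yx.T
            + B @ np.outer(sm.S_x, c)
            + np.outer(c, sm.S_x) @ B.T
            + B @ sm.S_xx @ B.T
        )
        out.append(0.5 * (S + S.T) / n)
    return out


def loglik_gvar(model: GVARModel, series, conditional: bool = False) -> float:
    """Log-likelihood of the observed entries of ``series`` under ``model``.

    ``conditional=False`` scores the first grid slot under the stationary
    distribution (exact likelihood); ``conditional=True`` matches the fitting
    objective. Missing entries are marginalized either way.
    """
    Y = _values(series)
    if Y.shape[1] != model.p:
        raise ValueError("model dimension does not match series")
    Sigma = model.Sigma
    if spectral_radius(model.B) >= 1.0:
        raise ValueError("non-stationary model: no finite stationary covariance")
    P0 = stationary_covariance(model.B, Sigma)
    c = (np.eye(model.p) - model.B) @ model.mu
    return kalman_loglik(Y, c, model.B, Sigma, model.mu, P0, conditional=conditional)


# ---------------------------------------------------------------------------
# LASSO-regularized fit with BIC selection
# ---------------------------------------------------------------------------


@dataclass
class LassoPathEntry:
    lambda_B: float
    lambda_K: float
    model: GVARModel
    bic: float
    n_temporal_edges: int
    n_contemporaneous_edges: int
    converged: bool


@dataclass
class LassoPath:
    entries: list[LassoPathEntry]
    selected: LassoPathEntry

    @property
    def selected_model(self) -> GVARModel:
        return self.selected.model


def default_penalty_grid(
    Y: np.ndarray, n_lambda: int = 20, min_ratio: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced penalty grids from the empty-network penalty downward."""
    col_mean = np.nanmean(Y, axis=0)
    Z = np.where(np.isfinite(Y), Y, col_mean) - col_mean
    X, R = Z[:-1], Z[1:]
    lamB_max = float(np.max(np.abs(X.T @ R)))
    S = np.cov(R, rowvar=False)
    off = S - np.diag(np.diag(S))
    lamK_max = max(float(np.max(np.abs(off))), 1e-3)
    lamsB = np.geomspace(lamB_max, lamB_max * min_ratio, n_lambda)
    lamsK = np.geomspace(lamK_max, lamK_max * min_ratio, n_lambda)
    return lamsB, lamsK


def fit_gvar_lasso(
    series,
    lambdas_B: np.ndarray | None = None,
    lambdas_K: np.ndarray | None = None,
    n_lambda: int = 20,
    max_alt: int = 25,
    tol: float = 1e-4,
) -> LassoPath:
    """Sparse GVAR: L1-penalized temporal regression alternated with a
    graphical-lasso update of the innovation precision, selected by BIC.

    Missing beeps are handled by expectation steps: at each alternation the
    Kalman smoother at the current parameters supplies the expected values of
    the missing entries. BIC uses the conditional FIML log-likelihood with
    the number of observed beeps as the effective sample size.
    """
    from sklearn.covariance import graphical_lasso
    from sklearn.linear_model import Lasso

    Y = _values(series)
    columns = series.columns if isinstance(series, SymptomSeries) else ()
    T, p = Y.shape
    n_completed = int(np.isfinite(Y).any(axis=1).sum())
    if n_completed < MIN_COMPLETED:
        raise ValueError(
            f"only {n_completed} completed assessments; need >= {MIN_COMPLETED}"
        )
    _check_identifiable(Y)
    if lambdas_B is None or lambdas_K is None:
        gB, gK = default_penalty_grid(Y, n_lambda=n_lambda)
        lambdas_B = gB if lambdas_B is None else np.asarray(lambdas_B, float)
        lambdas_K = gK if lambdas_K is None else np.asarray(lambdas_K, float)

    c0, B0, Sigma0 = _initial_params(Y)
    has_missing = not np.isfinite(Y).all()
    n_eff = n_completed

    entries: list[LassoPathEntry] = []
    for lamB in np.asarray(lambdas_B, float):
        for lamK in np.asarray(lambdas_K, float):
            try:
                entry = _fit_one_penalty(
                    Y, lamB, lamK, c0, B0, Sigma0, has_missing,
                    n_eff, max_alt, tol, columns, Lasso, graphical_lasso,
                )
            except Exception as exc:  # noqa: BLE001 - per-point skip contract
                warnings.warn(
                    f"penalty point (lambda_B={lamB:.3g}, lambda_K={lamK:.3g}) "
                    f"failed and was skipped: {exc}",
                    stacklevel=2,
                )
                continue
            entries.append(entry)
    if not entries:
        raise RuntimeError("all penalty grid points failed")
    selected = min(entries, key=lambda e: e.bic)
    return LassoPath(entries=entries, selected=selected)


def _fit_one_penalty(
    Y, lamB, lamK, c, B, Sigma, has_missing, n_eff, max_alt, tol,
    columns, Lasso, graphical_lasso,
):
    T, p = Y.shape
    Z = np.where(np.isfinite(Y), Y, np.nanmean(Y, axis=0))
    mu = Z.mean(axis=0)
    for _ in range(max_alt):
        B_old = B.copy()
        if has_missing:
            m0, P0 = _init_prior(c, B, Sigma)
            sm = kalman_smoother(Y, c, B, Sigma, m0, P0)
            Z = np.where(np.isfinite(Y), Y, sm.means)
            mu = Z.mean(axis=0)
        Zc = Z - mu
        X, R = Zc[:-1], Zc[1:]
        n = X.shape[0]
        # our objective 0.5||r - Xb||^2 + lamB*||b||_1 == sklearn alpha=lamB/n
        las = Lasso(alpha=lamB / n, fit_intercept=False, max_iter=50_000)
        Bn = np.empty((p, p))
        for i in range(p):
            las.fit(X, R[:, i])
            Bn[i] = las.coef_
        B = Bn
        resid = R - X @ B.T
        emp = resid.T @ resid / n
        emp = _spd_floor(emp, rel=1e-8)
        cov, K = graphical_lasso(emp, alpha=lamK, max_iter=200)
        Sigma = 0.5 * (cov + cov.T)
        c = mu - B @ mu
        if np.max(np.abs(B - B_old)) < tol:
            break
    K = 0.5 * (K + K.T)
    model = GVARModel(mu=mu, B=B, K=K, columns=tuple(columns))
    if spectral_radius(B) < 1.0:
        ll = loglik_gvar(model, Y, conditional=True)
    else:
        m0, P0 = _init_prior(c, B, Sigma)
        ll = kalman_loglik(Y, c, B, Sigma, m0, P0, conditional=True)
    nz_B = int(np.count_nonzero(np.abs(B) > 1e-8))
    nz_K = int(np.count_nonzero(np.abs(np.triu(K, 1)) > 1e-8))
    df = p + nz_B + p + nz_K  # means, temporal edges, variances, partials
    bic = -2.0 * ll + np.log(n_eff) * df
    model.loglik = ll
    model.n_params = df
    return LassoPathEntry(
        lambda_B=float(lamB),
        lambda_K=float(lamK),
        model=model,
        bic=float(bic),
        n_temporal_edges=nz_B,
        n_contemporaneous_edges=nz_K,
        converged=True,
    )
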