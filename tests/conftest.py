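import numpy as np
import pytest

from idionet.series import StudyDesign
from idionet.simulate import (
    MissingnessSpec,
    TrueGVAR,
    generate_precision_matrix,
    generate_stable_temporal_matrix,
    simulate_series,
)


@pytest.fixture(scope="session")
def truth6() -> TrueGVAR:
    """A fixed sparse stable 6-variable ground-truth model."""
    B = generate_stable_temporal_matrix(6, density=0.3, max_abs=0.4, seed=1)
    K = generate_precision_matrix(6, density=0.3, seed=2)
    mu = np.random.default_rng(3).uniform(30.0, 70.0, size=6)
    return TrueGVAR(mu=mu, B=B, K=K)


@pytest.fixture(scope="session")
def complete_series(truth6):
    """One participant, full 140-beep grid, no missingness."""
    return simulate_series(
        truth6, missing=MissingnessSpec(0.0), seed=10, participant_id="c01"
    )


@pytest.fixture(scope="session")
def missing_series(truth6):
    """One participant at the study's conditions: 18% beeps dropped MCAR."""
    return simulate_series(
        truth6, missing=MissingnessSpec(0.18), seed=11, participant_id="m01"
    )


@pytest.fixture(scope="session")
def small_design() -> StudyDesign:
    """A shorter grid (two weeks) used where full length is not the point."""
    return StudyDesign(n_days=14, beeps_per_day=5)


def conditional_ml_oracle(Y: np.ndarray):
    """Closed-form complete-data conditional ML for a VAR(1) with intercept.

    Lag-pair least squares plus the residual covariance MLE; the independent
    reference fit_gvar_ml must reproduce on complete data.
    """
    T, p = Y.shape
    X = np.column_stack([np.ones(T - 1), Y[:-1]])
    coef, *_ = np.linalg.lstsq(X, Y[1:], rcond=None)
    c, B = coef[0], coef[1:].T
    resid = Y[1:] - X @ coef
    Sigma = resid.T @ resid / (T - 1)
    mu = np.linalg.solve(np.eye(p) - B, c)
    from scipy.stats import multivariate_normal

    ll = float(
        sum(
            multivariate_normal.logpdf(Y[t], c + B @ Y[t - 1], Sigma)
            for t in range(1, T)
        )
    )
    return mu, B, Sigma, ll


def bruteforce_joint_loglik(mu, B, Sigma, Y):
    """Exact log-density of the observed entries via the full T*p joint
    Gaussian of the stationary VAR(1) — independent of the Kalman code path."""
    from scipy.linalg import solve_discrete_lyapunov
    from scipy.stats import multivariate_normal

    T, p = Y.shape
    G0 = solve_discrete_lyapunov(B, Sigma)
    pows = [np.linalg.matrix_power(B, k) for k in range(T)]
    Cov = np.zeros((T * p, T * p))
    for t in range(T):
        for s in range(T):
            blk = pows[t - s] @ G0 if t >= s else G0 @ pows[s - t].T
            Cov[t * p : (t + 1) * p, s * p : (s + 1) * p] = blk
    mean = np.tile(mu, T)
    obs = np.isfinite(Y.ravel())
    return float(
        multivariate_normal.logpdf(
            Y.ravel()[obs], mean[obs], Cov[np.ix_(obs, obs)]
        )
    )
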