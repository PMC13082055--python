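"""Per-feature Firth bias-corrected quasi-Poisson null model.

One null model per feature — intercept plus confounders, with a log-depth
offset and no covariate of interest — is fitted once and then reused for
score-statistic inference against arbitrarily many covariates.  The mean
model is ``mu_i = N_i * exp(x_i' theta)`` with quasi-Poisson variance
``phi * mu_i``; the dispersion ``phi`` never needs to be estimated because
all downstream uncertainty flows through the empirical sandwich.

The Firth correction adds ``h_i / 2`` (half the hat-matrix leverage) to the
score residual, which bias-reduces the estimates and keeps boundary cases
such as all-zero features finite:

    sum_i (Y_i - mu_i + h_i / 2) x_i = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)

#: convergence tolerances: max |score| and relative coefficient step
SCORE_TOL = 1e-8
STEP_TOL = 1e-10
MAX_ITER = 100
#: relative condition guard on the Cholesky pivots of X'WX
COND_GUARD = 1e12


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is (numerically) rank deficient — collinear columns."""


def _chol_solve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """SPD solve with a relative condition guard instead of explicit inversion."""
    try:
        c, low = linalg.cho_factor(a, lower=True)
    except linalg.LinAlgError as err:
        raise RankDeficientError(f"design leads to singular information matrix: {err}")
    d = np.diag(c)
    if d.min() <= 0 or (d.max() / d.min()) ** 2 > COND_GUARD:
        raise RankDeficientError("information matrix numerically singular (collinear columns?)")
    return linalg.cho_solve((c, low), b)


def hat_diagonals(mu: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Leverages h_i = mu_i * x_i' (X'WX)^{-1} x_i with W = diag(mu).

    These are the diagonal elements of the weighted projection matrix
    H = W^{1/2} X (X'WX)^{-1} X' W^{1/2}; they satisfy 0 <= h_i <= 1 and
    sum to the column rank of the design.
    """
    mu = np.asarray(mu, dtype=float)
    design = np.asarray(design, dtype=float)
    if (mu <= 0).any():
        raise ValueError("fitted means must be positive")
    xtwx = (design * mu[:, None]).T @ design
    sol = _chol_solve(xtwx, design.T)  # (q, n)
    return mu * np.einsum("ij,ji->i", design, sol)


@dataclass
class NullFit:
    """Converged (or flagged) null fit for a single feature."""

    theta_null: np.ndarray
    mu_null: np.ndarray
    hat_diag: np.ndarray
    design_null: np.ndarray
    offset: np.ndarray
    counts: np.ndarray
    converged: bool
    iterations: int

    @property
    def residuals(self) -> np.ndarray:
        """Firth-adjusted score residuals Y_i - mu_i + h_i/2."""
        return self.counts - self.mu_null + 0.5 * self.hat_diag


def _firth_score(theta, y, design, offset, firth):
    eta = offset + design @ theta
    mu = np.exp(eta)
    h = hat_diagonals(mu, design) if firth else 0.0
    resid = y - mu + 0.5 * h
    return design.T @ resid, mu


def fit_null(
    counts_k: np.ndarray,
    depths: np.ndarray,
    confounders: np.ndarray | None = None,
    *,
    firth: bool = True,
    max_iter: int = MAX_ITER,
) -> NullFit:
    """Fit the Firth quasi-Poisson null model for one feature.

    Parameters
    ----------
    counts_k
        Integer read counts Y_ik of the feature across samples.
    depths
        Sequencing depths N_i (the offset is log N_i).
    confounders
        Optional n x q_c matrix; an intercept is always prepended.
    firth
        Disable to obtain the ordinary quasi-Poisson root (testing hook).

    Notes
    -----
    Newton iterations with step-halving on score-norm increase.  The
    intercept start ``log((sum Y + q0/2) / sum N)`` is the exact fixed
    point for the intercept-only model, so degenerate features converge
    immediately.  With an intercept present the converged fit satisfies
    ``sum mu = sum Y + q0/2``.
    """
    y = np.asarray(counts_k, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if (depths <= 0).any():
        raise ValueError("depths must be positive")
    n = y.shape[0]
    if confounders is None or np.size(confounders) == 0:
        design = np.ones((n, 1))
    else:
        confounders = np.asarray(confounders, dtype=float)
        if confounders.ndim == 1:
            confounders = confounders[:, None]
        design = np.column_stack([np.ones(n), confounders])
    q0 = design.shape[1]
    if n < q0 + 1:
        raise ValueError(f"need at least {q0 + 1} samples for a rank-{q0} null design")
    if np.linalg.matrix_rank(design) < q0:
        raise RankDeficientError("null design (intercept + confounders) is rank deficient")
    offset = np.log(depths)

    theta = np.zeros(q0)
    theta[0] = np.log((y.sum() + (q0 / 2 if firth else 0.0)) / depths.sum())

    score, mu = _firth_score(theta, y, design, offset, firth)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        info = (design * mu[:, None]).T @ design
        try:
            step = _chol_solve(info, score)
        except RankDeficientError:
            raise
        norm0 = np.linalg.norm(score)
        for _ in range(30):
            candidate = theta + step
            with np.errstate(over="raise"):
                try:
                    new_score, new_mu = _firth_score(candidate, y, design, offset, firth)
                except FloatingPointError:
                    step = step / 2
                    continue
            if np.linalg.norm(new_score) <= norm0 or np.max(np.abs(step)) < STEP_TOL:
                break
            step = step / 2
        else:
            break
        rel_step = np.max(np.abs(step) / np.maximum(np.abs(theta), 1.0))
        theta, score, mu = candidate, new_score, new_mu
        if rel_step < STEP_TOL:
            converged = np.max(np.abs(score)) < SCORE_TOL * 1e4
            break
    else:
        converged = np.max(np.abs(score)) < SCORE_TOL

    if np.max(np.abs(score)) < SCORE_TOL:
        converged = True
    if not converged:
        logger.info("null fit did not converge (score norm %.3g after %d iterations)",
                    np.linalg.norm(score), it)

    h = hat_diagonals(mu, design)
    return NullFit(
        theta_null=theta,
        mu_null=mu,
        hat_diag=h,
        design_null=design,
        offset=offset,
        counts=y,
        converged=bool(converged),
        iterations=it,
    )
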