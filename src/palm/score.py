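"""Score-statistic effect estimation and robust sandwich variances.

Given a per-feature null fit, the relative-abundance (RA) level effect of a
covariate X is estimated from the quasi-score evaluated at the null:

    beta* = I1^{-1} S1(theta~),   I1 = I11 - I10 I00^{-1} I01,

where the quasi-information ``I = sum_i mu_i z_i z_i'`` over the full design
``z_i = (X_i, x_i)`` is partitioned into the covariate block and the
nuisance (intercept + confounder) block.  This avoids refitting the model
per covariate: one null fit serves an entire covariate scan.

Variances are model-robust sandwich estimates built from the per-sample
(or per-cluster) efficient score contributions
``U_i = S1_i - I10 I00^{-1} S0_i``; the Firth ``h/2`` term stays inside
the residual when forming the contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nullfit import NullFit, _chol_solve

#: relative floor on the effective information (covariate in the span of
#: the null design, or constant, falls below it)
INFO_REL_TOL = 1e-10


class DegenerateCovariateError(ValueError):
    """Covariate carries no information orthogonal to the null design."""


@dataclass
class FeatureSummaryRA:
    """RA-level summary for one (feature, covariate) pair."""

    feature_id: str
    beta_star: float
    var_star: float
    info_eff: float


def _score_pieces(fit: NullFit, covariate: np.ndarray):
    """Common intermediates: residuals, I blocks, projected covariate."""
    x = np.asarray(covariate, dtype=float)
    if x.shape != fit.mu_null.shape:
        raise ValueError("covariate length does not match fit")
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate contains non-finite values")
    mu = fit.mu_null
    xd = fit.design_null
    i11 = float(mu @ x**2)
    i10 = (mu * x) @ xd                      # (q0,)
    i00 = (xd * mu[:, None]).T @ xd
    gamma = _chol_solve(i00, i10)            # I00^{-1} I01
    info_eff = i11 - float(i10 @ gamma)
    if info_eff <= INFO_REL_TOL * max(i11, 1.0):
        raise DegenerateCovariateError(
            "effective information is numerically zero: covariate is constant "
            "or lies in the span of the null design"
        )
    resid = fit.residuals
    # per-sample efficient score contributions U_i
    u = resid * (x - xd @ gamma)
    return u, info_eff


def score_effect(fit: NullFit, covariate: np.ndarray) -> tuple[float, float, float]:
    """Score-statistic estimate of the RA-level effect.

    Returns ``(beta_star, info_eff, score_S1)``; ``beta_star`` is the
    one-step approximation ``S1 / I1`` to the full quasi-score root.
    """
    if not fit.converged:
        raise ValueError("null fit did not converge")
    x = np.asarray(covariate, dtype=float)
    u, info_eff = _score_pieces(fit, x)
    s1 = float(fit.residuals @ x)
    return s1 / info_eff, info_eff, s1


def sandwich_independent(fit: NullFit, covariate: np.ndarray) -> float:
    """Sandwich variance of beta* for independent samples."""
    u, info_eff = _score_pieces(fit, covariate)
    return float(u @ u) / info_eff**2


def sandwich_clustered(
    fit: NullFit, covariate: np.ndarray, cluster_ids: np.ndarray
) -> float:
    """Sandwich variance with per-cluster summed score contributions.

    Reduces exactly to the independent estimator when every sample is its
    own cluster.  No small-cluster-count correction is applied.
    """
    u, info_eff = _score_pieces(fit, covariate)
    cluster_ids = np.asarray(cluster_ids)
    if cluster_ids.shape != u.shape:
        raise ValueError("cluster_ids length does not match fit")
    _, inverse = np.unique(cluster_ids, return_inverse=True)
    cluster_sums = np.bincount(inverse, weights=u)
    return float(cluster_sums @ cluster_sums) / info_eff**2


def score_scan(
    fits: dict[str, NullFit],
    covariates: np.ndarray,
    cluster_ids: np.ndarray | None = None,
) -> list[list[FeatureSummaryRA | None]]:
    """Scan many covariates against per-feature null fits.

    ``covariates`` is n x M; the output is one list per covariate column,
    each with one entry per feature (None where the pair failed — failures
    are per-pair, never global).  Results are bitwise identical to the
    single-call path.
    """
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    out: list[list[FeatureSummaryRA | None]] = []
    for m in range(covariates.shape[1]):
        x = covariates[:, m]
        col: list[FeatureSummaryRA | None] = []
        for feature_id, fit in fits.items():
            try:
                beta, info_eff, _ = score_effect(fit, x)
                if cluster_ids is None:
                    var = sandwich_independent(fit, x)
                else:
                    var = sandwich_clustered(fit, x, cluster_ids)
                col.append(FeatureSummaryRA(feature_id, beta, var, info_eff))
            except (ValueError, np.linalg.LinAlgError):
                col.append(None)
        out.append(col)
    return out
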