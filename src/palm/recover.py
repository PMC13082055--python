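"""Recover absolute-abundance effects from relative-abundance effects.

Relative-abundance effects differ from the absolute-abundance (AA) effects
by a single compositional shift common to every feature — induced by the
covariate's association with total microbial load.  Under the sparsity
assumption that most features carry no AA effect, that shift is estimated
by the median of the RA-level effects and subtracted:

    beta_k = beta_k* - median_k{beta_k*}.

The variance is calibrated for the extra variability of the median,

    V_k = V_k* + K / (4 * (sum_j (2 pi V_j*)^{-1/2})^2),

which in the equal-variance case reduces to the classical asymptotic
variance ``pi V / (2K)`` of a normal sample median.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

#: below this many features the sparsity assumption behind the median is
#: fragile; a warning is logged (configurable via recover_aa)
SMALL_K_FLOOR = 20


def compositional_shift(beta_stars: np.ndarray) -> float:
    """Median of RA-level effects: the estimated compositional shift.

    The median is robust to the minority of truly differential features.
    For an even number of features it is the midpoint of the two central
    order statistics.
    """
    b = np.asarray(beta_stars, dtype=float)
    if b.ndim != 1 or b.size < 2:
        raise ValueError("compositional correction undefined for fewer than 2 features")
    if not np.all(np.isfinite(b)):
        raise ValueError("non-finite effect estimate")
    return float(np.median(b))


def median_variance_term(var_stars: np.ndarray) -> float:
    """Additive variance calibration for the variability of the median."""
    v = np.asarray(var_stars, dtype=float)
    if (v <= 0).any():
        raise ValueError("all RA-level variances must be positive")
    k = v.size
    dens = np.sum(1.0 / np.sqrt(2.0 * np.pi * v))
    return k / (4.0 * dens**2)


def recover_aa(
    beta_stars: np.ndarray,
    var_stars: np.ndarray,
    *,
    small_k_floor: int = SMALL_K_FLOOR,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Convert RA-level summaries to AA-level summaries for one study.

    Returns ``(beta_hat, var_hat, shift)``.  The correction is computed
    over exactly the features that produced valid RA summaries in this
    study; the calibration term is identical for all of them.
    """
    b = np.asarray(beta_stars, dtype=float)
    v = np.asarray(var_stars, dtype=float)
    if b.shape != v.shape:
        raise ValueError("effect and variance vectors differ in length")
    shift = compositional_shift(b)
    if b.size < small_k_floor:
        logger.warning(
            "only %d features contribute to the compositional median; the "
            "sparse-signal assumption may be fragile", b.size,
        )
    term = median_variance_term(v)
    return b - shift, v + term, shift
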