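"""Fixed-effect meta-analysis, Cochran's Q heterogeneity, BH correction.

Per-study AA-level summary statistics (effect, calibrated variance) are
pooled by inverse-variance weighting under a fixed-effect model; the
association test statistic ``Q = beta_meta^2 / V_meta`` is referred to a
chi-square with one degree of freedom.  Between-study heterogeneity is
assessed with Cochran's Q, and both p-value families receive their own
Benjamini-Hochberg pass over features.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import SummaryStatsTable

logger = logging.getLogger(__name__)


def fixed_effect_meta(betas: np.ndarray, variances: np.ndarray):
    """Inverse-variance pooled effect for one feature.

    Returns ``(beta_meta, var_meta, q_stat, p_value)`` with
    ``beta_meta = sum(b/V) / sum(1/V)``, ``var_meta = 1 / sum(1/V)`` and
    the chi-square(1) upper-tail p-value of ``beta_meta^2 / var_meta``.
    """
    b = np.asarray(betas, dtype=float)
    v = np.asarray(variances, dtype=float)
    if b.size == 0:
        raise ValueError("no studies contribute to this feature")
    if (v <= 0).any():
        raise ValueError("variances must be positive")
    w = 1.0 / v
    var_meta = 1.0 / w.sum()
    beta_meta = float((b * w).sum() * var_meta)
    q_stat = beta_meta**2 / var_meta
    return beta_meta, float(var_meta), float(q_stat), float(stats.chi2.sf(q_stat, df=1))


def cochran_q(betas: np.ndarray, variances: np.ndarray, beta_meta: float):
    """Cochran's Q heterogeneity test for one feature.

    ``Q = sum_l (b_l - beta_meta)^2 / V_l`` on ``L - 1`` degrees of
    freedom; requires at least two contributing studies.
    """
    b = np.asarray(betas, dtype=float)
    v = np.asarray(variances, dtype=float)
    if b.size < 2:
        raise ValueError("heterogeneity requires at least 2 studies")
    q = float(((b - beta_meta) ** 2 / v).sum())
    df = b.size - 1
    return q, df, float(stats.chi2.sf(q, df=df))


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN entries stay NaN.

    ``q_(i) = min_{j >= i} m p_(j) / j`` capped at 1, returned in the
    original order.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    q = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    qs = np.empty(m)
    qs[order] = q
    out[mask] = qs
    return out


def run_meta(
    stats_tables: list[SummaryStatsTable],
    fdr_level: float = 0.05,
    het_q_level: float = 0.1,
) -> pd.DataFrame:
    """Assemble per-feature meta-analysis results across studies.

    A feature contributes from exactly the studies whose summary table
    reports it.  Output columns: ``feature_id, beta_meta, var_meta,
    q_stat, p_value, q_value, n_studies, het_Q, het_df, het_p, het_q,
    significant, heterogeneous``.  Discoveries are flagged at
    ``q_value <= fdr_level`` and heterogeneous features at
    ``het_q < het_q_level``; heterogeneity fields are absent (NaN) for
    single-study features.
    """
    if not stats_tables:
        raise ValueError("need at least one summary-statistics table")
    per_feature: dict[str, list[tuple[float, float]]] = {}
    feature_order: list[str] = []
    for st in stats_tables:
        seen = set()
        for row in st.table.itertuples(index=False):
            fid = str(row.feature_id)
            if fid in seen:
                raise ValueError(f"feature {fid!r} appears twice in study {st.study_id!r}")
            seen.add(fid)
            if fid not in per_feature:
                per_feature[fid] = []
                feature_order.append(fid)
            per_feature[fid].append((float(row.beta_hat), float(row.var_hat)))
    feature_order.sort()

    rows = []
    for fid in feature_order:
        pairs = per_feature[fid]
        b = np.array([p[0] for p in pairs])
        v = np.array([p[1] for p in pairs])
        beta_meta, var_meta, q_stat, p_value = fixed_effect_meta(b, v)
        if b.size >= 2:
            het_Q, het_df, het_p = cochran_q(b, v, beta_meta)
        else:
            het_Q, het_df, het_p = np.nan, np.nan, np.nan
        rows.append(
            dict(feature_id=fid, beta_meta=beta_meta, var_meta=var_meta,
                 q_stat=q_stat, p_value=p_value, n_studies=b.size,
                 het_Q=het_Q, het_df=het_df, het_p=het_p)
        )
    table = pd.DataFrame(rows)
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table["het_q"] = bh_adjust(table["het_p"].to_numpy())
    table["significant"] = table["q_value"] <= fdr_level
    table["heterogeneous"] = table["het_q"] < het_q_level
    cols = ["feature_id", "beta_meta", "var_meta", "q_stat", "p_value", "q_value",
            "n_studies", "het_Q", "het_df", "het_p", "het_q",
            "significant", "heterogeneous"]
    return table[cols]
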