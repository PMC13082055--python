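"""Per-study pipeline: counts + design -> AA-level summary statistics."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_io import CountTable, StudyDesign, SummaryStatsTable, filter_prevalence
from .nullfit import fit_null, RankDeficientError
from .recover import recover_aa
from .score import (
    DegenerateCovariateError,
    sandwich_clustered,
    sandwich_independent,
    score_effect,
)

logger = logging.getLogger(__name__)


def fit_study(
    table: CountTable,
    design: StudyDesign,
    prev_threshold: float = 0.0,
) -> SummaryStatsTable:
    """Produce the study's AA-level summary-statistics table.

    Steps: drop zero-depth samples; apply the within-study prevalence
    filter (depths stay fixed at the pre-filter row sums); per feature, fit
    the Firth quasi-Poisson null model, form the score-statistic effect and
    its sandwich variance (clustered if the design carries cluster labels);
    finally apply the compositional median shift and variance calibration
    over the features that produced valid RA-level summaries.

    Features that fail to fit or converge are absent from the output and so
    drop out of any downstream meta-analysis for this study.
    """
    if design.n_samples != table.n_samples:
        raise ValueError("design and count table disagree on sample count")
    keep = table.depths > 0
    if not keep.all():
        table = table.drop_zero_depth()
        design = StudyDesign(
            covariate=design.covariate[keep],
            confounders=None if design.confounders is None else design.confounders[keep],
            cluster_ids=None if design.cluster_ids is None else design.cluster_ids[keep],
            study_id=design.study_id,
        )
    if np.ptp(design.covariate) == 0:
        raise DegenerateCovariateError("covariate is constant")
    table = filter_prevalence(table, prev_threshold)
    prevalence = table.prevalence()

    feature_ids: list[str] = []
    betas: list[float] = []
    variances: list[float] = []
    for j, fid in enumerate(table.feature_ids):
        y = table.counts[:, j]
        try:
            fit = fit_null(y, table.depths, design.confounders)
        except RankDeficientError:
            raise
        if not fit.converged:
            logger.info("feature %s: null fit did not converge; excluded", fid)
            continue
        try:
            beta_star, _, _ = score_effect(fit, design.covariate)
            if design.cluster_ids is None:
                var_star = sandwich_independent(fit, design.covariate)
            else:
                var_star = sandwich_clustered(fit, design.covariate, design.cluster_ids)
        except (DegenerateCovariateError, ValueError) as err:
            logger.info("feature %s: %s; excluded", fid, err)
            continue
        if not np.isfinite(beta_star) or not np.isfinite(var_star) or var_star <= 0:
            logger.info("feature %s: degenerate sandwich variance; excluded", fid)
            continue
        feature_ids.append(fid)
        betas.append(beta_star)
        variances.append(var_star)

    beta_hat, var_hat, shift = recover_aa(np.array(betas), np.array(variances))
    prev_map = dict(zip(table.feature_ids, prevalence))
    out = pd.DataFrame(
        dict(
            feature_id=feature_ids,
            beta_hat=beta_hat,
            var_hat=var_hat,
            n_samples=table.n_samples,
            prevalence=[prev_map[f] for f in feature_ids],
            converged=True,
        )
    )
    logger.info(
        "study %s: %d/%d features summarised (compositional shift %.4g)",
        design.study_id, len(feature_ids), table.n_features, shift,
    )
    return SummaryStatsTable(study_id=design.study_id, table=out)
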