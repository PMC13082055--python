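"""Data model and I/O: count tables, study designs, summary-statistics exchange.

Count tables are plain delimited text (TSV/CSV) with a header row and a
first column of identifiers, in either orientation.  Summary statistics are
exchanged as a fixed tab-delimited dialect so that studies can share
AA-level effect estimates without sharing individual-level data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "study_id",
    "feature_id",
    "beta_hat",
    "var_hat",
    "n_samples",
    "prevalence",
    "converged",
]


@dataclass
class CountTable:
    """Integer read counts for one study, samples x features.

    ``depths`` holds per-sample sequencing depths N_i.  When not supplied by
    the user they are the row sums of ``counts``; they are computed before
    any prevalence filtering so that filtering never changes model offsets.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    counts: np.ndarray
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-d matrix (samples x features)")
        n, k = self.counts.shape
        if len(self.sample_ids) != n or len(self.feature_ids) != k:
            raise ValueError("identifier lengths do not match count matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample identifiers")
        if len(set(self.feature_ids)) != k:
            raise ValueError("duplicate feature identifiers")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.rint(self.counts)
            if not np.allclose(self.counts, as_int, rtol=0, atol=0):
                raise ValueError("counts must be integers (count model); refusing to round")
            self.counts = as_int.astype(np.int64)
        if (self.counts < 0).any():
            i, k_ = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[k_]!r}"
            )
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.depths.shape != (n,):
            raise ValueError("depths must have one entry per sample")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def prevalence(self) -> np.ndarray:
        """Per-feature fraction of samples with a non-zero count."""
        return (self.counts > 0).mean(axis=0)

    def drop_zero_depth(self) -> "CountTable":
        """Remove samples whose depth is zero (with a logged warning)."""
        keep = self.depths > 0
        if keep.all():
            return self
        dropped = [s for s, k in zip(self.sample_ids, keep) if not k]
        logger.warning("dropping %d zero-depth sample(s): %s", len(dropped), dropped)
        return CountTable(
            sample_ids=[s for s, k in zip(self.sample_ids, keep) if k],
            feature_ids=list(self.feature_ids),
            counts=self.counts[keep],
            depths=self.depths[keep],
        )

    def select_samples(self, sample_ids: list[str]) -> "CountTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples not in count table: {missing[:5]}")
        rows = [idx[s] for s in sample_ids]
        return CountTable(
            sample_ids=list(sample_ids),
            feature_ids=list(self.feature_ids),
            counts=self.counts[rows],
            depths=self.depths[rows],
        )


@dataclass
class StudyDesign:
    """Covariate of interest, confounders and optional cluster labels."""

    covariate: np.ndarray
    confounders: np.ndarray | None = None
    cluster_ids: np.ndarray | None = None
    study_id: str = "study"

    def __post_init__(self) -> None:
        self.covariate = np.asarray(self.covariate, dtype=float)
        if self.covariate.ndim != 1:
            raise ValueError("covariate must be a vector")
        if not np.all(np.isfinite(self.covariate)):
            raise ValueError("covariate contains non-finite values")
        n = self.covariate.shape[0]
        if self.confounders is not None:
            self.confounders = np.asarray(self.confounders, dtype=float)
            if self.confounders.size == 0:
                self.confounders = None
            else:
                if self.confounders.ndim == 1:
                    self.confounders = self.confounders[:, None]
                if self.confounders.shape[0] != n:
                    raise ValueError("confounder rows must match covariate length")
        if self.cluster_ids is not None:
            self.cluster_ids = np.asarray(self.cluster_ids)
            if self.cluster_ids.shape != (n,):
                raise ValueError("cluster_ids must have one entry per sample")

    @property
    def n_samples(self) -> int:
        return self.covariate.shape[0]

    def null_design(self) -> np.ndarray:
        """Intercept + confounders: the design of the covariate-free null model."""
        n = self.n_samples
        cols = [np.ones(n)]
        if self.confounders is not None:
            cols.append(self.confounders)
        return np.column_stack(cols)


@dataclass
class SummaryStatsTable:
    """AA-level per-feature summary statistics for one study.

    Membership defines which studies contribute a feature to the
    meta-analysis: features that failed to fit or converge are absent.
    """

    study_id: str
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = [c for c in SUMMARY_COLUMNS if c != "study_id"]
        if self.table.empty and not set(required) <= set(self.table.columns):
            self.table = pd.DataFrame(columns=required)
        missing = set(required) - set(self.table.columns)
        if missing:
            raise ValueError(f"summary table missing column(s): {sorted(missing)}")
        if len(self.table):
            if self.table["feature_id"].duplicated().any():
                dupes = self.table.loc[self.table["feature_id"].duplicated(), "feature_id"]
                raise ValueError(f"duplicate feature identifiers: {list(dupes)[:5]}")
            if (self.table["var_hat"] <= 0).any():
                bad = self.table.loc[self.table["var_hat"] <= 0, "feature_id"]
                raise ValueError(f"non-positive var_hat for feature(s): {list(bad)[:5]}")
        self.table = self.table.reset_index(drop=True)


def _read_delimited(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_count_table(
    path,
    orientation: str = "samples_as_rows",
    depths: np.ndarray | None = None,
) -> CountTable:
    """Read a delimited count table into samples x features orientation.

    Parameters
    ----------
    path
        TSV/CSV file with a header row and first column of identifiers.
    orientation
        ``samples_as_rows`` or ``features_as_rows``.
    depths
        Optional user-supplied sequencing depths (overrides row sums).
    """
    if orientation not in ("samples_as_rows", "features_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_delimited(path)
    if orientation == "features_as_rows":
        df = df.T
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any():
        i, k = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell {df.iat[i, k]!r} at row {df.index[i]!r}, "
            f"column {df.columns[k]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, k = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"missing cell at row {df.index[i]!r}, column {df.columns[k]!r}")
    mat = numeric.to_numpy()
    if (mat < 0).any():
        i, k = np.argwhere(mat < 0)[0]
        raise ValueError(
            f"negative count {mat[i, k]} at row {df.index[i]!r}, column {df.columns[k]!r}"
        )
    counts = np.asarray(mat)
    if depths is None:
        depths = counts.sum(axis=1)
    table = CountTable(
        sample_ids=list(df.index),
        feature_ids=list(df.columns),
        counts=counts,
        depths=np.asarray(depths),
    )
    if (table.depths == 0).any():
        zero = [s for s, d in zip(table.sample_ids, table.depths) if d == 0]
        logger.warning("sample(s) with zero depth flagged for removal: %s", zero)
    return table


def read_metadata(
    path,
    covariate: str,
    confounders: list[str] | None = None,
    cluster: str | None = None,
    depth: str | None = None,
    study_id: str = "study",
) -> tuple[pd.DataFrame, StudyDesign, np.ndarray | None]:
    """Read a per-sample metadata table keyed by sample identifier.

    Returns the raw frame (indexed by sample id), the StudyDesign built from
    the named columns, and the user-supplied depth vector (or None).
    """
    df = _read_delimited(path)
    for col in [covariate, *(confounders or []), *( [cluster] if cluster else []),
                *([depth] if depth else [])]:
        if col not in df.columns:
            raise KeyError(f"metadata column {col!r} not found")
    design = StudyDesign(
        covariate=df[covariate].to_numpy(dtype=float),
        confounders=df[list(confounders)].to_numpy(dtype=float) if confounders else None,
        cluster_ids=df[cluster].to_numpy() if cluster else None,
        study_id=study_id,
    )
    depth_vec = df[depth].to_numpy(dtype=np.int64) if depth else None
    return df, design, depth_vec


def filter_prevalence(table: CountTable, threshold: float) -> CountTable:
    """Keep features with prevalence >= threshold (inclusive boundary).

    Prevalence is the within-study fraction of samples with a non-zero
    count.  Depths are left untouched: they were fixed from the full table.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    keep = table.prevalence() >= threshold
    return CountTable(
        sample_ids=list(table.sample_ids),
        feature_ids=[f for f, k in zip(table.feature_ids, keep) if k],
        counts=table.counts[:, keep],
        depths=table.depths,
    )


def filter_prevalence_pooled(
    tables: list[CountTable], threshold: float
) -> list[CountTable]:
    """Filter on prevalence pooled across all samples of several studies.

    The alternative to within-study filtering: a feature is kept in every
    study if its non-zero fraction over the union of samples reaches the
    threshold (inclusive).  All tables must share the same feature set.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if not tables:
        return []
    feature_ids = tables[0].feature_ids
    for t in tables[1:]:
        if t.feature_ids != feature_ids:
            raise ValueError("pooled filtering requires identical feature sets")
    nonzero = sum((t.counts > 0).sum(axis=0) for t in tables)
    total = sum(t.n_samples for t in tables)
    keep = nonzero / total >= threshold
    return [
        CountTable(
            sample_ids=list(t.sample_ids),
            feature_ids=[f for f, k in zip(feature_ids, keep) if k],
            counts=t.counts[:, keep],
            depths=t.depths,
        )
        for t in tables
    ]


def rank_inverse_normal(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom (3/8) offset.

    Maps value i to ``Phi^{-1}((r_i - 3/8) / (n + 1/4))`` where r_i is its
    mid-rank; ties map to equal outputs.  Standard normalisation for skewed
    quantitative covariates such as metabolite concentrations.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        raise ValueError("all values identical: degenerate covariate")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))


def write_summary_stats(summary: SummaryStatsTable, path) -> None:
    """Write the tab-delimited summary-statistics exchange format."""
    out = summary.table.copy()
    out.insert(0, "study_id", summary.study_id)
    out["converged"] = out["converged"].astype(bool)
    # shortest round-trip representation (>= 12 significant digits when needed)
    out.to_csv(path, sep="\t", index=False, float_format=lambda v: repr(float(v)))


def read_summary_stats(path) -> SummaryStatsTable:
    """Read the exchange format back; validates columns and variances."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary file missing column(s): {sorted(missing)}")
    study_ids = df["study_id"].unique()
    if len(study_ids) > 1:
        raise ValueError(f"multiple study ids in one file: {list(study_ids)}")
    study_id = str(study_ids[0]) if len(study_ids) else "study"
    table = df.drop(columns=["study_id"]).copy()
    table["feature_id"] = table["feature_id"].astype(str)
    table["converged"] = table["converged"].astype(bool)
    return SummaryStatsTable(study_id=study_id, table=table)
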