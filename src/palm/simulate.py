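"""Self-contained synthetic multi-study microbiome generator.

Emulates the statistical structure of a multi-study spike-in benchmark:
per-study baseline mean proportion vectors with a few abundant features and
a long tail of rare ones; a shared set of "active" features whose
proportions are multiplied by random fold changes in one of two equally
sized groups (homogeneous absolute-abundance effects across studies);
multinomial count generation with per-sample Dirichlet overdispersion;
log-normal sequencing depths with optional group-wise depth doubling; and
an optional mixing step that turns independent samples into correlated
within-cluster pairs.

Ground truth: the AA-level log effect of an active feature is
``sign * log(fold)``, and exactly 0 for every other feature — even though
renormalisation shifts the relative abundances of all features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .data_io import CountTable, StudyDesign

#: stream offsets so that adding a study never perturbs earlier ones
_BASELINE_STREAM = 1
_ACTIVE_STREAM = 2
_STUDY_STREAM = 10


@dataclass
class SimConfig:
    """Configuration of a simulated meta-analysis experiment.

    Defaults follow the genus-level, large-sample benchmark layout:
    five studies of 100..180 samples, K = 92 features, 10% active
    features with fold changes Uniform(1, 5), balanced effect signs and
    even depths.
    """

    n_studies: int = 5
    sample_sizes: tuple[int, ...] = (100, 120, 140, 160, 180)
    n_features: int = 92
    pi_active: float = 0.1
    max_fold: float = 5.0
    effect_direction: str = "balanced"      # balanced | positive
    depth_scheme: str = "even"              # even | uneven
    depth_log_mean: float = 9.5
    depth_log_sd: float = 0.5
    depth_min: int = 2000
    abundance_threshold: float = 1e-3
    baseline_log_sd: float = 2.5
    dirichlet_scale: float = 50.0
    correlated: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sample_sizes) != self.n_studies:
            raise ValueError("one sample size per study required")
        if not 0 < self.pi_active < 0.5:
            raise ValueError("pi_active must lie in (0, 0.5)")
        if self.max_fold <= 1:
            raise ValueError("max_fold must exceed 1")
        if any(n % 2 for n in self.sample_sizes):
            raise ValueError("sample sizes must be even (two equal groups)")
        if not 0 < self.abundance_threshold < 1:
            raise ValueError("abundance_threshold must lie in (0, 1)")
        if self.effect_direction not in ("balanced", "positive"):
            raise ValueError("effect_direction must be 'balanced' or 'positive'")
        if self.depth_scheme not in ("even", "uneven"):
            raise ValueError("depth_scheme must be 'even' or 'uneven'")

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "sample_sizes" in raw:
            raw["sample_sizes"] = tuple(raw["sample_sizes"])
        return cls(**raw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    active_idx: np.ndarray                  # indices of active features
    folds: np.ndarray                       # fold change per active feature
    signs: np.ndarray                       # +1 / -1 per active feature
    baselines: list[np.ndarray] = field(default_factory=list)
    group_means: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def true_log_effects(self, n_features: int) -> np.ndarray:
        """AA-level log effect per feature: sign*log(fold) if active, else 0."""
        eff = np.zeros(n_features)
        eff[self.active_idx] = self.signs * np.log(self.folds)
        return eff


def make_baseline(n_features: int, rng: np.random.Generator,
                  log_sd: float = 2.5) -> np.ndarray:
    """Baseline mean proportion vector: normalised exp of iid normal draws.

    The log-normal profile yields a few abundant features with the bulk of
    the mass, and a long tail of rare features — the canonical shape of
    taxonomic profiles.
    """
    if n_features < 2:
        raise ValueError("need at least 2 features")
    log_abund = rng.normal(0.0, log_sd, size=n_features)
    mu = np.exp(log_abund - log_abund.max())
    return mu / mu.sum()


def choose_active(
    mu: np.ndarray,
    pi_active: float,
    threshold: float,
    rng: np.random.Generator,
    effect_direction: str = "balanced",
) -> tuple[np.ndarray, np.ndarray]:
    """Pick active features: half abundant, half rare; draw their signs.

    ``round(pi_active * K)`` features total, ``floor(m/2)`` from the
    stratum with mean proportion >= threshold and the remainder from its
    complement.
    """
    mu = np.asarray(mu, dtype=float)
    k = mu.size
    m = int(round(pi_active * k))
    n_abundant = m // 2
    n_rare = m - n_abundant
    abundant = np.flatnonzero(mu >= threshold)
    rare = np.flatnonzero(mu < threshold)
    if abundant.size < n_abundant:
        raise ValueError(
            f"abundant stratum has {abundant.size} features, need {n_abundant}")
    if rare.size < n_rare:
        raise ValueError(f"rare stratum has {rare.size} features, need {n_rare}")
    chosen = np.concatenate([
        rng.choice(abundant, size=n_abundant, replace=False),
        rng.choice(rare, size=n_rare, replace=False),
    ])
    chosen.sort()
    if effect_direction == "positive":
        signs = np.ones(m)
    else:
        signs = rng.choice([-1.0, 1.0], size=m)
    return chosen, signs


def spike_in(
    mu: np.ndarray,
    active_idx: np.ndarray,
    folds: np.ndarray,
    signs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Multiply active features' proportions by their folds, renormalise.

    Positive effects inflate group 1, negative effects inflate group 0;
    both group vectors are renormalised to sum to one, which shifts the
    relative abundance of every feature while the AA-level truth of
    non-active features stays exactly zero.
    """
    mu0 = np.asarray(mu, dtype=float).copy()
    mu1 = mu0.copy()
    active_idx = np.asarray(active_idx, dtype=int)
    pos = np.asarray(signs) > 0
    mu1[active_idx[pos]] *= np.asarray(folds)[pos]
    mu0[active_idx[~pos]] *= np.asarray(folds)[~pos]
    return mu0 / mu0.sum(), mu1 / mu1.sum()


def _draw_depths(n: int, rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    d = rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd, size=n)
    return np.maximum(np.rint(d).astype(np.int64), cfg.depth_min)


def simulate_study(
    mu0: np.ndarray,
    mu1: np.ndarray,
    n: int,
    rng: np.random.Generator,
    cfg: SimConfig,
    study_id: str = "study",
) -> tuple[CountTable, StudyDesign]:
    """Generate one study: two equal groups of Dirichlet-multinomial counts.

    Per sample the composition is drawn ``Dirichlet(phi * mu_g)`` with the
    configured overdispersion scale ``phi`` and counts
    ``Multinomial(N_i, p_i)``.  Under the uneven depth scheme the depths of
    one randomly picked group are doubled.
    """
    if n % 2:
        raise ValueError("sample size must be even")
    half = n // 2
    x = np.repeat([0, 1], half)
    depths = _draw_depths(n, rng, cfg)
    if cfg.depth_scheme == "uneven":
        boosted = rng.integers(0, 2)
        depths = np.where(x == boosted, depths * 2, depths)
    k = mu0.size
    counts = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        mu_g = mu1 if x[i] == 1 else mu0
        p = rng.dirichlet(cfg.dirichlet_scale * mu_g)
        counts[i] = rng.multinomial(depths[i], p)
    table = CountTable(
        sample_ids=[f"{study_id}_s{i}" for i in range(n)],
        feature_ids=[f"feat{j}" for j in range(k)],
        counts=counts,
        depths=depths,
    )
    design = StudyDesign(covariate=x.astype(float), study_id=study_id)
    return table, design


def make_correlated(
    table: CountTable,
    design: StudyDesign,
    rng: np.random.Generator,
    mu0: np.ndarray,
    mu1: np.ndarray,
    cfg: SimConfig,
) -> tuple[CountTable, StudyDesign]:
    """Mix paired samples with a fresh draw to induce within-cluster correlation.

    Samples are paired within group into clusters; each member Y_it is
    replaced by ``round((Y_i* + Y_it) / 2)`` where Y_i* is an extra
    independent sample from the same group (rounding half to even so counts
    stay integral).  Depths are recomputed as row sums.
    """
    x = design.covariate
    counts = table.counts.copy()
    n = counts.shape[0]
    cluster = np.empty(n, dtype=int)
    next_cluster = 0
    for g in (0, 1):
        members = np.flatnonzero(x == g)
        if members.size % 2:
            raise ValueError("group size must be divisible by 2 for pairing")
        mu_g = mu1 if g == 1 else mu0
        for j in range(0, members.size, 2):
            pair = members[j:j + 2]
            depth_star = _draw_depths(1, rng, cfg)[0]
            p = rng.dirichlet(cfg.dirichlet_scale * mu_g)
            y_star = rng.multinomial(depth_star, p)
            for idx in pair:
                counts[idx] = np.rint((counts[idx] + y_star) / 2.0).astype(np.int64)
                cluster[idx] = next_cluster
            next_cluster += 1
    new_table = CountTable(
        sample_ids=list(table.sample_ids),
        feature_ids=list(table.feature_ids),
        counts=counts,
        depths=counts.sum(axis=1),
    )
    new_design = StudyDesign(
        covariate=x, confounders=design.confounders,
        cluster_ids=cluster, study_id=design.study_id,
    )
    return new_table, new_design


def simulate_meta_experiment(
    cfg: SimConfig,
) -> tuple[list[tuple[CountTable, StudyDesign]], SimTruth]:
    """Generate a full multi-study experiment with shared ground truth.

    The active set, fold changes and signs are drawn once and applied to
    every study (homogeneous effects); baselines are study-specific.  Fully
    reproducible from the config's seed; per-study RNG streams are derived
    from it by fixed offsets so adding a study never changes earlier ones.
    """
    baselines = [
        make_baseline(
            cfg.n_features,
            np.random.default_rng([cfg.seed, _BASELINE_STREAM, s]),
            cfg.baseline_log_sd,
        )
        for s in range(cfg.n_studies)
    ]
    mean_mu = np.mean(baselines, axis=0)
    rng_active = np.random.default_rng([cfg.seed, _ACTIVE_STREAM])
    active_idx, signs = choose_active(
        mean_mu, cfg.pi_active, cfg.abundance_threshold, rng_active,
        cfg.effect_direction,
    )
    folds = rng_active.uniform(1.0, cfg.max_fold, size=active_idx.size)
    truth = SimTruth(active_idx=active_idx, folds=folds, signs=signs,
                     baselines=baselines)
    studies = []
    for s, (mu, n) in enumerate(zip(baselines, cfg.sample_sizes)):
        mu0, mu1 = spike_in(mu, active_idx, folds, signs)
        truth.group_means.append((mu0, mu1))
        rng = np.random.default_rng([cfg.seed, _STUDY_STREAM + s])
        table, design = simulate_study(mu0, mu1, n, rng, cfg, study_id=f"study{s}")
        if cfg.correlated:
            table, design = make_correlated(table, design, rng, mu0, mu1, cfg)
        studies.append((table, design))
    return studies, truth
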