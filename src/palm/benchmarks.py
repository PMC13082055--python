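"""Reproducible evaluation protocols on synthetic multi-study data.

These drive both the test suite and the reproduction script: a spike-in
benchmark measuring empirical FDR, power and spurious heterogeneity of the
full pipeline, and a global-null experiment collecting meta-analysis
p-values.  Study conditions follow the genus-level, large-sample benchmark
layout of :class:`palm.simulate.SimConfig`; analyses apply the external
20% within-study prevalence filter that precedes differential-abundance
testing in this protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meta import run_meta
from .pipeline import fit_study
from .simulate import SimConfig, make_baseline, simulate_meta_experiment, simulate_study

PREV_FILTER = 0.2


@dataclass
class SpikeInResult:
    fdp: list[float]
    power: list[float]
    het_fraction: list[float]

    @property
    def fdr(self) -> float:
        """Mean false-discovery proportion over replicates."""
        return float(np.mean(self.fdp))

    def fdr_mc_se(self) -> float:
        return float(np.std(self.fdp, ddof=1) / np.sqrt(len(self.fdp)))


def spike_in_benchmark(
    seed: int,
    n_replicates: int = 50,
    fdr_level: float = 0.05,
    config_kwargs: dict | None = None,
) -> SpikeInResult:
    """Run the five-study spike-in benchmark and score it against truth.

    Per replicate: simulate the meta-experiment, fit every study, pool with
    the fixed-effect meta-analysis, call discoveries at BH
    ``q <= fdr_level``, and record the false-discovery proportion, power
    over active features and the fraction of features flagged
    heterogeneous (Cochran het_q < 0.1).
    """
    res = SpikeInResult([], [], [])
    for rep in range(n_replicates):
        cfg = SimConfig(seed=int(seed) * 100_000 + rep, **(config_kwargs or {}))
        studies, truth = simulate_meta_experiment(cfg)
        stats = [fit_study(t, d, prev_threshold=PREV_FILTER) for t, d in studies]
        meta = run_meta(stats, fdr_level=fdr_level)
        active = {f"feat{j}" for j in truth.active_idx}
        discovered = set(meta.loc[meta["significant"], "feature_id"])
        false_disc = len(discovered - active)
        res.fdp.append(false_disc / max(len(discovered), 1))
        res.power.append(len(discovered & active) / len(active))
        res.het_fraction.append(float(meta["heterogeneous"].mean()))
    return res


def null_meta_pvalues(seed: int, min_features: int = 2000) -> np.ndarray:
    """Meta-analysis p-values under the global null (no spiked features).

    Five studies per replicate with study-specific baselines and even
    depths; replicates accumulate until at least ``min_features``
    feature-level p-values are collected.
    """
    cfg = SimConfig(seed=int(seed))
    pvals: list[float] = []
    rep = 0
    while len(pvals) < min_features:
        stats = []
        for s in range(cfg.n_studies):
            mu = make_baseline(
                cfg.n_features,
                np.random.default_rng([seed, 900 + rep, 1, s]),
                cfg.baseline_log_sd,
            )
            table, design = simulate_study(
                mu, mu, cfg.sample_sizes[s],
                np.random.default_rng([seed, 900 + rep, 2, s]),
                cfg, study_id=f"null{rep}_s{s}",
            )
            stats.append(fit_study(table, design, prev_threshold=PREV_FILTER))
        meta = run_meta(stats)
        pvals.extend(meta["p_value"].tolist())
        rep += 1
    return np.asarray(pvals)


def recovery_experiment(
    seed: int, n_replicates: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Bias of recovered AA effects at n = 200 per study, 10% active.

    Returns per-replicate mean error of active features' pooled effects
    against ``sign * log(fold)`` and per-replicate mean pooled effect of
    inactive features (whose truth is 0).
    """
    active_bias, inactive_mean = [], []
    for rep in range(n_replicates):
        cfg = SimConfig(
            n_studies=3, sample_sizes=(200, 200, 200),
            seed=int(seed) * 50_000 + rep,
        )
        studies, truth = simulate_meta_experiment(cfg)
        stats = [fit_study(t, d, prev_threshold=PREV_FILTER) for t, d in studies]
        meta = run_meta(stats).set_index("feature_id")
        eff = truth.true_log_effects(cfg.n_features)
        active = [f"feat{j}" for j in truth.active_idx]
        errs = [
            meta.loc[f, "beta_meta"] - eff[int(f[4:])]
            for f in active if f in meta.index
        ]
        inact = [
            meta.loc[f, "beta_meta"]
            for f in meta.index if f not in active
        ]
        active_bias.append(float(np.mean(errs)))
        inactive_mean.append(float(np.mean(inact)))
    return np.asarray(active_bias), np.asarray(inactive_mean)
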