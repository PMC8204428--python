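"""Synthetic RRBS dataset generator.

Produces site x sample depth/methylation matrices with the hallmarks of
real RRBS data: bimodal methylation (site means massed below 0.05 and
above 0.95), long-tailed negative-binomial read depths, a "core" subset
of enrichment-favoured sites covered in every sample at elevated depth,
and patchy coverage elsewhere.  An optional two-group effect spikes a
methylation difference into a subset of sites so that detection methods
can be benchmarked against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import RRBSDataset
from .nb import NBDepthModel, sample_depths

__all__ = ["GeneratorConfig", "GroupEffect", "GeneratorTruth", "generate"]


@dataclass(frozen=True)
class GroupEffect:
    """A spiked-in between-group difference at a fraction of sites."""

    delta: float
    fraction_affected: float
    group_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_affected <= 1.0:
            raise ValueError("fraction_affected must be in [0, 1]")
        if len(set(self.group_labels)) != 2:
            raise ValueError("group_labels must have exactly 2 levels")


@dataclass(frozen=True)
class GeneratorConfig:
    """Defaults mirror a large rodent-brain RRBS cohort: 125 libraries,
    heavily dispersed depth (r = 1.5) around a mean of 30, ~49%/50% of
    sites essentially un/fully methylated, and a 20% core of sites
    covered in every sample."""

    n_sites: int = 50_000
    n_samples: int = 125
    depth_mu: float = 30.0
    depth_r: float = 1.5
    core_fraction: float = 0.20
    core_depth_boost: float = 2.0
    dropout: float = 0.3
    meth_mix: tuple[float, float, float] = (0.49, 0.01, 0.50)
    group_effect: GroupEffect | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.meth_mix), 1.0):
            raise ValueError("meth_mix weights must sum to 1")
        if any(w < 0 for w in self.meth_mix):
            raise ValueError("meth_mix weights must be non-negative")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ValueError("core_fraction must be in [0, 1]")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        if self.n_sites < 1 or self.n_samples < 1:
            raise ValueError("need at least one site and one sample")
        if self.group_effect is not None and len(
            self.group_effect.group_labels
        ) != self.n_samples:
            raise ValueError("group_labels length must equal n_samples")


@dataclass
class GeneratorTruth:
    """Ground truth retained for recovery tests."""

    site_means: np.ndarray  # (n_sites,) mixture-drawn true methylation
    core_sites: np.ndarray  # boolean (n_sites,)
    affected_sites: np.ndarray  # boolean (n_sites,), all False without effect
    group_labels: list[str] | None
    config: GeneratorConfig = field(repr=False, default=None)


def _draw_site_means(
    n: int, weights: tuple[float, float, float], rng: np.random.Generator
) -> np.ndarray:
    """Three-component mixture: low [0, 0.05), mid [0.05, 0.95], high (0.95, 1]."""
    component = rng.choice(3, size=n, p=np.asarray(weights))
    u = rng.uniform(size=n)
    lo = np.array([0.0, 0.05, 0.95])
    hi = np.array([0.05, 0.95, 1.0])
    return lo[component] + u * (hi[component] - lo[component])


def generate(config: GeneratorConfig) -> tuple[RRBSDataset, GeneratorTruth]:
    """Generate one synthetic dataset plus its ground-truth record.

    Core sites draw depth from NB(boost * depth_mu, depth_r) truncated at
    >= 1 in every sample; the remainder draw untruncated NB(depth_mu,
    depth_r) depths (natural zeros) and additionally lose each point
    with probability ``dropout``.  Methylated read counts are binomial
    around the site mean, shifted by the group effect where spiked.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_sites, config.n_samples

    site_means = _draw_site_means(n, config.meth_mix, rng)
    n_core = int(round(config.core_fraction * n))
    core = np.zeros(n, dtype=bool)
    core[rng.choice(n, size=n_core, replace=False)] = True

    depth = np.zeros((n, m), dtype=np.int64)
    if n_core:
        core_model = NBDepthModel(
            mu=config.core_depth_boost * config.depth_mu, r=config.depth_r
        )
        depth[core] = sample_depths(core_model, 0, 1, rng, size=(n_core, m))
    n_rest = n - n_core
    if n_rest:
        p_nb = config.depth_r / (config.depth_r + config.depth_mu)
        rest = rng.negative_binomial(config.depth_r, p_nb, size=(n_rest, m))
        rest[rng.uniform(size=(n_rest, m)) < config.dropout] = 0
        depth[~core] = rest

    p_cell = np.broadcast_to(site_means[:, None], (n, m)).copy()
    affected = np.zeros(n, dtype=bool)
    labels: list[str] | None = None
    if config.group_effect is not None:
        eff = config.group_effect
        labels = list(eff.group_labels)
        n_aff = int(round(eff.fraction_affected * n))
        affected[rng.choice(n, size=n_aff, replace=False)] = True
        levels = sorted(set(labels))
        group_b = np.asarray(labels) == levels[1]
        p_cell[np.ix_(affected, group_b)] = np.clip(
            p_cell[np.ix_(affected, group_b)] + eff.delta, 0.0, 1.0
        )

    meth_counts = rng.binomial(depth, p_cell)
    with np.errstate(invalid="ignore"):
        meth = np.where(depth > 0, meth_counts / np.maximum(depth, 1), np.nan)

    site_ids = [("chr1", 1_000 + 50 * i) for i in range(n)]
    sample_ids = [f"s{j + 1:0{len(str(m))}d}" for j in range(m)]
    data = RRBSDataset(
        site_ids=site_ids, sample_ids=sample_ids, depth=depth, meth=meth
    )
    truth = GeneratorTruth(
        site_means=site_means,
        core_sites=core,
        affected_sites=affected,
        group_labels=labels,
        config=config,
    )
    return data, truth
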