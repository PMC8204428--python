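"""Study-level power prediction for a two-group bisulfite-sequencing study.

Given an unfiltered RRBS dataset, the expected between-group methylation
difference, and the filtering thresholds the analyst intends to apply
(minimum read depth per point, minimum number of points per site), the
predictor works in four stages:

1. estimate the NB read-depth parameters (mu, r) and the distribution of
   site-mean methylation — summarised as the probabilities of a filtered
   site falling in [0, 0.05), [0.05, 0.95] or (0.95, 1] — from random
   site subsets of the data;
2. simulate many filtered DNAm sites: the first ``min_points`` points
   per group are guaranteed to survive the read-depth filter (truncated
   NB at mean max(mu, rd_filter)), while the rest draw ordinary NB
   depths and are masked when below the filter;
3. Welch-test each simulated site and bootstrap the p-values up to the
   number of real sites surviving the same filter;
4. report power at the Bonferroni threshold alpha / n_sites_remaining,
   taking the median over independent iterations (single iterations can
   produce outliers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import RRBSDataset, filter_dataset
from .nb import NBDepthModel, estimate_r, sample_depths
from .site_sim import welch_p_values

__all__ = [
    "StudyPowerConfig",
    "DNAmPriors",
    "StudyPowerResult",
    "estimate_study_parameters",
    "simulate_filtered_site",
    "predict_power",
    "qq_check",
]


@dataclass(frozen=True)
class StudyPowerConfig:
    delta: float
    min_points: int
    rd_filter: int
    pheno: tuple[str, ...] | None = None
    n_sim_sites: int = 40_000
    r_subset: int = 60_000
    prior_subset: int = 100_000
    alpha: float = 0.05
    n_iterations: int = 5
    seed: int = 0
    pooled_priors: bool = False  # read-pooled site means instead of unweighted

    def __post_init__(self) -> None:
        if not 0.0 < self.delta <= 1.0:
            raise ValueError("delta must be in (0, 1]")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2 (a t-test needs 2 per group)")
        if self.rd_filter < 1:
            raise ValueError("rd_filter must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass(frozen=True)
class DNAmPriors:
    """Probability that a filtered site's mean methylation is low/mid/high."""

    p_low: float  # [0, 0.05)
    p_mid: float  # [0.05, 0.95]
    p_high: float  # (0.95, 1]

    def __post_init__(self) -> None:
        total = self.p_low + self.p_mid + self.p_high
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"prior probabilities sum to {total}, not 1")
        if min(self.p_low, self.p_mid, self.p_high) < 0:
            raise ValueError("prior probabilities must be non-negative")

    def sample_site_means(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw site means: pick a range by prior, then uniform within it."""
        component = rng.choice(
            3, size=n, p=[self.p_low, self.p_mid, self.p_high]
        )
        u = rng.uniform(size=n)
        lo = np.array([0.0, 0.05, 0.95])
        hi = np.array([0.05, 0.95, 1.0])
        return lo[component] + u * (hi[component] - lo[component])


@dataclass(frozen=True)
class StudyPowerResult:
    power: float  # median over iterations
    mean_power: float
    per_iteration_powers: tuple[float, ...]
    n_sites_remaining: int
    bonferroni_threshold: float
    estimated_r: float
    estimated_mean_depth: float
    priors: DNAmPriors
    group_sizes: tuple[int, int]
    config: StudyPowerConfig = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "power": self.power,
            "mean_power": self.mean_power,
            "per_iteration_powers": list(self.per_iteration_powers),
            "n_sites_remaining": self.n_sites_remaining,
            "bonferroni_threshold": self.bonferroni_threshold,
            "estimated_r": self.estimated_r,
            "estimated_mean_depth": self.estimated_mean_depth,
            "priors": {
                "p_low": self.priors.p_low,
                "p_mid": self.priors.p_mid,
                "p_high": self.priors.p_high,
            },
            "group_sizes": list(self.group_sizes),
        }


def _group_sizes(n_samples: int, pheno: Sequence[str] | None) -> tuple[int, int]:
    if pheno is None:
        return (n_samples // 2, n_samples - n_samples // 2)
    levels = sorted(set(pheno))
    if len(levels) != 2:
        raise ValueError(f"pheno must have exactly 2 levels, got {levels}")
    pheno_arr = np.asarray(list(pheno))
    return (int((pheno_arr == levels[0]).sum()), int((pheno_arr == levels[1]).sum()))


def _site_means(sub: RRBSDataset, pooled: bool) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if pooled:
            meth_reads = np.where(sub.covered, sub.meth * sub.depth, 0.0).sum(axis=1)
            totals = sub.depth.sum(axis=1)
            return meth_reads / totals
        return np.nanmean(sub.meth, axis=1)


def estimate_study_parameters(
    data: RRBSDataset, config: StudyPowerConfig, rng: np.random.Generator
) -> tuple[NBDepthModel, DNAmPriors, tuple[int, int]]:
    """Estimate (depth model, methylation priors, group sizes) from the data.

    The depth model is fit by pooling unmasked depths over a random site
    subset of size min(r_subset, n_sites).  The priors come from an
    independent random subset of size min(prior_subset, n_sites): the
    configured filter is applied, each surviving site's mean methylation
    is computed over its unmasked points, and the three ranges are
    tallied.  Group sizes come from ``pheno`` or split the samples in
    half.
    """
    if data.n_samples < 2 * config.min_points:
        raise ValueError(
            f"dataset has {data.n_samples} samples but 2 x min_points = "
            f"{2 * config.min_points} are required"
        )
    n = data.n_sites
    r_idx = rng.choice(n, size=min(config.r_subset, n), replace=False)
    sub = data.subset_sites(r_idx)
    pooled_depths = sub.depth[sub.covered]
    model = estimate_r(pooled_depths)

    prior_idx = rng.choice(n, size=min(config.prior_subset, n), replace=False)
    prior_sub = data.subset_sites(prior_idx)
    filtered, _ = filter_dataset(
        prior_sub, config.rd_filter, config.min_points, config.pheno
    )
    if filtered.n_sites == 0:
        raise ValueError("filters remove all sites in the prior subset")
    means = _site_means(filtered, config.pooled_priors)
    priors = DNAmPriors(
        p_low=float(np.mean(means < 0.05)),
        p_mid=float(np.mean((means >= 0.05) & (means <= 0.95))),
        p_high=float(np.mean(means > 0.95)),
    )
    return model, priors, _group_sizes(data.n_samples, config.pheno)


def _simulate_study_p_values(
    model: NBDepthModel,
    priors: DNAmPriors,
    config: StudyPowerConfig,
    group_sizes: tuple[int, int],
    n_sites: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised simulation of ``n_sites`` filtered sites -> Welch p-values.

    Per group, the first ``min_points`` points survive filtering by
    construction (truncated NB at mean max(mu, rd_filter)); the rest
    draw plain NB depths, masked where below the filter.  Sites left
    with < 2 points in a group are non-significant by convention (p=1).
    """
    n1, n2 = group_sizes
    if min(n1, n2) < config.min_points:
        raise ValueError(
            f"group sizes {group_sizes} cannot supply min_points={config.min_points}"
        )
    mu_high = max(model.mu, float(config.rd_filter))
    high_model = NBDepthModel(mu=mu_high, r=model.r)
    p_nb = model.r / (model.r + model.mu)

    site_mu = priors.sample_site_means(n_sites, rng)
    p_groups = (site_mu, np.clip(site_mu + config.delta, 0.0, 1.0))

    stats_per_group = []
    for n_g, p_meth in zip((n1, n2), p_groups):
        depth = np.zeros((n_sites, n_g), dtype=np.int64)
        depth[:, : config.min_points] = sample_depths(
            high_model, 0, config.rd_filter, rng, size=(n_sites, config.min_points)
        )
        n_rest = n_g - config.min_points
        if n_rest:
            rest = rng.negative_binomial(model.r, p_nb, size=(n_sites, n_rest))
            rest[rest < config.rd_filter] = 0
            depth[:, config.min_points :] = rest
        meth_counts = rng.binomial(depth, p_meth[:, None])
        usable = depth > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = np.where(usable, meth_counts / np.maximum(depth, 1), np.nan)
        k = usable.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.nansum(prop, axis=1) / k
            sq = np.nansum((prop - mean[:, None]) ** 2, axis=1)
            var = sq / np.maximum(k - 1, 1)
        stats_per_group.append((mean, var, k))

    (ma, va, ka), (mb, vb, kb) = stats_per_group
    ok = (ka >= 2) & (kb >= 2)
    p = np.ones(n_sites)
    p[ok] = welch_p_values(ma[ok], va[ok], ka[ok], mb[ok], vb[ok], kb[ok])
    return p


def simulate_filtered_site(
    model: NBDepthModel,
    priors: DNAmPriors,
    config: StudyPowerConfig,
    group_sizes: tuple[int, int],
    rng: np.random.Generator,
) -> float:
    """One filtered-site p-value (scalar convenience over the bulk path)."""
    return float(
        _simulate_study_p_values(model, priors, config, group_sizes, 1, rng)[0]
    )


def predict_power(data: RRBSDataset, config: StudyPowerConfig) -> StudyPowerResult:
    """Predict whole-study power under the configured filtering.

    Runs ``n_iterations`` independent rounds of parameter estimation and
    simulation, bootstraps each round's p-values up to the number of real
    sites surviving the filter, and reports the median power at the
    Bonferroni threshold alpha / n_sites_remaining.
    """
    rng = np.random.default_rng(config.seed)
    _, report = filter_dataset(data, config.rd_filter, config.min_points, config.pheno)
    n_remaining = report.n_sites_after
    if n_remaining == 0:
        raise ValueError("filters remove all sites from the dataset")
    threshold = config.alpha / n_remaining

    powers = []
    model = priors = group_sizes = None
    for _ in range(config.n_iterations):
        model, priors, group_sizes = estimate_study_parameters(data, config, rng)
        p = _simulate_study_p_values(
            model, priors, config, group_sizes, config.n_sim_sites, rng
        )
        boot = rng.choice(p, size=n_remaining, replace=True)
        powers.append(float(np.mean(boot < threshold)))

    return StudyPowerResult(
        power=float(np.median(powers)),
        mean_power=float(np.mean(powers)),
        per_iteration_powers=tuple(powers),
        n_sites_remaining=n_remaining,
        bonferroni_threshold=threshold,
        estimated_r=model.r,
        estimated_mean_depth=model.mu,
        priors=priors,
        group_sizes=group_sizes,
        config=config,
    )


def qq_check(
    data: RRBSDataset,
    model: NBDepthModel,
    priors: DNAmPriors,
    n: int,
    rng: np.random.Generator,
    n_quantiles: int = 101,
) -> dict:
    """Paired quantiles of simulated vs real depth and methylation.

    Samples ``n`` real unmasked points and ``n`` simulated points
    (zero-truncated NB depth; binomial methylation around prior-drawn
    site means) and returns their matched quantile tables, flagging a
    warning when the simulated 95th-percentile depth deviates from the
    real one by more than 25% (the NB tail is known to understate very
    high depths).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    covered_idx = np.flatnonzero(data.covered.ravel())
    if n > covered_idx.size:
        raise ValueError(
            f"requested {n} points but only {covered_idx.size} are available"
        )
    pick = rng.choice(covered_idx, size=n, replace=False)
    real_depth = data.depth.ravel()[pick]
    real_meth = data.meth.ravel()[pick]

    sim_depth = sample_depths(model, n, 1, rng)
    site_mu = priors.sample_site_means(n, rng)
    sim_meth = rng.binomial(sim_depth, site_mu) / sim_depth

    q = np.linspace(0.0, 1.0, n_quantiles)
    depth_table = pd.DataFrame(
        {
            "quantile": q,
            "real": np.quantile(real_depth, q),
            "simulated": np.quantile(sim_depth, q),
        }
    )
    meth_table = pd.DataFrame(
        {
            "quantile": q,
            "real": np.quantile(real_meth, q),
            "simulated": np.quantile(sim_meth, q),
        }
    )
    real_p95 = float(np.quantile(real_depth, 0.95))
    sim_p95 = float(np.quantile(sim_depth, 0.95))
    tail_warning = real_p95 > 0 and abs(sim_p95 - real_p95) / real_p95 > 0.25
    if tail_warning:
        warnings.warn(
            f"simulated 95th-percentile depth ({sim_p95:g}) deviates from real "
            f"({real_p95:g}) by > 25%; the NB model understates high depths",
            stacklevel=2,
        )
    return {"depth": depth_table, "meth": meth_table, "tail_warning": tail_warning}
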