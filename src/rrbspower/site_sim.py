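"""Site-level simulation of a two-group differential-methylation test.

One simulated DNAm site consists of n1 + n2 DNAm points.  Per point the
read depth is drawn from a zero-truncated NB(mu_rd, r); the number of
methylated reads is Binomial(depth, p) with p = mu_dnam in group A and
p = clamp(mu_dnam + delta, 0, 1) in group B.  A two-sided Welch t-test
compares the per-sample methylation proportions, and statistical power
is the fraction of simulated sites whose p-value falls below the chosen
significance threshold.

The bulk path (:func:`estimate_power`) is fully vectorised over sites;
:func:`simulate_site` exposes the same generative process for a single
site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MethCall
from .nb import NBDepthModel, sample_depths

__all__ = [
    "SiteSimConfig",
    "SimulatedSite",
    "PowerEstimate",
    "simulate_site",
    "site_p_value",
    "welch_p_values",
    "estimate_power",
    "power_curve",
    "split_group_sizes",
    "allocate_groups",
    "minimum_total_sample_size",
]


@dataclass(frozen=True)
class SiteSimConfig:
    """The eight site-simulation parameters (plus the truncation floor)."""

    n1: int
    n2: int
    mu_rd: float
    r: float
    mu_dnam: float
    delta: float
    n_sites: int = 10_000
    p_value: float = 5e-6
    min_depth: int = 1

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs >= 2 samples for a t-test")
        if not 0.0 <= self.mu_dnam <= 1.0:
            raise ValueError("mu_dnam must be in [0, 1]")
        if not -1.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [-1, 1]")
        if not 0.0 < self.p_value < 1.0:
            raise ValueError("p_value must be in (0, 1)")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    @property
    def p_group_b(self) -> float:
        """Group-B methylation probability, clamped to [0, 1]."""
        return float(np.clip(self.mu_dnam + self.delta, 0.0, 1.0))

    @property
    def depth_model(self) -> NBDepthModel:
        return NBDepthModel(mu=self.mu_rd, r=self.r)


@dataclass(frozen=True)
class SimulatedSite:
    group_a: tuple[MethCall, ...]
    group_b: tuple[MethCall, ...]

    def proportions(self) -> tuple[np.ndarray, np.ndarray]:
        a = np.array([c.proportion for c in self.group_a])
        b = np.array([c.proportion for c in self.group_b])
        return a, b


@dataclass(frozen=True)
class PowerEstimate:
    """Power as the fraction of simulated sites significant at ``threshold``."""

    power: float
    n_sites: int
    threshold: float
    p_values: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def from_p_values(
        cls, p_values: np.ndarray, threshold: float, keep_p_values: bool = True
    ) -> "PowerEstimate":
        p_values = np.asarray(p_values, dtype=float)
        power = float(np.mean(p_values < threshold))
        return cls(
            power=power,
            n_sites=p_values.size,
            threshold=threshold,
            p_values=p_values if keep_p_values else None,
        )


def simulate_site(config: SiteSimConfig, rng: np.random.Generator) -> SimulatedSite:
    """Simulate one DNAm site: depths, then methylated read counts."""
    model = config.depth_model
    calls: list[tuple[MethCall, ...]] = []
    for n, p in ((config.n1, config.mu_dnam), (config.n2, config.p_group_b)):
        depths = sample_depths(model, n, config.min_depth, rng)
        meth = rng.binomial(depths, p)
        calls.append(tuple(MethCall(int(m), int(d)) for m, d in zip(meth, depths)))
    return SimulatedSite(group_a=calls[0], group_b=calls[1])


def welch_p_values(
    mean_a, var_a, n_a, mean_b, var_b, n_b, equal_var: bool = False
) -> np.ndarray:
    """Vectorised two-sided t-test p-values from per-group summaries.

    ``var_*`` are unbiased (ddof=1) variances.  Degenerate sites follow
    the conventions: zero variance in both groups with equal means gives
    p = 1; with different means, p = 0 (perfect separation).
    """
    mean_a, var_a, mean_b, var_b = map(
        np.asarray, (mean_a, var_a, mean_b, var_b)
    )
    n_a = np.broadcast_to(np.asarray(n_a, dtype=float), mean_a.shape)
    n_b = np.broadcast_to(np.asarray(n_b, dtype=float), mean_b.shape)
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            dof = n_a + n_b - 2
            pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / dof
            se2 = pooled * (1.0 / n_a + 1.0 / n_b)
        else:
            sa, sb = var_a / n_a, var_b / n_b
            se2 = sa + sb
            dof = se2**2 / (sa**2 / (n_a - 1) + sb**2 / (n_b - 1))
        t = diff / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), dof)
    zero = se2 == 0
    p = np.where(zero & (diff == 0), 1.0, p)
    p = np.where(zero & (diff != 0), 0.0, p)
    return p


def site_p_value(site: SimulatedSite, equal_var: bool = False) -> float:
    """Two-sided Welch p-value comparing the two groups of one site."""
    a, b = site.proportions()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 usable methylation proportions")
    return float(
        welch_p_values(
            a.mean(), a.var(ddof=1), a.size, b.mean(), b.var(ddof=1), b.size,
            equal_var=equal_var,
        )
    )


def _simulate_proportions(
    n_sites: int,
    n: int,
    p_meth: float,
    model: NBDepthModel,
    min_depth: int,
    rng: np.random.Generator,
) -> np.ndarray:
    depths = sample_depths(model, 0, min_depth, rng, size=(n_sites, n))
    meth = rng.binomial(depths, p_meth)
    return meth / depths


def estimate_power(
    config: SiteSimConfig,
    rng: np.random.Generator,
    keep_p_values: bool = False,
    equal_var: bool = False,
) -> PowerEstimate:
    """Monte-Carlo power over ``config.n_sites`` independent sites."""
    if config.n_sites < 100:
        warnings.warn(
            f"n_sites={config.n_sites} is small; power estimates will be noisy",
            stacklevel=2,
        )
    model = config.depth_model
    a = _simulate_proportions(
        config.n_sites, config.n1, config.mu_dnam, model, config.min_depth, rng
    )
    b = _simulate_proportions(
        config.n_sites, config.n2, config.p_group_b, model, config.min_depth, rng
    )
    p = welch_p_values(
        a.mean(axis=1), a.var(axis=1, ddof=1), config.n1,
        b.mean(axis=1), b.var(axis=1, ddof=1), config.n2,
        equal_var=equal_var,
    )
    return PowerEstimate.from_p_values(p, config.p_value, keep_p_values)


def split_group_sizes(n_total: int, ratio: float) -> tuple[int, int]:
    """Split a total sample size into two groups at the given group-A ratio.

    Group A gets round(ratio * n_total); group B the remainder, so the
    total is preserved exactly (e.g. 94 at 60:40 -> (56, 38)).
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    n1 = int(round(ratio * n_total))
    n2 = n_total - n1
    return n1, n2


def allocate_groups(
    n_total: int, ratio: float, p_a: float, p_b: float
) -> tuple[int, int]:
    """Split a total at an unbalanced ratio, favouring the noisier group.

    ``ratio`` is the majority share (0.6 for a 60:40 design).  The larger
    group is assigned to whichever methylation probability has the larger
    binomial variance p(1-p) — the allocation that maximises two-sample
    power for a given imbalance (Neyman allocation puts more samples
    where the variance is higher).
    """
    major = max(ratio, 1.0 - ratio)
    n_major = int(round(major * n_total))
    n_minor = n_total - n_major
    if p_b * (1 - p_b) >= p_a * (1 - p_a):
        return n_minor, n_major
    return n_major, n_minor


def minimum_total_sample_size(
    base: SiteSimConfig,
    ratio: float,
    rng: np.random.Generator,
    power_target: float = 0.80,
    step: int = 2,
    start: int = 10,
    stop: int = 1000,
) -> tuple[int, float]:
    """Smallest total sample size whose simulated power reaches the target.

    Sweeps totals upward in steps of ``step`` with groups split at
    ``ratio`` (majority share to the higher-variance group, see
    :func:`allocate_groups`); each total runs ``base.n_sites`` simulated
    sites with an independent child seed.  Returns (total, power at that
    total); raises if the target is never reached before ``stop``.
    """
    for total in range(start, stop + 1, step):
        n1, n2 = allocate_groups(total, ratio, base.mu_dnam, base.p_group_b)
        if min(n1, n2) < 2:
            continue
        config = SiteSimConfig(
            n1=n1, n2=n2, mu_rd=base.mu_rd, r=base.r, mu_dnam=base.mu_dnam,
            delta=base.delta, n_sites=base.n_sites, p_value=base.p_value,
            min_depth=base.min_depth,
        )
        child = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
        est = estimate_power(config, child)
        if est.power >= power_target:
            return total, est.power
    raise ValueError(
        f"power target {power_target} not reached by total sample size {stop}"
    )


_VARYABLE = ("mu_rd", "n_total", "delta", "mu_dnam")


def power_curve(
    base: SiteSimConfig,
    vary: str,
    values: Sequence[float],
    rng: np.random.Generator,
    ratio: float = 0.5,
) -> pd.DataFrame:
    """Power along a one-parameter grid.

    ``vary`` is one of mu_rd, n_total (groups split at ``ratio``), delta
    or mu_dnam.  Each grid value runs with an independent child seed
    drawn from ``rng`` so columns are reproducible and independent.  The
    returned table also carries the across-site variance of the group-A
    site means (the mean-variance relationship of proportion data).
    """
    if vary not in _VARYABLE:
        raise ValueError(f"unknown parameter {vary!r}; choose from {_VARYABLE}")
    child_seeds = rng.integers(0, 2**31 - 1, size=len(values))
    rows = []
    for value, seed in zip(values, child_seeds):
        kwargs = dict(
            n1=base.n1, n2=base.n2, mu_rd=base.mu_rd, r=base.r,
            mu_dnam=base.mu_dnam, delta=base.delta, n_sites=base.n_sites,
            p_value=base.p_value, min_depth=base.min_depth,
        )
        if vary == "n_total":
            kwargs["n1"], kwargs["n2"] = allocate_groups(
                int(value), ratio, base.mu_dnam, base.p_group_b
            )
        else:
            kwargs[vary] = value
        config = SiteSimConfig(**kwargs)
        child = np.random.default_rng(int(seed))
        model = config.depth_model
        a = _simulate_proportions(
            config.n_sites, config.n1, config.mu_dnam, model, config.min_depth, child
        )
        b = _simulate_proportions(
            config.n_sites, config.n2, config.p_group_b, model, config.min_depth, child
        )
        p = welch_p_values(
            a.mean(axis=1), a.var(axis=1, ddof=1), config.n1,
            b.mean(axis=1), b.var(axis=1, ddof=1), config.n2,
        )
        rows.append(
            {
                vary: value,
                "n1": config.n1,
                "n2": config.n2,
                "power": float(np.mean(p < config.p_value)),
                "n_sites": config.n_sites,
                "threshold": config.p_value,
                "site_mean_variance": float(a.mean(axis=1).var(ddof=1)),
                "seed": int(seed),
            }
        )
    return pd.DataFrame(rows)
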