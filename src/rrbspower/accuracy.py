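"""How read depth limits the accuracy of methylation-proportion estimates.

A DNAm point covered by d reads can only take d + 1 distinct proportion
values, so at low depth the estimate is both coarse and noisy.  With
true methylation p and depth d the estimate is Binomial(d, p) / d; for
truths uniform on [0, 1] the law of total variance gives the closed
forms corr(d) = sqrt(d / (d + 2)) and RMSE(d) = sqrt(1 / (6 d)), which
the Monte-Carlo routines here reproduce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import RRBSDataset

__all__ = [
    "AccuracyResult",
    "simulate_estimates",
    "accuracy_vs_depth",
    "proportion_extreme",
    "theoretical_correlation",
    "theoretical_rmse",
]


@dataclass(frozen=True)
class AccuracyResult:
    read_depth: int
    pearson_correlation: float
    rmse: float
    n_points: int


def theoretical_correlation(depth: float) -> float:
    """Exact truth-vs-estimate correlation for uniform truths at this depth."""
    return float(np.sqrt(depth / (depth + 2.0)))


def theoretical_rmse(depth: float) -> float:
    """Exact truth-vs-estimate RMSE for uniform truths at this depth."""
    return float(np.sqrt(1.0 / (6.0 * depth)))


def simulate_estimates(
    true_dnam, read_depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Binomial methylation estimates at a fixed read depth.

    For each true proportion p, draws methylated reads ~ Binomial(read_depth, p)
    and returns methylated / read_depth.
    """
    if read_depth < 1:
        raise ValueError("read_depth must be >= 1")
    p = np.asarray(true_dnam, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("true methylation values must lie in [0, 1]")
    return rng.binomial(read_depth, p) / read_depth


def accuracy_vs_depth(
    depth_grid,
    n_points: int,
    rng: np.random.Generator,
) -> list[AccuracyResult]:
    """Correlation and RMSE between uniform truths and binomial estimates.

    Per depth d, n_points truths are drawn uniformly on [0, 1], estimated
    at depth d, and compared to the truth series.
    """
    if n_points < 1000:
        warnings.warn(
            f"n_points={n_points} is small; accuracy estimates will be noisy",
            stacklevel=2,
        )
    results = []
    for d in depth_grid:
        d = int(d)
        truth = rng.uniform(0.0, 1.0, size=n_points)
        est = simulate_estimates(truth, d, rng)
        corr = float(np.corrcoef(truth, est)[0, 1])
        rmse = float(np.sqrt(np.mean((est - truth) ** 2)))
        results.append(
            AccuracyResult(
                read_depth=d, pearson_correlation=corr, rmse=rmse, n_points=n_points
            )
        )
    return results


def accuracy_table(results: list[AccuracyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_depth": [r.read_depth for r in results],
            "pearson_correlation": [r.pearson_correlation for r in results],
            "rmse": [r.rmse for r in results],
            "n_points": [r.n_points for r in results],
        }
    )


@dataclass(frozen=True)
class ExtremeFractionResult:
    """Per-sample fraction of extreme DNAm calls at one read depth."""

    read_depth: int
    window: int
    per_sample: pd.Series  # NaN where a sample has no points at that depth
    mean: float
    sd: float


def proportion_extreme(
    data: RRBSDataset, depth: int, window: int = 0
) -> ExtremeFractionResult:
    """Fraction of DNAm points called extreme (< 0.05 or > 0.95) at a depth.

    Considers unmasked points whose depth lies within ``depth ± window``
    (exact depth by default) and reports the extreme fraction per sample,
    with its mean and SD across samples.  Samples with no qualifying
    points are reported as missing.
    """
    if data.n_sites == 0:
        raise ValueError("empty dataset")
    in_bin = data.covered & (np.abs(data.depth - depth) <= window)
    fractions = []
    for j in range(data.n_samples):
        sel = in_bin[:, j]
        if not sel.any():
            fractions.append(np.nan)
            continue
        m = data.meth[sel, j]
        fractions.append(float(np.mean((m < 0.05) | (m > 0.95))))
    per_sample = pd.Series(fractions, index=data.sample_ids, name=f"depth_{depth}")
    return ExtremeFractionResult(
        read_depth=depth,
        window=window,
        per_sample=per_sample,
        mean=float(per_sample.mean()),
        sd=float(per_sample.std()),
    )
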