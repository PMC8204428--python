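"""Descriptive statistics of an RRBS dataset.

Covers the standard quality-control views of a site x sample methylation
matrix: per-sample read-depth histograms (long-tailed count data),
per-sample methylation densities (bimodal, massed near 0 and 1), the
extent of missing data, rank correlation of depth between samples (a
signature of the MspI enrichment shared across libraries), and the decay
of the fraction of DNAm points shared as more samples are intersected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import RRBSDataset

__all__ = ["DatasetSummary", "summarize", "overlap_decay"]

_METH_BINS = np.linspace(0.0, 1.0, 51)


@dataclass
class DatasetSummary:
    depth_histogram: pd.DataFrame  # rows depth 1..cap (top bin pools > cap), cols samples
    meth_histogram: pd.DataFrame  # rows 50 proportion bins, cols samples (densities)
    fraction_le_depth: pd.Series  # threshold -> fraction of points with depth <= t
    fraction_gt_depth: pd.Series  # threshold -> fraction of points with depth > t
    fraction_fully_covered: float  # sites with a DNAm point in every sample
    depth_correlation: pd.DataFrame  # Spearman rho between sample depth vectors
    mean_points_per_sample: float


def summarize(
    data: RRBSDataset,
    depth_cap: int = 200,
    le_thresholds: tuple[int, ...] = (5,),
    gt_thresholds: tuple[int, ...] = (100,),
) -> DatasetSummary:
    """Compute the descriptive summary of one dataset.

    Depth histograms count unmasked points only, pooling depths above
    ``depth_cap`` into the top bin.  Pairwise depth correlation is
    Spearman's over all sites (zeros included); samples with zero
    depth variance get missing correlations.
    """
    if data.n_sites == 0:
        raise ValueError("empty dataset")
    covered = data.covered
    depths = data.depth

    bins = np.arange(1, depth_cap + 1)
    hist = np.zeros((depth_cap, data.n_samples), dtype=np.int64)
    for j in range(data.n_samples):
        d = np.minimum(depths[covered[:, j], j], depth_cap)
        hist[:, j] = np.bincount(d, minlength=depth_cap + 1)[1:]
    depth_histogram = pd.DataFrame(hist, index=bins, columns=data.sample_ids)

    mhist = np.zeros((_METH_BINS.size - 1, data.n_samples))
    for j in range(data.n_samples):
        m = data.meth[covered[:, j], j]
        if m.size:
            mhist[:, j] = np.histogram(m, bins=_METH_BINS, density=True)[0]
    meth_histogram = pd.DataFrame(
        mhist, index=_METH_BINS[:-1], columns=data.sample_ids
    )

    all_point_depths = depths[covered]
    fraction_le = pd.Series(
        {t: float(np.mean(all_point_depths <= t)) for t in le_thresholds}
    )
    fraction_gt = pd.Series(
        {t: float(np.mean(all_point_depths > t)) for t in gt_thresholds}
    )

    # Spearman over the depth columns; constant columns have undefined rho
    corr = np.full((data.n_samples, data.n_samples), np.nan)
    variable = depths.std(axis=0) > 0
    if variable.sum() >= 2:
        idx = np.flatnonzero(variable)
        rho = stats.spearmanr(depths[:, idx]).statistic
        if idx.size == 2:  # scipy collapses the 2-column case to a scalar
            rho = np.array([[1.0, rho], [rho, 1.0]])
        for a, i in enumerate(idx):
            for b, k in enumerate(idx):
                corr[i, k] = rho[a, b]
    np.fill_diagonal(corr, 1.0)
    depth_correlation = pd.DataFrame(
        corr, index=data.sample_ids, columns=data.sample_ids
    )

    return DatasetSummary(
        depth_histogram=depth_histogram,
        meth_histogram=meth_histogram,
        fraction_le_depth=fraction_le,
        fraction_gt_depth=fraction_gt,
        fraction_fully_covered=float(covered.all(axis=1).mean()),
        depth_correlation=depth_correlation,
        mean_points_per_sample=float(covered.sum(axis=0).mean()),
    )


def overlap_decay(
    data: RRBSDataset,
    max_k: int | None = None,
    n_orderings: int = 20,
    rng: np.random.Generator | None = None,
    fixed_order: bool = False,
) -> pd.DataFrame:
    """Fraction of sites covered in all of the first k samples, vs k.

    For each of ``n_orderings`` random sample orderings (or the given
    column order when ``fixed_order``), computes for k = 1..max_k the
    fraction of sites with a DNAm point in every one of the first k
    samples, then averages across orderings.  The curve is
    non-increasing in k for every ordering and plateaus at the fraction
    of sites covered in all samples.
    """
    if max_k is None:
        max_k = data.n_samples
    if max_k > data.n_samples:
        raise ValueError(
            f"max_k={max_k} exceeds the number of samples ({data.n_samples})"
        )
    covered = data.covered
    if fixed_order:
        orderings = [np.arange(data.n_samples)]
    else:
        if rng is None:
            rng = np.random.default_rng()
        orderings = [rng.permutation(data.n_samples) for _ in range(n_orderings)]
    curves = np.empty((len(orderings), max_k))
    for i, perm in enumerate(orderings):
        cum = np.cumprod(covered[:, perm[:max_k]], axis=1, dtype=bool)
        curves[i] = cum.mean(axis=0)
    return pd.DataFrame(
        {"k": np.arange(1, max_k + 1), "fraction_shared": curves.mean(axis=0)}
    )
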