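"""Core containers for RRBS methylation data.

An RRBS experiment yields, for every assayed cytosine ("DNAm site") and
every sample, a *DNAm point*: the pair (methylated reads, total reads).
A site with zero total reads in a sample has no DNAm point there; that
missingness is encoded as depth 0 with the methylation value masked
(NaN).  All downstream modules (filtering, characterization, power
prediction) operate on the :class:`RRBSDataset` container defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MethCall",
    "RRBSDataset",
    "FilterReport",
    "SiteId",
    "assemble_dataset",
    "filter_dataset",
]

# Site identity is (chromosome, 1-based position); strand is not tracked
# because cytosine contexts are pooled.
SiteId = tuple[str, int]


@dataclass(frozen=True)
class MethCall:
    """One DNAm point: methylated and total read counts at a site in a sample."""

    methylated_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.methylated_reads < 0 or self.total_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.methylated_reads > self.total_reads:
            raise ValueError(
                f"methylated reads ({self.methylated_reads}) exceed "
                f"total reads ({self.total_reads})"
            )

    @property
    def proportion(self) -> float:
        """Methylation proportion; undefined (ValueError) at zero depth."""
        if self.total_reads == 0:
            raise ValueError("methylation proportion undefined at zero depth")
        return self.methylated_reads / self.total_reads


@dataclass
class RRBSDataset:
    """Site x sample matrices of read depth and methylation proportion.

    ``meth`` is NaN exactly where ``depth`` is 0 (no DNAm point).  Rows
    are keyed by ``site_ids`` (chromosome, position), columns by
    ``sample_ids``.
    """

    site_ids: list[SiteId]
    sample_ids: list[str]
    depth: np.ndarray  # (n_sites, n_samples) non-negative int
    meth: np.ndarray  # (n_sites, n_samples) float in [0,1], NaN where depth==0

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        self.meth = np.asarray(self.meth, dtype=float)
        n_sites, n_samples = len(self.site_ids), len(self.sample_ids)
        if self.depth.shape != (n_sites, n_samples):
            raise ValueError(
                f"depth shape {self.depth.shape} does not match "
                f"{n_sites} sites x {n_samples} samples"
            )
        if self.meth.shape != self.depth.shape:
            raise ValueError("depth and meth shapes differ")
        if len(set(self.site_ids)) != n_sites:
            raise ValueError("site_ids are not unique")
        if (self.depth < 0).any():
            raise ValueError("negative read depth")
        zero = self.depth == 0
        if not np.isnan(self.meth[zero]).all():
            raise ValueError("meth must be masked (NaN) where depth == 0")
        if np.isnan(self.meth[~zero]).any():
            raise ValueError("meth must be defined where depth > 0")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def covered(self) -> np.ndarray:
        """Boolean matrix: True where a DNAm point exists (depth > 0)."""
        return self.depth > 0

    def site_labels(self) -> list[str]:
        return [f"{c}:{p}" for c, p in self.site_ids]

    def depth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.depth, index=self.site_labels(), columns=self.sample_ids)

    def meth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.meth, index=self.site_labels(), columns=self.sample_ids)

    def subset_sites(self, indices: Sequence[int] | np.ndarray) -> "RRBSDataset":
        idx = np.asarray(indices)
        return RRBSDataset(
            site_ids=[self.site_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            depth=self.depth[idx].copy(),
            meth=self.meth[idx].copy(),
        )


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for one application of read-depth / min-points filtering."""

    rd_filter: int
    min_points_per_group: int
    n_sites_before: int
    n_sites_after: int
    proportion_points_remaining: float

    def __post_init__(self) -> None:
        if self.n_sites_after > self.n_sites_before:
            raise ValueError("n_sites_after exceeds n_sites_before")
        if not 0.0 <= self.proportion_points_remaining <= 1.0:
            raise ValueError("proportion_points_remaining outside [0, 1]")


def assemble_dataset(
    per_sample_calls: dict[str, Sequence[tuple[SiteId, MethCall]]],
) -> RRBSDataset:
    """Combine per-sample call collections into one aligned dataset.

    The row set is the union of all site ids, sorted by (chromosome,
    position); a (site, sample) pair absent from a sample's calls gets
    depth 0 and masked methylation.
    """
    if not per_sample_calls:
        raise ValueError("no samples provided")
    sample_ids = list(per_sample_calls)
    all_sites: set[SiteId] = set()
    for sample, calls in per_sample_calls.items():
        seen: set[SiteId] = set()
        for site, _ in calls:
            if site in seen:
                raise ValueError(f"duplicate site {site} in sample {sample!r}")
            seen.add(site)
        all_sites |= seen
    site_ids = sorted(all_sites)
    row_of = {s: i for i, s in enumerate(site_ids)}

    depth = np.zeros((len(site_ids), len(sample_ids)), dtype=np.int64)
    meth = np.full((len(site_ids), len(sample_ids)), np.nan)
    for j, sample in enumerate(sample_ids):
        for site, call in per_sample_calls[sample]:
            i = row_of[site]
            depth[i, j] = call.total_reads
            if call.total_reads > 0:
                meth[i, j] = call.methylated_reads / call.total_reads
    return RRBSDataset(site_ids=site_ids, sample_ids=sample_ids, depth=depth, meth=meth)


def _group_columns(
    n_samples: int, pheno: Sequence[str] | None
) -> list[np.ndarray]:
    """Column index arrays for the (one or two) comparison groups."""
    if pheno is None:
        return [np.arange(n_samples)]
    pheno = list(pheno)
    if len(pheno) != n_samples:
        raise ValueError(
            f"pheno length {len(pheno)} does not match {n_samples} samples"
        )
    levels = sorted(set(pheno))
    if len(levels) != 2:
        raise ValueError(f"pheno must have exactly 2 levels, got {levels}")
    arr = np.asarray(pheno)
    return [np.flatnonzero(arr == lev) for lev in levels]


def filter_dataset(
    data: RRBSDataset,
    rd_filter: int,
    min_points_per_group: int,
    pheno: Sequence[str] | None = None,
) -> tuple[RRBSDataset, FilterReport]:
    """Apply read-depth and minimum-DNAm-points filtering.

    Cells with depth below ``rd_filter`` are masked (a point is KEPT iff
    its depth >= rd_filter).  A site is retained iff every comparison
    group keeps at least ``min_points_per_group`` unmasked points; with
    no ``pheno`` all samples form a single group.
    """
    if rd_filter < 1:
        raise ValueError("rd_filter must be >= 1")
    if min_points_per_group < 1:
        raise ValueError("min_points_per_group must be >= 1")
    groups = _group_columns(data.n_samples, pheno)

    keep_cell = data.depth >= rd_filter
    depth = np.where(keep_cell, data.depth, 0)
    meth = np.where(keep_cell, data.meth, np.nan)

    keep_site = np.ones(data.n_sites, dtype=bool)
    for cols in groups:
        keep_site &= keep_cell[:, cols].sum(axis=1) >= min_points_per_group

    points_before = int(data.covered.sum())
    points_after = int(keep_cell[keep_site].sum())
    filtered = RRBSDataset(
        site_ids=[s for s, k in zip(data.site_ids, keep_site) if k],
        sample_ids=list(data.sample_ids),
        depth=depth[keep_site],
        meth=meth[keep_site],
    )
    report = FilterReport(
        rd_filter=rd_filter,
        min_points_per_group=min_points_per_group,
        n_sites_before=data.n_sites,
        n_sites_after=int(keep_site.sum()),
        proportion_points_remaining=(
            points_after / points_before if points_before else 0.0
        ),
    )
    return filtered, report
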