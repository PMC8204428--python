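"""Readers and writers: Bismark coverage files and aligned matrix TSV pairs.

The Bismark ``.cov`` dialect is a 6-column TSV with 1-based inclusive
coordinates::

    chromosome  start  end  %methylation  count_methylated  count_unmethylated

The percentage column is advisory only: proportions are always recomputed
from the counts, and the stated percentage is validated against them to
within 0.5 percentage points.  Plain and gzip-compressed files are both
accepted.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import MethCall, RRBSDataset, SiteId

__all__ = [
    "read_bismark_coverage",
    "write_bismark_coverage",
    "read_matrix_pair",
    "write_matrix_pair",
]


class CoverageParseError(ValueError):
    """Malformed line in a Bismark coverage file."""


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return _io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_bismark_coverage(
    path: str | Path, sample_id: str | None = None
) -> list[tuple[SiteId, MethCall]]:
    """Parse one Bismark coverage file into (site_id, MethCall) records.

    Lines are returned in file order; ``site_id`` is (chromosome, start).
    Zero-depth lines are rejected — coverage files never report sites
    without reads.
    """
    calls: list[tuple[SiteId, MethCall]] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise CoverageParseError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, start_s, _end, pct_s, meth_s, unmeth_s = fields
            try:
                start = int(start_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
                pct = float(pct_s)
            except ValueError as exc:
                raise CoverageParseError(f"{path}:{lineno}: {exc}") from exc
            if meth < 0 or unmeth < 0:
                raise CoverageParseError(f"{path}:{lineno}: negative read count")
            total = meth + unmeth
            if total == 0:
                raise CoverageParseError(
                    f"{path}:{lineno}: zero total reads (coverage files never "
                    "report uncovered sites)"
                )
            if abs(pct - 100.0 * meth / total) > 0.5:
                raise CoverageParseError(
                    f"{path}:{lineno}: stated methylation {pct}% disagrees with "
                    f"counts {meth}/{total} by more than 0.5 points"
                )
            calls.append(((chrom, start), MethCall(meth, total)))
    return calls


def write_bismark_coverage(
    calls: Sequence[tuple[SiteId, MethCall]], path: str | Path
) -> None:
    """Write (site_id, MethCall) records as a 6-column Bismark coverage file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for (chrom, pos), call in calls:
            pct = 100.0 * call.methylated_reads / call.total_reads
            unmeth = call.total_reads - call.methylated_reads
            fh.write(
                f"{chrom}\t{pos}\t{pos}\t{pct:g}\t{call.methylated_reads}\t{unmeth}\n"
            )


def _parse_site_label(label: str) -> SiteId:
    chrom, _, pos = label.rpartition(":")
    if not chrom:
        raise ValueError(f"site id {label!r} is not of the form 'chrom:pos'")
    return (chrom, int(pos))


def read_matrix_pair(depth_path: str | Path, meth_path: str | Path) -> RRBSDataset:
    """Read the aligned (depth TSV, methylation TSV) pair into a dataset.

    Both tables carry a header of sample ids and a first column of
    ``chrom:pos`` site labels; masked cells are 0 in the depth matrix and
    NA in the methylation matrix.
    """
    depth_df = pd.read_csv(depth_path, sep="\t", index_col=0)
    meth_df = pd.read_csv(meth_path, sep="\t", index_col=0)
    if not depth_df.index.equals(meth_df.index) or not depth_df.columns.equals(
        meth_df.columns
    ):
        raise ValueError("depth and methylation tables are not aligned")
    site_ids = [_parse_site_label(str(s)) for s in depth_df.index]
    return RRBSDataset(
        site_ids=site_ids,
        sample_ids=[str(c) for c in depth_df.columns],
        depth=depth_df.to_numpy(dtype=np.int64),
        meth=meth_df.to_numpy(dtype=float),
    )


def write_matrix_pair(
    data: RRBSDataset, depth_path: str | Path, meth_path: str | Path
) -> None:
    """Write the dataset as an aligned depth/methylation TSV pair."""
    data.depth_frame().to_csv(depth_path, sep="\t")
    data.meth_frame().to_csv(meth_path, sep="\t", na_rep="NA")
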