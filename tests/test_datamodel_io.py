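"""Data containers, Bismark coverage parsing, and filtering."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrbspower import (
    MethCall,
    RRBSDataset,
    assemble_dataset,
    filter_dataset,
    read_bismark_coverage,
    read_matrix_pair,
    write_bismark_coverage,
    write_matrix_pair,
)
from rrbspower.io import CoverageParseError


def make_dataset(depth, meth=None):
    depth = np.asarray(depth)
    if meth is None:
        meth = np.where(depth > 0, 0.5, np.nan)
    sites = [("chr1", 100 + i) for i in range(depth.shape[0])]
    samples = [f"s{j}" for j in range(depth.shape[1])]
    return RRBSDataset(site_ids=sites, sample_ids=samples, depth=depth, meth=meth)


class TestMethCall:
    def test_proportion(self):
        assert MethCall(7, 7).proportion == 1.0
        assert MethCall(0, 5).proportion == 0.0
        assert MethCall(1, 4).proportion == 0.25

    def test_invariants(self):
        with pytest.raises(ValueError):
            MethCall(5, 3)
        with pytest.raises(ValueError):
            MethCall(-1, 3)
        with pytest.raises(ValueError):
            MethCall(0, 0).proportion


class TestBismarkCoverage:
    def test_parses_counts_and_sites(self, tmp_path):
        path = tmp_path / "a.cov"
        path.write_text(
            "chr1\t3020917\t3020917\t100\t7\t0\n"
            "chr1\t3020930\t3020930\t0\t0\t5\n"
        )
        calls = read_bismark_coverage(path)
        assert calls[0] == (("chr1", 3020917), MethCall(7, 7))
        assert calls[0][1].proportion == 1.0
        assert calls[1] == (("chr1", 3020930), MethCall(0, 5))
        assert calls[1][1].proportion == 0.0

    def test_gzip_accepted(self, tmp_path):
        path = tmp_path / "a.cov.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("chr2\t50\t50\t50\t2\t2\n")
        assert read_bismark_coverage(path) == [(("chr2", 50), MethCall(2, 4))]

    @pytest.mark.parametrize(
        "line",
        [
            "chr1\t10\t10\t100\t7",  # wrong field count
            "chr1\t10\t10\t100\t-1\t2",  # negative count
            "chr1\t10\t10\t0\t0\t0",  # zero depth
            "chr1\t10\t10\t90\t7\t0",  # percentage disagrees with counts
        ],
    )
    def test_malformed_lines_name_the_line(self, tmp_path, line):
        path = tmp_path / "bad.cov"
        path.write_text("chr1\t1\t1\t100\t3\t0\n" + line + "\n")
        with pytest.raises(CoverageParseError, match=":2"):
            read_bismark_coverage(path)

    def test_round_trip_preserves_counts(self, tmp_path):
        rng = np.random.default_rng(3)
        calls = []
        for i in range(50):
            total = int(rng.integers(1, 200))
            meth = int(rng.integers(0, total + 1))
            calls.append(((f"chr{1 + i % 3}", 1000 + i), MethCall(meth, total)))
        path = tmp_path / "rt.cov"
        write_bismark_coverage(calls, path)
        assert read_bismark_coverage(path) == calls


class TestAssemble:
    def test_union_of_sites_with_masking(self, tmp_path):
        # three-file set where one file lacks a site present in the others
        shared = [(("chr1", i), MethCall(1, 2)) for i in (10, 20, 30)]
        per_sample = {
            "s1": shared + [(("chr1", 40), MethCall(2, 2))],
            "s2": shared + [(("chr2", 5), MethCall(0, 3))],
            "s3": shared,
        }
        data = assemble_dataset(per_sample)
        assert data.n_sites == 5 and data.n_samples == 3
        # absent cells: (chr1,40) in s2,s3; (chr2,5) in s1,s3
        assert int((~data.covered).sum()) == 4
        assert np.isnan(data.meth[~data.covered]).all()
        # rows sorted by (chromosome, position)
        assert data.site_ids == sorted(data.site_ids)

    def test_single_sample_has_no_masking(self):
        data = assemble_dataset({"s1": [(("chr1", 1), MethCall(1, 4))]})
        assert data.covered.all()

    def test_empty_and_duplicate_inputs_error(self):
        with pytest.raises(ValueError):
            assemble_dataset({})
        dup = {"sA": [(("chr1", 1), MethCall(1, 2)), (("chr1", 1), MethCall(0, 2))]}
        with pytest.raises(ValueError, match="sA"):
            assemble_dataset(dup)


class TestFilterDataset:
    def test_hand_enumerated_toy(self):
        # depths: rows are sites; groups (A,A,B,B); rd>=5, >=2 points/group
        depth = np.array(
            [[5, 5, 5, 5], [1, 1, 9, 9], [0, 0, 9, 9], [9, 9, 9, 9]]
        )
        data = make_dataset(depth)
        filtered, report = filter_dataset(
            data, rd_filter=5, min_points_per_group=2, pheno=("A", "A", "B", "B")
        )
        assert report.n_sites_after == 2
        assert filtered.site_ids == [("chr1", 100), ("chr1", 103)]
        # surviving cells: 8 of the 14 originally covered points
        assert report.proportion_points_remaining == pytest.approx(8 / 14)

    def test_identity_filter(self):
        data = make_dataset(np.full((3, 4), 7))
        filtered, report = filter_dataset(data, 1, 1)
        assert report.n_sites_after == 3
        assert report.proportion_points_remaining == 1.0
        assert np.array_equal(filtered.depth, data.depth)

    def test_filter_above_max_depth_removes_everything(self):
        data = make_dataset(np.full((3, 4), 7))
        _, report = filter_dataset(data, 100, 1)
        assert report.n_sites_after == 0

    def test_keep_rule_is_inclusive_at_the_threshold(self):
        # a point with depth exactly rd_filter survives
        data = make_dataset(np.array([[5, 5], [4, 4]]))
        _, report = filter_dataset(data, 5, 2)
        assert report.n_sites_after == 1

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        depth = rng.integers(0, 12, size=(30, 6))
        data = make_dataset(depth)
        once, r1 = filter_dataset(data, 4, 2)
        twice, r2 = filter_dataset(once, 4, 2)
        assert np.array_equal(once.depth, twice.depth)
        assert r2.n_sites_after == r1.n_sites_after

    def test_bad_arguments(self):
        data = make_dataset(np.full((2, 4), 3))
        with pytest.raises(ValueError):
            filter_dataset(data, 0, 1)
        with pytest.raises(ValueError):
            filter_dataset(data, 1, 1, pheno=("A", "A", "A", "A"))
        with pytest.raises(ValueError):
            filter_dataset(data, 1, 1, pheno=("A", "B", "C", "A"))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        rd=st.integers(1, 8),
        mp=st.integers(1, 4),
    )
    def test_monotone_in_thresholds(self, seed, rd, mp):
        """Retained sites never increase as either threshold tightens."""
        rng = np.random.default_rng(seed)
        data = make_dataset(rng.integers(0, 10, size=(25, 8)))
        _, base = filter_dataset(data, rd, mp)
        _, harder_rd = filter_dataset(data, rd + 1, mp)
        _, harder_mp = filter_dataset(data, rd, mp + 1)
        assert harder_rd.n_sites_after <= base.n_sites_after
        assert harder_mp.n_sites_after <= base.n_sites_after


class TestMatrixPair:
    def test_round_trip(self, tmp_path, small_synthetic):
        data, _ = small_synthetic
        dpath, mpath = tmp_path / "d.tsv", tmp_path / "m.tsv"
        write_matrix_pair(data, dpath, mpath)
        back = read_matrix_pair(dpath, mpath)
        assert back.site_ids == data.site_ids
        assert back.sample_ids == data.sample_ids
        assert np.array_equal(back.depth, data.depth)
        assert np.allclose(back.meth, data.meth, equal_nan=True)

    def test_misaligned_tables_rejected(self, tmp_path):
        data = make_dataset(np.full((2, 2), 3))
        write_matrix_pair(data, tmp_path / "d.tsv", tmp_path / "m.tsv")
        other = make_dataset(np.full((3, 2), 3))
        write_matrix_pair(other, tmp_path / "d2.tsv", tmp_path / "m2.tsv")
        with pytest.raises(ValueError, match="aligned"):
            read_matrix_pair(tmp_path / "d.tsv", tmp_path / "m2.tsv")
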