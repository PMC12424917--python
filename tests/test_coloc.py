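"""Proximity colocalization: parsing, filtering, window join, reporting."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from heartbrain.coloc import (
    GwasSnp,
    ReadDiagnostics,
    annotate_and_filter,
    count_pairings,
    filter_significant,
    normalize_chromosome,
    pairs_to_frame,
    read_summary_stats,
    unique_pair_count,
    window_join,
)


def snp(rsid, chrom="1", pos=1000, p=1e-10, trait="t", side="catalog"):
    return GwasSnp(rsid, chrom, pos, p, trait, side)


def brute_force_join(catalog, biobank, window_bp):
    """O(n^2) all-pairs oracle."""
    return {
        (c.rsid, c.trait, b.rsid, b.trait)
        for c, b in itertools.product(catalog, biobank)
        if c.chromosome == b.chromosome and abs(c.position - b.position) <= window_bp
    }


class TestReadSummaryStats:
    def test_native_dialect_round_trip(self, tmp_path):
        f = tmp_path / "native.tsv"
        f.write_text(
            "rsid\tchrom\tpos\tpvalue\ttrait\n"
            "rs429358\t19\t44908684\t1e-100\tAlzheimer disease\n"
            "rs1\tchr2\t100\t5E-8\theart rate\n"
            "rs2\tX\t200\t1e-9\theart rate\n"
        )
        snps = read_summary_stats(f, "native", side="biobank")
        assert len(snps) == 3
        assert snps[0].rsid == "rs429358" and snps[0].position == 44908684
        assert snps[1].chromosome == "2"  # chr prefix stripped
        assert snps[1].p_value == pytest.approx(5e-8)  # scientific notation
        assert snps[2].chromosome == "X"
        assert all(s.side == "biobank" for s in snps)

    def test_catalog_dialect_and_malformed_rows_skipped(self, tmp_path):
        f = tmp_path / "catalog.tsv"
        f.write_text(
            "SNPS\tCHR_ID\tCHR_POS\tP-VALUE\tDISEASE/TRAIT\n"
            "rs1\t19\t44908684\t1e-100\tAlzheimer disease\n"
            "rs2\t19\tNR\t1e-20\tAlzheimer disease\n"
            "rs3\tbogus\t100\t1e-20\tAlzheimer disease\n"
        )
        diag = ReadDiagnostics()
        snps = read_summary_stats(f, "catalog_tsv", diagnostics=diag)
        assert [s.rsid for s in snps] == ["rs1"]
        assert diag.n_skipped == 2

    def test_missing_column_error_names_it(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("rsid\tchrom\tpos\tpvalue\nrs1\t1\t10\t1e-10\n")
        with pytest.raises(ValueError, match="trait"):
            read_summary_stats(f, "native")

    @pytest.mark.parametrize(
        "raw,expected",
        [("chr1", "1"), ("19", "19"), ("x", "X"), ("chrM", "MT"), ("23", "X"), ("NR", None)],
    )
    def test_chromosome_normalization(self, raw, expected):
        assert normalize_chromosome(raw) == expected


class TestFilterSignificant:
    def test_boundary_is_strict(self):
        at = snp("rs_at", p=5e-8)
        below = snp("rs_below", p=4.9e-8)
        kept = filter_significant([at, below], 5e-8)
        assert [s.rsid for s in kept] == ["rs_below"]

    def test_empty_input(self):
        assert filter_significant([], 5e-8) == []

    def test_order_stable(self):
        snps = [snp(f"rs{i}", p=1e-9) for i in range(5)]
        assert [s.rsid for s in filter_significant(snps)] == [f"rs{i}" for i in range(5)]


class TestWindowJoin:
    def test_inclusive_boundary_at_exactly_window(self):
        pairs = window_join([snp("c1", pos=100_000)], [snp("b1", pos=150_000, side="biobank")], 50_000)
        assert len(pairs) == 1
        assert pairs[0].distance == 50_000

    def test_just_outside_window_excluded(self):
        pairs = window_join([snp("c1", pos=100_000)], [snp("b1", pos=150_001, side="biobank")], 50_000)
        assert pairs == []

    def test_different_chromosomes_never_pair(self):
        pairs = window_join([snp("c1", chrom="1")], [snp("b1", chrom="2", side="biobank")], 50_000)
        assert pairs == []

    def test_matches_bruteforce_on_random_instance(self):
        import numpy as np

        rng = np.random.default_rng(17)
        cat = [
            snp(f"c{i}", chrom=str(rng.integers(1, 5)), pos=int(rng.integers(1, 2_000_000)),
                trait=f"ct{rng.integers(3)}")
            for i in range(500)
        ]
        bio = [
            snp(f"b{i}", chrom=str(rng.integers(1, 5)), pos=int(rng.integers(1, 2_000_000)),
                trait=f"bt{rng.integers(3)}", side="biobank")
            for i in range(500)
        ]
        got = {
            (p.catalog_snp.rsid, p.catalog_snp.trait, p.biobank_snp.rsid, p.biobank_snp.trait)
            for p in window_join(cat, bio, 50_000)
        }
        assert got == brute_force_join(cat, bio, 50_000)

    def test_symmetric_under_side_swap(self):
        cat = [snp("c1", pos=100), snp("c2", pos=40_000)]
        bio = [snp("b1", pos=30_000, side="biobank"), snp("b2", pos=90_000, side="biobank")]
        fwd = {(p.catalog_snp.rsid, p.biobank_snp.rsid) for p in window_join(cat, bio, 50_000)}
        swapped_cat = [snp(s.rsid, pos=s.position, side="catalog") for s in bio]
        swapped_bio = [snp(s.rsid, pos=s.position, side="biobank") for s in cat]
        rev = {(p.biobank_snp.rsid, p.catalog_snp.rsid) for p in window_join(swapped_cat, swapped_bio, 50_000)}
        assert fwd == rev

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.randoms(use_true_random=False), st.integers(1, 3))
    def test_invariant_under_permutation_and_duplication(self, rnd, dup):
        cat = [snp(f"c{i}", pos=1 + 10_000 * i) for i in range(8)]
        bio = [snp(f"b{i}", pos=1 + 7_000 * i, side="biobank") for i in range(8)]
        base = pairs_to_frame(window_join(cat, bio, 20_000))
        cat2, bio2 = cat * dup, bio * dup
        rnd.shuffle(cat2)
        rnd.shuffle(bio2)
        pd.testing.assert_frame_equal(base, pairs_to_frame(window_join(cat2, bio2, 20_000)))


class TestCountPairings:
    def test_three_distinct_biobank_snps(self):
        anchor = snp("cA", pos=100_000)
        bio = [snp(f"b{i}", pos=100_000 + i, side="biobank", trait=f"t{i}") for i in range(3)]
        report = count_pairings(window_join([anchor], bio, 50_000))
        assert report["n_pairings"].tolist() == [3]

    def test_one_snp_two_traits_counts_twice_by_default(self):
        anchor = snp("cA", pos=100_000)
        bio = [
            snp("b1", pos=100_010, side="biobank", trait="wall thickness"),
            snp("b1", pos=100_010, side="biobank", trait="heart rate"),
        ]
        pairs = window_join([anchor], bio, 50_000)
        assert count_pairings(pairs)["n_pairings"].tolist() == [2]
        assert count_pairings(pairs, count_key="rsid")["n_pairings"].tolist() == [1]

    def test_empty_report(self):
        assert count_pairings([]).empty

    def test_counts_conserve_pair_records(self):
        import numpy as np

        rng = np.random.default_rng(23)
        cat = [snp(f"c{i}", pos=int(rng.integers(1, 500_000))) for i in range(30)]
        bio = [snp(f"b{i}", pos=int(rng.integers(1, 500_000)), side="biobank") for i in range(30)]
        pairs = window_join(cat, bio, 50_000)
        report = count_pairings(pairs)
        assert report["n_pairings"].sum() == len(pairs)
        assert unique_pair_count(pairs) <= len(pairs)


class TestAnnotateAndFilter:
    def _report(self):
        return pd.DataFrame(
            {
                "catalog_rsid": ["A", "B", "C"],
                "catalog_traits": ["x", "y", "z"],
                "biobank_traits": ["u", "v", "w"],
                "n_pairings": [42, 3, 2],
            }
        )

    def test_threshold_and_order(self):
        out = annotate_and_filter(self._report(), {"A": "KANSL1"}, min_pairings=3)
        assert out["catalog_rsid"].tolist() == ["A", "B"]

    def test_unmapped_rsid_gets_na_and_stays(self):
        out = annotate_and_filter(self._report(), {"A": "KANSL1"}, min_pairings=3)
        assert out.loc[out["catalog_rsid"] == "B", "genes"].iloc[0] == "NA"

    def test_min_pairings_one_keeps_all(self):
        assert len(annotate_and_filter(self._report(), {}, min_pairings=1)) == 3


def test_invalid_snp_fields_rejected():
    with pytest.raises(ValueError):
        GwasSnp("rs1", "26", 100, 1e-9, "t")
    with pytest.raises(ValueError):
        GwasSnp("rs1", "1", 0, 1e-9, "t")
    with pytest.raises(ValueError):
        GwasSnp("", "1", 100, 1e-9, "t")
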