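import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedpattern.bsa import (
    MarkerTable,
    Region,
    bsa_scan,
    bulk_call,
    filter_polymorphic,
    intersect_blocks,
    regions_from_bed,
    regions_to_bed,
    regions_to_tsv,
    verify_region,
)


def make_table(states: str, chrom: str = "Vu02", roles=None) -> MarkerTable:
    """Build a table from a state string: 'R'/'A' = qualifying marker of
    that orientation, '.' = non-qualifying (recessive bulk het)."""
    n = len(states)
    meta = pd.DataFrame(
        {"marker": [f"m{i:04d}" for i in range(n)],
         "chrom": [chrom] * n,
         "bp": [1000 * (i + 1) for i in range(n)]}
    )
    rec = np.where(np.isin(list(states), ["R", "A"]),
                   np.where(np.array(list(states)) == "R", "hom_ref", "hom_alt"),
                   "het")
    calls = pd.DataFrame({
        "rec_bulk": rec,
        "dom_bulk": ["het"] * n,
    })
    return MarkerTable(meta, calls, roles or {"rec_bulk": "recessive_bulk",
                                              "dom_bulk": "dominant_bulk"})


def region(chrom, start, end):
    return Region(chrom, start, end, "", "", 0)


class TestBulkCall:
    def test_uniform_pool(self):
        assert bulk_call(["hom_ref"] * 20) == "hom_ref"

    def test_single_contaminant_reads_het(self):
        assert bulk_call(["hom_ref"] * 19 + ["hom_alt"]) == "het"

    def test_het_mixture(self):
        assert bulk_call(["het"] * 10 + ["hom_ref"] * 10) == "het"

    def test_missing_dropped(self):
        assert bulk_call(["missing", "hom_alt", "missing"]) == "hom_alt"

    def test_all_missing(self):
        assert bulk_call(["missing", "missing"]) == "missing"

    def test_unknown_call_rejected(self):
        with pytest.raises(ValueError, match="unknown call"):
            bulk_call(["homref"])


class TestMarkerTable:
    def test_duplicate_samples_rejected(self):
        meta = pd.DataFrame({"marker": ["m"], "chrom": ["c"], "bp": [1]})
        calls = pd.DataFrame([["hom_ref", "het"]], columns=["s", "s"])
        with pytest.raises(ValueError, match="duplicate sample"):
            MarkerTable(meta, calls)

    def test_positions_strictly_increasing(self):
        meta = pd.DataFrame({"marker": ["a", "b"], "chrom": ["c", "c"], "bp": [5, 5]})
        calls = pd.DataFrame({"s": ["het", "het"]})
        with pytest.raises(ValueError, match="strictly increasing"):
            MarkerTable(meta, calls)

    def test_bad_call_value_rejected(self):
        meta = pd.DataFrame({"marker": ["a"], "chrom": ["c"], "bp": [1]})
        calls = pd.DataFrame({"s": ["0/1"]})
        with pytest.raises(ValueError, match="unknown call"):
            MarkerTable(meta, calls)

    def test_tsv_round_trip(self, tmp_path):
        table = make_table("RR.AA")
        path = tmp_path / "t.tsv"
        table.to_tsv(path)
        clone = MarkerTable.from_tsv(path)
        pd.testing.assert_frame_equal(clone.meta, table.meta)
        pd.testing.assert_frame_equal(clone.calls, table.calls)
        assert clone.roles == table.roles

    def test_vcf_import(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=Vu01,length=100000>\n'
            "##FORMAT=<ID=GT,Number=1,Type=String,Description=\"Genotype\">\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsA\tsB\tsC\n"
            "Vu01\t100\tsnp1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "Vu01\t200\tsnp2\tC\tT\t.\t.\t.\tGT\t./.\t1|1\t0/0\n"
        )
        table = MarkerTable.from_vcf(str(vcf))
        assert table.samples == ["sA", "sB", "sC"]
        assert table.calls.loc[0].tolist() == ["hom_ref", "het", "hom_alt"]
        assert table.calls.loc[1].tolist() == ["missing", "hom_alt", "hom_ref"]


class TestFilterPolymorphic:
    def _table(self, pa, pb):
        n = len(pa)
        meta = pd.DataFrame({"marker": [f"m{i}" for i in range(n)],
                             "chrom": ["c"] * n, "bp": range(1, n + 1)})
        calls = pd.DataFrame({"pa": pa, "pb": pb})
        return MarkerTable(meta, calls)

    def test_opposite_homozygotes_kept(self):
        out = filter_polymorphic(self._table(["hom_ref"], ["hom_alt"]), "pa", "pb")
        assert out.n_markers == 1

    def test_shared_homozygote_dropped(self):
        out = filter_polymorphic(self._table(["hom_ref"], ["hom_ref"]), "pa", "pb")
        assert out.n_markers == 0

    def test_missing_parent_dropped(self):
        out = filter_polymorphic(
            self._table(["missing", "hom_alt"], ["hom_alt", "hom_ref"]), "pa", "pb"
        )
        assert out.meta["marker"].tolist() == ["m1"]

    def test_absent_parent_errors(self):
        with pytest.raises(KeyError):
            filter_polymorphic(self._table(["het"], ["het"]), "pa", "nope")


class TestBsaScan:
    def test_recovers_embedded_run(self, rng):
        states = ["."] * 500
        states[200:212] = ["R"] * 12
        table = make_table("".join(states))
        regions = bsa_scan(table, "rec_bulk", "dom_bulk", min_run=5)
        assert len(regions) == 1
        r = regions[0]
        assert r.n_markers == 12
        assert (r.start, r.end) == (1000 * 201, 1000 * 212)
        assert r.flank_left == "m0200" and r.flank_right == "m0211"

    def test_no_qualifying_markers(self):
        regions = bsa_scan(make_table("." * 50), "rec_bulk", "dom_bulk")
        assert regions == []

    def test_gap_merging(self):
        # two 6-marker runs split by one discordant marker
        table = make_table("...RRRRRR.RRRRRR...")
        merged = bsa_scan(table, "rec_bulk", "dom_bulk", min_run=5, max_gap=1)
        assert len(merged) == 1
        assert merged[0].n_markers == 12
        split = bsa_scan(table, "rec_bulk", "dom_bulk", min_run=5, max_gap=0)
        assert len(split) == 2

    def test_short_runs_discarded(self):
        table = make_table("..RRRR..")
        assert bsa_scan(table, "rec_bulk", "dom_bulk", min_run=5) == []
        assert len(bsa_scan(table, "rec_bulk", "dom_bulk", min_run=4)) == 1

    def test_opposite_orientation_not_merged(self):
        table = make_table("RRRRRRAAAAAA")
        regions = bsa_scan(table, "rec_bulk", "dom_bulk", min_run=5, max_gap=1)
        assert len(regions) == 2
        assert {r.n_markers for r in regions} == {6}

    def test_row_order_invariance(self, rng):
        states = ["."] * 100
        states[40:50] = ["R"] * 10
        table = make_table("".join(states))
        shuffled = rng.permutation(len(states))
        scrambled = MarkerTable(
            table.meta.iloc[shuffled].reset_index(drop=True),
            table.calls.iloc[shuffled].reset_index(drop=True),
            table.roles,
        )
        assert bsa_scan(table, "rec_bulk", "dom_bulk") == bsa_scan(
            scrambled, "rec_bulk", "dom_bulk"
        )

    def test_regions_reverify(self):
        states = ["."] * 60
        states[10:20] = ["R"] * 10
        states[40:48] = ["A"] * 8
        table = make_table("".join(states))
        for r in bsa_scan(table, "rec_bulk", "dom_bulk"):
            assert verify_region(table, r, "rec_bulk", "dom_bulk")

    def test_absent_bulk_errors(self):
        with pytest.raises(KeyError):
            bsa_scan(make_table("RRRRR"), "rec_bulk", "nope")


class TestIntersectBlocks:
    def test_four_population_example(self):
        regions = [region("c", 1000, 5000), region("c", 2000, 6000),
                   region("c", 1500, 5500), region("c", 2500, 4500)]
        block = intersect_blocks(regions)
        assert (block.start, block.end) == (2500, 4500)
        assert block.length == 2001

    def test_single_population_identity(self):
        r = region("c", 10, 99)
        block = intersect_blocks([r])
        assert (block.start, block.end) == (10, 99)

    def test_disjoint_errors(self):
        with pytest.raises(ValueError, match="no shared block"):
            intersect_blocks([region("c", 1, 10), region("c", 20, 30)])

    def test_multiple_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="chromosomes"):
            intersect_blocks([region("c1", 1, 10), region("c2", 5, 15)])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no regions"):
            intersect_blocks([])

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(0, 500)).map(
                lambda t: (min(t), max(t))
            ),
            min_size=2,
            max_size=6,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_commutative_and_associative(self, intervals):
        regions = [region("c", a + 1, b + 1000) for a, b in intervals]
        ordered = intersect_blocks(regions)
        shuffled = intersect_blocks(list(reversed(regions)))
        assert (ordered.start, ordered.end) == (shuffled.start, shuffled.end)
        left = intersect_blocks(
            [intersect_blocks(regions[:2])] + regions[2:]
        )
        assert (left.start, left.end) == (ordered.start, ordered.end)


class TestCoordinates:
    def test_length_is_inclusive(self):
        assert region("c", 100, 100).length == 1
        assert region("c", 1, 10).length == 10

    def test_bed_interval_round_trip(self):
        r = region("Vu07", 20315975, 20544306)
        chrom, start0, end = r.to_bed_interval()
        assert (start0, end) == (20315974, 20544306)
        back = Region.from_bed_interval(chrom, start0, end)
        assert (back.start, back.end) == (r.start, r.end)

    def test_bed_file_round_trip(self, tmp_path):
        regions = [region("c1", 100, 250), region("c2", 1, 1)]
        path = tmp_path / "r.bed"
        regions_to_bed(regions, path)
        back = regions_from_bed(path)
        assert [(r.chromosome, r.start, r.end) for r in back] == [
            ("c1", 100, 250), ("c2", 1, 1)
        ]

    def test_region_tsv(self, tmp_path):
        path = tmp_path / "r.tsv"
        regions_to_tsv([region("c", 5, 25)], path)
        df = pd.read_csv(path, sep="\t")
        assert df.loc[0, "length"] == 21

    def test_invalid_region_rejected(self):
        with pytest.raises(ValueError, match="start"):
            region("c", 10, 5)
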