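import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ncoscan import pedio

from conftest import genotype_matrix_from_arrays, make_individuals


class TestSnpClass:
    @pytest.mark.parametrize(
        "a0,a1,expect",
        [
            ("A", "G", "AT_GC"), ("A", "C", "AT_GC"), ("T", "G", "AT_GC"),
            ("G", "A", "AT_GC"), ("A", "T", "AT_AT"), ("C", "G", "CG_CG"),
        ],
    )
    def test_classification(self, a0, a1, expect):
        assert pedio.classify_snp(a0, a1) == expect

    def test_invalid_alleles_rejected(self):
        with pytest.raises(pedio.InputError):
            pedio.classify_snp("A", "A")
        with pytest.raises(pedio.InputError):
            pedio.classify_snp("A", "N")

    @given(st.sampled_from("ACGT"), st.sampled_from("ACGT"))
    @settings(max_examples=16, deadline=None)
    def test_at_gc_iff_one_allele_each_class(self, a0, a1):
        if a0 == a1:
            return
        expect = (a0 in "AT") != (a1 in "AT")
        assert (pedio.classify_snp(a0, a1) == "AT_GC") == expect


class TestPedigree:
    def test_twelve_member_family_analyzable(self, twelve_member_family, tmp_path):
        peds = pedio.build_pedigree_set(twelve_member_family)
        assert len(peds.analyzable()) == 1
        ped = peds.analyzable()[0]
        assert ped.father == "P1" and ped.mother == "P2"
        assert len(ped.children) == 4
        assert set(ped.analyzed) == {"C1", "C2"}
        assert ped.analyzed["C1"] == ("C1P", ["G1", "G2"])
        # round-trips through the PED dialect
        path = tmp_path / "fam.ped"
        pedio.write_pedigree(peds, path)
        again = pedio.read_pedigree(path)
        assert [p.family for p in again.analyzable()] == ["F1"]
        assert again.analyzable()[0].analyzed == ped.analyzed

    def test_two_children_not_analyzable(self):
        rows = [
            ("F1", "P1", "0", "0", "M", "gen1"),
            ("F1", "P2", "0", "0", "F", "gen1"),
            ("F1", "C1", "P1", "P2", "M", "gen2"),
            ("F1", "C2", "P1", "P2", "F", "gen2"),
            ("F1", "C1P", "0", "0", "F", "gen2_partner"),
            ("F1", "G1", "C1", "C1P", "M", "gen3"),
        ]
        peds = pedio.build_pedigree_set(make_individuals(rows))
        assert not peds.pedigrees[0].analyzable
        assert any("gen2 children" in r for r in peds.pedigrees[0].reasons)

    def test_child_without_grandchild_not_analyzed(self, twelve_member_family):
        df = twelve_member_family[~twelve_member_family.id.isin(["G3", "G4"])]
        peds = pedio.build_pedigree_set(df)
        ped = peds.analyzable()[0]
        assert "C2" not in ped.analyzed  # partner present but no child
        assert "C1" in ped.analyzed

    def test_missing_parent_reference_is_fatal(self):
        rows = [
            ("F1", "P1", "0", "0", "M", "gen1"),
            ("F1", "C1", "P1", "PX", "M", "gen2"),
        ]
        with pytest.raises(pedio.InputError, match="PX"):
            pedio.build_pedigree_set(make_individuals(rows))


class TestGeneticMap:
    def test_three_anchor_map(self, tmp_path):
        p = tmp_path / "map.txt"
        p.write_text(
            "chrom pos rate cM\n"
            "chr1 1 1.0 0.0\nchr1 500001 1.0 0.5\nchr1 1000001 1.0 1.0\n"
        )
        m = pedio.read_genetic_map(p)
        assert m.total_cm("chr1") == pytest.approx(1.0)
        assert m.cm_at("chr1", 250001)[0] == pytest.approx(0.25)
        assert np.isnan(m.cm_at("chr1", 2_000_000)[0])

    def test_decreasing_cm_is_fatal_with_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("chr1 1 1.0 0.0\nchr1 1000 1.0 0.5\nchr1 2000 1.0 0.2\n")
        with pytest.raises(pedio.InputError, match=":3"):
            pedio.read_genetic_map(p)

    def test_round_trip(self, tmp_path):
        m = pedio.flat_map({"chr1": 1_000_000, "chr2": 2_000_000}, 1.3)
        path = tmp_path / "m.txt"
        pedio.write_genetic_map(m, path)
        m2 = pedio.read_genetic_map(path)
        for c in m.chromosomes:
            np.testing.assert_allclose(m2.chrom_pos[c], m.chrom_pos[c])
            np.testing.assert_allclose(m2.chrom_cm[c], m.chrom_cm[c])

    def test_inverse_interpolation(self):
        m = pedio.flat_map({"c": 2_000_000}, 1.0)
        pos = m.pos_at_cm("c", [0.5])[0]
        assert m.cm_at("c", pos)[0] == pytest.approx(0.5)


class TestIntervals:
    def test_bed_line_is_half_open(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        t = pedio.read_intervals(p)
        # BED [100, 200) == 1-based [101, 200]
        assert t.contains("chr1", [100])[0] == False  # noqa: E712
        assert t.contains("chr1", [101])[0]
        assert t.contains("chr1", [200])[0]
        assert not t.contains("chr1", [201])[0]

    def test_overlapping_intervals_retained(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t50\nchr1\t30\t40\n")
        t = pedio.read_intervals(p)
        assert t.n_intervals == 2

    def test_empty_track(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("")
        t = pedio.read_intervals(p)
        assert not t.contains("chr1", [5])[0]
        assert t.total_bp() == 0

    def test_bad_interval_fatal(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(pedio.InputError, match=":1"):
            pedio.read_intervals(p)

    def test_round_trip(self, tmp_path):
        t = pedio.IntervalTrack(
            "x", {"c": np.array([[11, 20], [5, 8], [15, 40]])}
        )
        path = tmp_path / "t.bed"
        pedio.write_intervals(t, path)
        t2 = pedio.read_intervals(path)
        np.testing.assert_array_equal(
            t2.intervals["c"], t.intervals["c"]
        )

    @given(st.lists(st.tuples(st.integers(1, 200), st.integers(1, 50)),
                    min_size=1, max_size=20),
           st.lists(st.integers(1, 300), min_size=1, max_size=30))
    @settings(max_examples=30, deadline=None)
    def test_contains_matches_brute_force(self, spans, queries):
        iv = np.array([[lo, lo + ln] for lo, ln in spans])
        t = pedio.IntervalTrack("x", {"c": iv})
        got = t.contains("c", queries)
        for q, g in zip(queries, got):
            assert g == any(lo <= q <= hi for lo, hi in iv)


class TestVcf:
    def test_write_read_round_trip(self, tmp_path, twelve_member_family):
        peds = pedio.build_pedigree_set(twelve_member_family)
        rng = np.random.default_rng(5)
        gm = genotype_matrix_from_arrays(
            "chr1", [100, 200, 300, 400],
            {s: rng.integers(0, 3, 4) for s in peds.sample_ids},
        )
        gm.dosage[2, 3] = pedio.MISSING
        path = tmp_path / "g.vcf"
        pedio.write_vcf(gm, path)
        gm2 = pedio.read_genotypes(path, peds)
        np.testing.assert_array_equal(gm2.dosage, gm.dosage)
        assert list(gm2.markers.pos) == [100, 200, 300, 400]
        assert (gm2.markers.snp_class == "AT_GC").all()

    def test_indel_skipped_and_missing_sample_fatal(self, tmp_path,
                                                    twelve_member_family):
        peds = pedio.build_pedigree_set(twelve_member_family)
        gts = "\t".join(["0/1"] * 12)
        path = tmp_path / "g.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(peds.sample_ids) + "\n"
            f"chr1\t100\tv1\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            f"chr1\t200\tv2\tA\tAT\t.\tPASS\t.\tGT\t{gts}\n"
        )
        gm = pedio.read_genotypes(path, peds)
        assert len(gm.markers) == 1 and gm.n_skipped == 1
        bad = pedio.build_pedigree_set(
            make_individuals([("F9", "ZZ", "0", "0", "M", "gen1"),
                              ("F9", "ZY", "0", "0", "F", "gen1")])
        )
        with pytest.raises(pedio.InputError, match="ZZ"):
            pedio.read_genotypes(path, bad)
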