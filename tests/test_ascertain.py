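"""Toy-pedigree tests of the six informative-site requirements and site QC.

The base family: father heterozygous at every marker with haplotypes
(all-0, all-1), mother and all married-in founders homozygous 0.  Children
C1/C3 receive the father's haplotype 0, C2/C4 haplotype 1; grandchild G3
receives C2's paternal haplotype, G4 the maternal one.  Under this setup
the father->child transmissions are fully determined and every interior
marker is informative for (father, C1) and (father, C2).
"""

import numpy as np
import pytest

from ncoscan import pedio
from ncoscan.pipeline import analyze

from conftest import genotype_matrix_from_arrays

M = 12
MID = 6


def base_dosages():
    z = np.zeros(M, dtype=np.int8)
    o = np.ones(M, dtype=np.int8)
    return {
        "P1": o.copy(),   # father het everywhere
        "P2": z.copy(),
        "C1": z.copy(),   # father hap0 (allele 0) + mother 0
        "C2": o.copy(),   # father hap1 (allele 1) + mother 0
        "C3": z.copy(),
        "C4": o.copy(),
        "C1P": z.copy(),
        "C2P": z.copy(),
        "G1": z.copy(),
        "G2": z.copy(),
        "G3": o.copy(),   # C2's paternal haplotype (allele 1) + partner 0
        "G4": z.copy(),
    }


@pytest.fixture()
def toy(twelve_member_family):
    peds = pedio.build_pedigree_set(twelve_member_family)

    def run(dosages):
        gm = genotype_matrix_from_arrays(
            "chr1", (np.arange(M) + 1) * 1000, dosages
        )
        return gm, analyze(peds, gm)

    return peds, run


class TestRequirements:
    def test_base_family_interior_markers_informative(self, toy):
        peds, run = toy
        _gm, res = run(base_dosages())
        row = res.table.rows[("F1", "P1", "C2")]
        assert row.informative[1:-1].all()
        assert not row.informative[0] and not row.informative[M - 1]  # R3
        assert not res.events

    def test_homozygous_parent_never_informative(self, toy):
        peds, run = toy
        _gm, res = run(base_dosages())
        for child in ("C1", "C2"):
            row = res.table.rows[("F1", "P2", child)]  # mother hom 0
            assert not row.informative.any()
            assert not row.flags[0].any()  # R1

    def test_sole_haplotype_recipient_fails_r4(self, toy):
        peds, run = toy
        d = base_dosages()
        d["C4"] = np.zeros(M, dtype=np.int8)  # now C2 alone carries hap1
        _gm, res = run(d)
        row = res.table.rows[("F1", "P1", "C2")]
        assert not row.informative.any()
        assert not row.flags[3].any()  # R4: no second child shares hap1
        # the other children still qualify
        assert res.table.rows[("F1", "P1", "C1")].informative[1:-1].all()

    def test_onward_transmission_required_r2(self, toy):
        peds, run = toy
        d = base_dosages()
        d["G3"] = np.zeros(M, dtype=np.int8)  # G3 now gets C2's maternal hap
        _gm, res = run(d)
        row = res.table.rows[("F1", "P1", "C2")]
        # father's allele 1 reaches no grandchild of C2
        assert not row.informative.any()
        assert not row.flags[1].any()

    def test_child_hom_all_others_het_fails_r5(self, toy):
        peds, run = toy
        d = base_dosages()
        # at MID: mother het, all children het except C2 hom
        d["P2"][MID] = 1
        d["C1"][MID] = 1
        d["C3"][MID] = 1
        d["C4"][MID] = 1  # het: father 1 + mother 0 (or father 0 + mother 1)
        d["C2"][MID] = 0  # hom: a NCO would make it het -> all het
        _gm, res = run(d)
        row = res.table.rows[("F1", "P1", "C2")]
        assert not row.flags[4][MID]  # R5
        assert not row.informative[MID]
        # flanking markers unaffected
        assert row.informative[MID - 1] and row.informative[MID + 1]


class TestSiteQC:
    def test_missing_genotype_masks_site_for_pedigree(self, toy):
        peds, run = toy
        d = base_dosages()
        d["C3"][MID] = pedio.MISSING
        _gm, res = run(d)
        assert not res.table.qc_mask["F1"][MID]
        for key in (("F1", "P1", "C1"), ("F1", "P1", "C2")):
            assert not res.table.rows[key].informative[MID]

    def test_gen3_single_site_nco_masks_site(self, toy):
        peds, run = toy
        d = base_dosages()
        d["G3"][MID] = 0  # G3 switches to C2's maternal hap at one marker
        _gm, res = run(d)
        assert not res.table.qc_mask["F1"][MID]
        assert not res.table.rows[("F1", "P1", "C2")].informative[MID]
        assert not res.events

    def test_exclusion_track_masks_sites(self, toy, twelve_member_family):
        from ncoscan.pipeline import AnalysisConfig

        peds = pedio.build_pedigree_set(twelve_member_family)
        gm = genotype_matrix_from_arrays(
            "chr1", (np.arange(M) + 1) * 1000, base_dosages()
        )
        excl = pedio.IntervalTrack("x", {"chr1": np.array([[6500, 7500]])})
        res = analyze(peds, gm, AnalysisConfig(exclusion=excl))
        row = res.table.rows[("F1", "P1", "C2")]
        assert not row.informative[MID]  # pos 7000 inside the track


class TestDetectionOnToy:
    def test_single_site_conversion_called_and_counted(self, toy):
        peds, run = toy
        d = base_dosages()
        # conversion in C2 at MID: father transmits hap0 allele (0) inside
        # a hap1 background; transmitted onward to G3
        d["C2"][MID] = 0
        d["G3"][MID] = 0
        _gm, res = run(d)
        assert len(res.events) == 1
        e = res.events[0]
        assert e.child == "C2" and e.parent == "P1"
        assert e.sites.tolist() == [MID]
        assert e.alleles.tolist() == [0]
        assert not e.ambiguous and e.weight == 1.0
        assert e.klass == "NCO"
        assert e.tract_lower == 1 and e.tract_upper == 1999
        # numerator/denominator symmetry: converted site is informative
        row = res.table.rows[("F1", "P1", "C2")]
        assert row.informative[MID]

    def test_nonstandard_event_at_ambiguous_marker(self, toy):
        """A child homozygous at a marker where every other family member is
        heterozygous sits on ambiguously phased ground and is excluded from
        the rate; when a sibling's own nuclear family pins the parental
        phase and the homozygote contradicts its background haplotype, the
        conversion is still called, flagged non-standard."""
        peds, run = toy
        d = self._ambiguous_marker_dosages()
        # conversion in C2 at MID: the father transmits his other
        # haplotype's allele (1), making C2 homozygous 1/1 while every
        # other family member is heterozygous there
        d["C2"][MID] = 2
        d["G3"][MID] = 1  # transmitted onward along C2's paternal chromatid
        _gm, res = run(d)
        ns = [e for e in res.events if e.ascertainment == "nonstandard"]
        assert len(ns) == 1
        e = ns[0]
        assert e.child == "C2" and e.parent == "P1"
        assert e.sites.tolist() == [MID]
        assert e.alleles.tolist() == [1]
        # excluded from the rate's numerator and denominator
        row = res.table.rows[("F1", "P1", "C2")]
        assert not row.informative[MID]
        sites, _w = res.nco_site_weights()
        assert MID not in sites

    @staticmethod
    def _ambiguous_marker_dosages():
        """Father het everywhere (haps all-0 / all-1); mother hom 0 except
        het at MID (haps 0s / 1-at-MID).  C1/C4 carry the father's 1-hap
        and the mother's 0-hap; C2/C3 the father's 0-hap and the mother's
        MID-1 hap.  At MID the whole family is het, so phase there is
        pinned only through C1's own nuclear family (partner hom, one
        grandchild per C1 haplotype)."""
        o = np.ones(M, dtype=np.int8)
        z = np.zeros(M, dtype=np.int8)
        z_mid1 = z.copy()
        z_mid1[MID] = 1
        p2 = z.copy()
        p2[MID] = 1
        return {
            "P1": o.copy(), "P2": p2,
            "C1": o.copy(), "C4": o.copy(),
            "C2": z_mid1.copy(), "C3": z_mid1.copy(),
            "C1P": z.copy(), "C2P": z.copy(),
            "G1": o.copy(),       # C1's paternal haplotype
            "G2": z.copy(),       # C1's maternal haplotype
            "G3": z_mid1.copy(),  # C2's paternal haplotype
            "G4": z_mid1.copy(),  # C2's maternal haplotype
        }

    def test_ambiguous_marker_het_child_no_event(self, toy):
        peds, run = toy
        d = self._ambiguous_marker_dosages()  # C2 het at MID: no conversion
        _gm, res = run(d)
        assert not [e for e in res.events if e.ascertainment == "nonstandard"]

    def test_conversion_not_transmitted_to_gen3_is_not_called(self, toy):
        peds, run = toy
        d = base_dosages()
        d["C2"][MID] = 0  # conversion, but G3 keeps allele 1
        _gm, res = run(d)
        assert not res.events
        # and the site is no longer informative for C2 (R2 fails there)
        assert not res.table.rows[("F1", "P1", "C2")].informative[MID]
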