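"""Pedigree-level site QC and the six informative-site requirements.

A site is informative for a (parent, child) transmission when a gene
conversion occurring there would be detectable, and the detection's
numerator (converted sites) and denominator (informative sites) are
ascertained identically.  The six requirements, per (gen1 parent P,
analyzed gen2 child C, marker):

Requirements whose outcome depends on C's genotype are evaluated on the
*converted* genotype — the observed one at putative-NCO sites, the
counterfactual allele flip elsewhere (propagated to grandchildren along
C's P-derived chromatid) — which keeps numerator and denominator
identically ascertained:

R1  P is heterozygous.
R2  a grandchild carries C's chromatid derived from P (where a conversion
    would sit), with its allele-from-C determinable from genotypes under
    the converted configuration (C or partner homozygous, or the grandchild
    itself homozygous) and consistent with the converted allele.
R3  not the first or last otherwise-qualifying site of the chromosome
    (detection needs a flanking informative site on each side).
R4  siblings attest both parental haplotypes at the site: a second gen2
    child received the same haplotype of P as C's local background, and at
    least one sibling received the opposite haplotype (otherwise P
    "transmits only one haplotype" there and P's heterozygous call rests
    entirely on the putative conversion — the signature of a genotyping
    error in P or in the other parent).
R5  phase unambiguous across two generations and under the conversion:
    when the other gen1 parent is heterozygous, a conversion is
    unambiguously placeable only if the converted genotype is homozygous
    and at least two homozygous siblings pin the parental phase (a single
    one yields a minimum-recombinant tie — the non-standard category).
R6  when the converted genotype is homozygous, gen3 attestation is vacuous
    and a single het->hom miscall in C can mimic a conversion; the site
    counts only if the partner is homozygous and a grandchild demonstrably
    received P's chromatid.

Pedigree site QC additionally masks, per pedigree: sites with any missing
genotype; sites exhibiting a single-site NCO in any grandchild
(second-to-third generation); and sites inside user-supplied exclusion
intervals.

The requirements reference putative-NCO status, so flags are resolved in
two passes: candidate conversions are detected on provisionally informative
sites, then the final flags and events are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ncoscan import detect as _detect
from ncoscan.pedio import GenotypeMatrix, IntervalTrack, Pedigree, PedigreeSet
from ncoscan.phase import PedigreePhase, fill_nearest


@dataclass
class MeiosisRows:
    """Ascertainment state for one (pedigree, parent, child) over all markers."""

    family: str
    parent: str
    parent_sex: str
    child: str
    flags: np.ndarray  # (6, n_markers) bool, R1..R6
    informative: np.ndarray  # (n_markers,) bool
    vector: np.ndarray  # physical transmission bits (int8)
    received: np.ndarray  # allele received from parent (-1 unknown)
    nco_waiver: np.ndarray  # putative-NCO sites (pass 1)


@dataclass
class InformativeSiteTable:
    """Informative-site flags for every analyzed (parent, child) pair."""

    markers: pd.DataFrame
    rows: dict[tuple[str, str, str], MeiosisRows] = field(default_factory=dict)
    qc_mask: dict[str, np.ndarray] = field(default_factory=dict)

    def n_informative(self) -> int:
        return int(sum(r.informative.sum() for r in self.rows.values()))

    def informative_counts(self) -> pd.DataFrame:
        rec = [
            dict(family=f, parent=p, child=c, n=int(r.informative.sum()))
            for (f, p, c), r in self.rows.items()
        ]
        return pd.DataFrame(rec)

    def exposure_by_marker(self) -> np.ndarray:
        """Number of informative (parent, child) rows per marker."""
        out = np.zeros(len(self.markers), dtype=np.int64)
        for r in self.rows.values():
            out += r.informative
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (informative rows only)."""
        rec = []
        pos = self.markers["pos"].to_numpy()
        chroms = self.markers["chrom"].to_numpy()
        for (f, p, c), r in self.rows.items():
            for m in np.flatnonzero(r.informative):
                rec.append(
                    dict(family=f, parent=p, child=c, chrom=chroms[m],
                         pos=int(pos[m]), marker=int(m))
                )
        return pd.DataFrame(rec)


def pedigree_site_qc(
    ped: Pedigree,
    gm: GenotypeMatrix,
    phases: dict[str, PedigreePhase],
    exclusion: IntervalTrack | None = None,
    window: int = _detect.SCAN_WINDOW,
) -> tuple[np.ndarray, dict]:
    """Per-pedigree site validity mask plus pass-1 putative-NCO candidates.

    Returns (mask (n_markers,) bool, candidates) where candidates maps
    (parent, child) -> list of (chrom, CandidateRun with global indices).
    """
    n = len(gm.markers)
    mask = np.ones(n, dtype=bool)
    # (a) all pedigree members genotyped
    for member in ped.members:
        mask &= gm.of(member) != -1
    # (d) exclusion intervals
    if exclusion is not None:
        pos = gm.markers["pos"].to_numpy()
        for chrom in gm.chromosomes:
            sl = gm.chrom_slice(chrom)
            mask[sl] &= ~exclusion.contains(chrom, pos[sl])
    pos_all = gm.markers["pos"].to_numpy()
    # (b) single-site NCO transmitted from the second to the third generation
    for chrom, pp in phases.items():
        sl = gm.chrom_slice(chrom)
        off = sl.start
        for child, (partner, gkids) in ped.analyzed.items():
            fam2 = pp.gen2[child]
            for p, parent_id in ((0, child), (1, partner)):
                dP = gm.of(parent_id)[sl]
                for gi in range(len(gkids)):
                    informative = (dP == 1) & ~fam2.amb[p, gi] & mask[sl]
                    if informative.sum() < 3:
                        continue
                    cands = _detect.find_double_switches(
                        fam2.trans[p, gi], informative, pos_all[sl], window
                    )
                    for cand in cands:
                        for sites in (cand.sites, cand.sites_b):
                            if sites.size == 1:
                                mask[off + sites[0]] = False
    # pass-1 gen1 candidates (putative NCO sites, for the R4 waiver and the
    # background-haplotype evaluation at converted sites)
    candidates: dict[tuple[str, str], list] = {}
    for chrom, pp in phases.items():
        sl = gm.chrom_slice(chrom)
        off = sl.start
        fam1 = pp.gen1
        for p, parent_id in ((0, ped.father), (1, ped.mother)):
            dP = gm.of(parent_id)[sl]
            for child in ped.analyzed:
                ci = ped.children.index(child)
                informative = (dP == 1) & ~fam1.amb[p, ci] & mask[sl]
                if informative.sum() < 3:
                    continue
                cands = _detect.find_double_switches(
                    fam1.trans[p, ci], informative, pos_all[sl], window
                )
                kept = []
                for cand in cands:
                    cand.sites = cand.sites + off
                    cand.sites_b = cand.sites_b + off
                    kept.append((chrom, cand))
                candidates.setdefault((parent_id, child), []).extend(kept)
    return mask, candidates


def ascertain_informative(
    peds: PedigreeSet,
    gm: GenotypeMatrix,
    ped: Pedigree,
    phases: dict[str, PedigreePhase],
    mask: np.ndarray,
    candidates: dict[tuple[str, str], list],
    table: InformativeSiteTable | None = None,
) -> InformativeSiteTable:
    """Evaluate the six requirements for every (gen1 parent, analyzed child)."""
    if table is None:
        table = InformativeSiteTable(gm.markers)
    n = len(gm.markers)
    pos = gm.markers["pos"].to_numpy()
    sex = {ped.father: "M", ped.mother: "F"}
    for p, parent_id in ((0, ped.father), (1, ped.mother)):
        dP_all = gm.of(parent_id)
        for child in ped.analyzed:
            ci = ped.children.index(child)
            partner, gkids = ped.analyzed[child]
            flags = np.zeros((6, n), dtype=bool)
            vector = np.zeros(n, dtype=np.int8)
            received = np.full(n, -1, dtype=np.int8)
            waiver = np.zeros(n, dtype=bool)
            bg_override = np.full(n, -1, dtype=np.int8)
            for chrom, cand in candidates.get((parent_id, child), []):
                waiver[cand.sites] = True
                waiver[cand.sites_b] = True
                bg_override[cand.sites] = cand.background
                bg_override[cand.sites_b] = cand.background_b
            for chrom in gm.chromosomes:
                pp = phases[chrom]
                sl = gm.chrom_slice(chrom)
                fam1, fam2 = pp.gen1, pp.gen2[child]
                dP = dP_all[sl]
                dC = gm.of(child)[sl]
                r = fam1.received[p, ci]
                v = fam1.trans[p, ci]
                amb1 = fam1.amb[p, ci]
                vector[sl] = v
                received[sl] = r
                r1 = dP == 1
                # converted genotype of the child: observed at putative-NCO
                # sites, the counterfactual allele flip elsewhere; several
                # requirements below are evaluated on it so that numerator
                # and denominator stay identically ascertained
                hypo = dC + 1 - 2 * np.clip(r, 0, 1)
                w_sl = waiver[sl]
                conv_d = np.where(w_sl, dC, hypo)
                delta = np.where(w_sl, 0, 1 - 2 * np.clip(r, 0, 1)).astype(np.int8)
                dPt = gm.of(partner)[sl]
                partner_hom = (dPt == 0) | (dPt == 2)
                cv_c_hom = (conv_d == 0) | (conv_d == 2)
                orient = pp.orient[child]
                omask = pp.orient_mask[child]
                # R2 (conversion-detectability form): a grandchild must carry
                # the child's chromatid derived from the transmitting parent
                # (which is where a conversion would sit), with its
                # allele-from-child determinable from genotypes under the
                # converted configuration — the child or the partner
                # homozygous, or the grandchild itself homozygous after the
                # conversion propagates along that chromatid.
                y = np.where(w_sl, r, 1 - np.clip(r, 0, 1)).astype(np.int8)
                pt_lo = (dPt == 2).astype(np.int8)  # partner's forced allele
                pt_hi = np.where(dPt == 1, 1, pt_lo).astype(np.int8)
                r2 = np.zeros(len(r), dtype=bool)
                on_p_any = np.zeros(len(r), dtype=bool)
                for gi, g in enumerate(gkids):
                    reliable = (dC == 1) & ~fam2.amb[0, gi]
                    bits = fill_nearest(fam2.trans[0, gi], reliable)
                    onp = ((bits ^ orient) == p) & ~omask
                    on_p_any |= onp
                    dg = gm.of(g)[sl]
                    dg_cv = np.where(onp, dg + delta, dg)
                    det = cv_c_hom | partner_hom | (dg_cv == 0) | (dg_cv == 2)
                    # the grandchild's (converted) genotype must be consistent
                    # with receiving the converted allele from the child
                    consistent = (dg_cv >= y + pt_lo) & (dg_cv <= y + pt_hi)
                    r2 |= onp & det & consistent
                r2 &= (r >= 0) & ~fam2.mendel
                # R4: siblings must attest BOTH parental haplotypes at the
                # site — one sharing the child's background (validating the
                # allele a conversion would replace) and one carrying the
                # opposite haplotype (so the parental het call does not rest
                # on the putative conversion alone).  At putative-NCO sites
                # the child's background haplotype stands in for its own bit.
                bg = np.where(bg_override[sl] >= 0, bg_override[sl], v)
                same = np.zeros(len(r), dtype=bool)
                other = np.zeros(len(r), dtype=bool)
                for cj in range(len(ped.children)):
                    if cj == ci:
                        continue
                    ok_cj = ~fam1.amb[p, cj]
                    same |= (fam1.trans[p, cj] == bg) & ok_cj
                    other |= (fam1.trans[p, cj] == 1 - bg) & ok_cj
                r4 = same & other & (~amb1 | waiver[sl])
                # R5: unambiguous phase now and under a (counterfactual)
                # conversion.  When the other gen1 parent is heterozygous,
                # children's received alleles are determined only where they
                # are homozygous; a conversion is then unambiguously
                # detectable only if the converted genotype is homozygous
                # (a het child of two hets has undetermined parental origin)
                # and at least two homozygous siblings pin the parental
                # phase (a single one produces a minimum-recombinant tie:
                # either the recipient or that sibling recombined).
                other_parent = ped.mother if p == 0 else ped.father
                e_het = gm.of(other_parent)[sl] == 1
                hom_sibs = np.zeros(len(r), dtype=np.int16)
                for cj, sib in enumerate(ped.children):
                    if sib == child:
                        continue
                    dS = gm.of(sib)[sl]
                    hom_sibs += (((dS == 0) | (dS == 2))
                                 & ~fam1.amb[p, cj]).astype(np.int16)
                cf_ambiguous = e_het & ((conv_d == 1) | (hom_sibs < 2))
                r5 = (
                    ~amb1
                    & (r >= 0)
                    & ~pp.orient_mask[child][: len(r)]
                    & ~cf_ambiguous
                )
                # R6: guard against miscalled heterozygotes.  When the
                # recipient's genotype *after* a conversion is homozygous,
                # every grandchild trivially carries the converted allele and
                # third-generation attestation is vacuous; a single het->hom
                # error in the recipient can then mimic a conversion.  The
                # attestation is genuine only when the partner is homozygous
                # (so grandchild allele attributions are forced, and a
                # suppressed allele would surface as a Mendelian conflict)
                # and at least one grandchild demonstrably received the
                # recipient's chromatid derived from the transmitting parent.
                # Evaluated on the converted genotype (observed at putative-
                # NCO sites, counterfactual elsewhere), keeping numerator and
                # denominator identically ascertained.
                hom_conv = cv_c_hom & ((r >= 0) | w_sl)
                r6 = ~hom_conv | (partner_hom & on_p_any)
                flags[0, sl] = r1
                flags[1, sl] = r2
                flags[2, sl] = True  # R3 set below, per chromosome
                flags[3, sl] = r4
                flags[4, sl] = r5
                flags[5, sl] = r6
            qualifying = flags.all(axis=0) & mask
            informative = qualifying.copy()
            for chrom in gm.chromosomes:
                sl = gm.chrom_slice(chrom)
                qi = np.flatnonzero(qualifying[sl])
                if qi.size:
                    informative[sl.start + qi[0]] = False
                    informative[sl.start + qi[-1]] = False
                    flags[2, sl.start + qi[0]] = False
                    flags[2, sl.start + qi[-1]] = False
            table.rows[(ped.family, parent_id, child)] = MeiosisRows(
                ped.family, parent_id, sex[parent_id], child,
                flags, informative, vector, received, waiver,
            )
    table.qc_mask[ped.family] = mask
    return table
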