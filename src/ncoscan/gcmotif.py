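"""GC-transmission bias statistics and PRDM9 degenerate-motif scanning.

When heteroduplex DNA formed during recombination carries an AT/GC
mismatch, repair is biased toward the G/C allele (GC-biased gene
conversion).  The strength of the bias is the proportion of converted
heterozygous AT/GC sites transmitting G or C, tested against the Mendelian
1/2 with an exact two-sided binomial test and summarised with a
Clopper-Pearson interval.  Strand-ambiguous A/T and C/G SNPs carry no GC
information and are excluded, as are sites inside PRDM9-motif matches
(where transmission distortion may instead reflect initiation bias) and
crossover-adjacent ambiguous events (converted sites unknown).

The PRDM9 A/B zinc-finger array binds a degenerate 13-mer with eight
non-degenerate ("predictive") positions; a converted SNP sitting on a
predictive position of a >=6/8 match is flagged, along with equally good or
better matches within +-2 kb (which weaken an initiation-bias reading).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_MOTIF = "CCNCCNTNNCCNC"
_GC = frozenset("GC")
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class GCTally:
    """GC vs AT transmission counts at converted heterozygous AT/GC sites."""

    n_gc: int
    n_at: int
    stratum: str = "all"

    @property
    def total(self) -> int:
        return self.n_gc + self.n_at

    @property
    def proportion(self) -> float:
        return self.n_gc / self.total if self.total else float("nan")

    @property
    def p_value(self) -> float:
        """Exact two-sided binomial p versus 1/2 (sum of outcome
        probabilities no larger than the observed outcome's)."""
        if self.total == 0:
            return float("nan")
        return float(stats.binomtest(self.n_gc, self.total, 0.5).pvalue)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Clopper-Pearson exact interval for the GC-transmission proportion."""
        if self.total == 0:
            return (float("nan"), float("nan"))
        r = stats.binomtest(self.n_gc, self.total, 0.5).proportion_ci(
            confidence_level=level, method="exact"
        )
        return (float(r.low), float(r.high))

    def to_dict(self) -> dict:
        lo, hi = self.ci()
        return dict(
            stratum=self.stratum, n_gc=self.n_gc, n_at=self.n_at,
            proportion=self.proportion, ci95=(lo, hi), p_value=self.p_value,
        )


def eligible_gc_sites(events, markers) -> list[dict]:
    """Converted sites entering GC tallies: heterozygous AT/GC sites of
    unambiguous standard events and non-standard events, excluding sites
    annotated as overlapping a PRDM9 motif.

    Returns one record per site with the transmitted-allele class and
    stratum covariates.
    """
    gc_is_a1 = markers["gc_is_a1"].to_numpy()
    snp_class = markers["snp_class"].to_numpy()
    cpg = markers["cpg"].to_numpy()
    out = []
    for e in events:
        if e.ambiguous:
            continue
        motif_sites = set(e.meta.get("motif_sites", ()))
        pairs = list(zip(e.sites.tolist(), e.alleles.tolist()))
        pairs += list(e.meta.get("nonstandard_sites", ()))
        for m, a in pairs:
            if snp_class[m] != "AT_GC" or a < 0 or m in motif_sites:
                continue
            out.append(
                dict(
                    marker=int(m),
                    gc=bool((a == 1) == gc_is_a1[m]),
                    cpg=bool(cpg[m]),
                    parent_sex=e.parent_sex,
                    family=e.family,
                )
            )
    return out


def gc_transmission_test(events, markers, stratum: str = "all") -> GCTally:
    """Overall GC-transmission tally and exact test for the eligible sites."""
    sites = eligible_gc_sites(events, markers)
    n_gc = sum(s["gc"] for s in sites)
    return GCTally(n_gc, len(sites) - n_gc, stratum)


def stratified_homogeneity(tallies: list[GCTally]) -> tuple[float, float]:
    """Chi-square homogeneity of GC proportions across strata (df = k-1)."""
    if len(tallies) < 2:
        raise ValueError("need >=2 strata")
    table = np.array([[t.n_gc, t.n_at] for t in tallies])
    keep = table.sum(axis=1) > 0
    table = table[keep]
    stat, p, _df, _exp = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# PRDM9 motif scanning
# ---------------------------------------------------------------------------


@dataclass
class MotifAnnotation:
    marker: int
    best_score: int  # matching predictive positions (of 8) over the SNP
    snp_at_predictive: bool
    nearby_better: bool  # an equally good or better match within +-2 kb
    strand: str = "."


def _match_score(window: str, motif: str) -> int:
    return sum(
        1 for a, b in zip(window, motif) if b != "N" and a == b
    )


def prdm9_scan(
    sequence: str,
    marker_offset: int,
    marker: int = -1,
    motif: str = DEFAULT_MOTIF,
    min_score: int = 6,
    flank_bp: int = 2000,
) -> MotifAnnotation:
    """Scan a sequence window around a SNP for degenerate 13-mer matches.

    ``sequence`` is the reference window (uppercase ACGTN), ``marker_offset``
    the 0-based index of the SNP within it.  Both strands are scanned at
    every offset; the SNP-overlap flag requires a match of >= ``min_score``
    of the 8 predictive positions with the SNP on a predictive
    (non-degenerate) position.  Matches elsewhere within ``flank_bp`` that
    score at least as well set ``nearby_better``.
    """
    n_pred = sum(1 for b in motif if b != "N")
    if n_pred != 8:
        # the predictive-position count follows the motif; scoring still works
        pass
    L = len(motif)
    seq_f = sequence.upper()
    seq_r = seq_f.translate(_COMP)[::-1]
    best = 0
    snp_pred = False
    strand = "."
    nearby = False
    overlap_best = 0
    for strand_id, seq in (("+", seq_f), ("-", seq_r)):
        for off in range(0, len(seq) - L + 1):
            sc = _match_score(seq[off : off + L], motif)
            if sc < min_score:
                continue
            # map the SNP into this scan's coordinates
            m = marker_offset if strand_id == "+" else len(seq) - 1 - marker_offset
            covers = off <= m < off + L
            if covers:
                if sc > overlap_best:
                    overlap_best = sc
                    strand = strand_id
                if motif[m - off] != "N":
                    snp_pred = True
            best = max(best, sc)
    if overlap_best >= min_score and snp_pred:
        for strand_id, seq in (("+", seq_f), ("-", seq_r)):
            m = marker_offset if strand_id == "+" else len(seq) - 1 - marker_offset
            lo = max(0, m - flank_bp - L + 1)
            hi = min(len(seq) - L, m + flank_bp)
            for off in range(lo, hi + 1):
                if off <= m < off + L:
                    continue
                if _match_score(seq[off : off + L], motif) >= overlap_best:
                    nearby = True
                    break
            if nearby:
                break
    return MotifAnnotation(
        marker, overlap_best, snp_pred and overlap_best >= min_score,
        nearby, strand,
    )


def annotate_events_with_motifs(
    events, markers, fasta, motif: str = DEFAULT_MOTIF, flank_bp: int = 2000
) -> int:
    """Annotate converted sites overlapping PRDM9-motif matches.

    ``fasta`` is a pyfaidx-style mapping of chromosome name to sequence.
    Sites flagged (SNP on a predictive position of a >= 6/8 match) are
    recorded in ``event.meta['motif_sites']`` and excluded from GC tallies.
    Returns the number of flagged sites.
    """
    pos = markers["pos"].to_numpy()
    n_flagged = 0
    for e in events:
        hits = []
        for m in e.all_sites():
            try:
                seq = fasta[e.chrom]
            except KeyError:
                continue
            p = int(pos[m])  # 1-based
            lo = max(0, p - 1 - flank_bp)
            hi = min(len(seq), p + flank_bp)
            window = str(seq[lo:hi])
            ann = prdm9_scan(window, p - 1 - lo, int(m), motif, flank_bp=flank_bp)
            if ann.snp_at_predictive:
                hits.append(int(m))
                e.meta.setdefault("motif_annotations", []).append(ann)
        if hits:
            e.meta["motif_sites"] = hits
            n_flagged += len(hits)
    return n_flagged
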