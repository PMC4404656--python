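"""NCO event detection: double-switch scanning, classification, false-positive
filters, non-standard ascertainment and clustering.

A transmission vector restricted to informative sites is segmented into
maximal constant runs.  Runs longer than the scan window (default 20
informative sites) and the two terminal runs act as *anchors*; short runs
between two anchors of equal haplotype are switch-and-revert candidates
(putative NCO tracts), while short runs between anchors of opposite
haplotype sit next to a crossover and are ambiguous: either the runs
matching the left anchor or those matching the right anchor are the
converted sites, and both orientations are emitted with weight 0.5.
Ambiguity lapses (one orientation becomes definitive, weight 1) when the
competing orientation would require a conversion covering >= 3 sites
spanning more than the NCO span limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ncoscan.phase import PedigreePhase

SCAN_WINDOW = 20  # informative sites, first to last converted inclusive
NCO_SPAN_BP = 5000  # lower-bound span below this => NCO, else long-range
CLUSTER_WINDOW_BP = 30_000
LAPSE_MIN_SITES = 3

CLASS_NCO = "NCO"
CLASS_LONG = "longRange"


@dataclass
class CandidateRun:
    """Candidate double-switch event in informative-site coordinates."""

    sites: np.ndarray  # informative-site ordinals, orientation A
    sites_b: np.ndarray  # orientation B (empty when unambiguous)
    background: int  # haplotype value of the orientation-A background
    background_b: int
    ambiguous: bool


def _runs(v: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs of v as (start, end_inclusive, value)."""
    if v.size == 0:
        return []
    cut = np.flatnonzero(np.diff(v)) + 1
    starts = np.concatenate(([0], cut))
    ends = np.concatenate((cut - 1, [v.size - 1]))
    return [(int(s), int(e), int(v[s])) for s, e in zip(starts, ends)]


def scan_vector(
    v: np.ndarray,
    pos: np.ndarray,
    window: int = SCAN_WINDOW,
    span_limit: int = NCO_SPAN_BP,
) -> list[CandidateRun]:
    """Scan a 0/1 vector over informative sites for double-switch candidates.

    ``pos`` gives bp positions of the informative sites (used only by the
    ambiguity-lapse rule).  Runs longer than ``window`` and the terminal
    runs are anchors and never candidates.
    """
    runs = _runs(np.asarray(v))
    if len(runs) < 3:
        return []
    anchors = [
        i
        for i, (s, e, _val) in enumerate(runs)
        if i == 0 or i == len(runs) - 1 or (e - s + 1) > window
    ]
    out: list[CandidateRun] = []
    for a, b in zip(anchors[:-1], anchors[1:]):
        gap = runs[a + 1 : b]
        if not gap:
            continue  # clean crossover boundary or adjacent anchors
        xval, yval = runs[a][2], runs[b][2]
        if xval == yval:
            for s, e, val in gap:
                if val != xval:
                    out.append(
                        CandidateRun(
                            np.arange(s, e + 1), np.empty(0, np.int64),
                            xval, xval, False,
                        )
                    )
            continue
        a_sites = np.concatenate(
            [np.arange(s, e + 1) for s, e, val in gap if val != xval]
        )
        b_sites = np.concatenate(
            [np.arange(s, e + 1) for s, e, val in gap if val != yval]
        )
        span_a = pos[a_sites[-1]] - pos[a_sites[0]] + 1 if a_sites.size else 0
        span_b = pos[b_sites[-1]] - pos[b_sites[0]] + 1 if b_sites.size else 0
        a_bad = a_sites.size >= LAPSE_MIN_SITES and span_a > span_limit
        b_bad = b_sites.size >= LAPSE_MIN_SITES and span_b > span_limit
        if b_bad and not a_bad:
            for s, e, val in gap:  # orientation A definitive
                if val != xval:
                    out.append(
                        CandidateRun(np.arange(s, e + 1), np.empty(0, np.int64),
                                     xval, xval, False)
                    )
        elif a_bad and not b_bad:
            for s, e, val in gap:
                if val != yval:
                    out.append(
                        CandidateRun(np.arange(s, e + 1), np.empty(0, np.int64),
                                     yval, yval, False)
                    )
        else:
            out.append(CandidateRun(a_sites, b_sites, xval, yval, True))
    return out


def find_double_switches(
    vector: np.ndarray,
    informative: np.ndarray,
    pos: np.ndarray,
    window: int = SCAN_WINDOW,
) -> list[CandidateRun]:
    """Candidates on one (parent, child, chromosome) transmission vector.

    ``vector`` is the per-marker haplotype-origin sequence, ``informative``
    the boolean informative-site mask, ``pos`` the marker bp positions.
    Returned site indices are marker indices (positions within ``vector``).
    """
    idx = np.flatnonzero(informative)
    cands = scan_vector(vector[idx], pos[idx], window)
    for c in cands:
        c.sites = idx[c.sites]
        c.sites_b = idx[c.sites_b]
    return cands


@dataclass
class NCOEvent:
    """A called gene-conversion event.

    ``sites`` hold global marker indices of converted sites (orientation A;
    ``sites_b`` is non-empty only for ambiguous, crossover-adjacent events,
    where each orientation carries weight 0.5 per site).  ``tract_lower`` is
    the inclusive bp span of the converted sites, ``tract_upper`` the span
    between the flanking background informative sites minus one.
    """

    family: str
    parent: str
    parent_sex: str
    child: str
    chrom: str
    sites: np.ndarray
    sites_b: np.ndarray
    alleles: np.ndarray  # transmitted allele index per orientation-A site
    alleles_b: np.ndarray
    ambiguous: bool
    weight: float
    ascertainment: str = "standard"
    klass: str = CLASS_NCO
    tract_lower: int = 0
    tract_upper: int = 0
    meta: dict = field(default_factory=dict)

    def all_sites(self) -> np.ndarray:
        return np.concatenate([self.sites, self.sites_b]).astype(np.int64)

    def site_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """(marker indices, per-site ascertainment weights) for rate counting."""
        s = self.all_sites()
        return s, np.full(s.size, self.weight)

    @property
    def meiosis_key(self) -> tuple[str, str, str]:
        return (self.family, self.parent, self.child)


def classify_event(
    sites: np.ndarray,
    flank_prev: int,
    flank_next: int,
    pos: np.ndarray,
    span_limit: int = NCO_SPAN_BP,
) -> tuple[str, int, int]:
    """Tract bounds and class from converted sites and flanking informative sites.

    ``flank_prev``/``flank_next`` are marker indices of the nearest
    background informative sites on each side; both must exist (candidates
    at a chromosome edge are rejected upstream).
    """
    lower = int(pos[sites[-1]] - pos[sites[0]] + 1)
    upper = int(pos[flank_next] - pos[flank_prev] - 1)
    klass = CLASS_NCO if lower < span_limit else CLASS_LONG
    return klass, lower, upper


# ---------------------------------------------------------------------------
# Event assembly from ascertained rows
# ---------------------------------------------------------------------------


def assemble_events(
    row,  # ascertain.MeiosisRows
    markers,
    chrom_slices: dict[str, slice],
    window: int = SCAN_WINDOW,
    span_limit: int = NCO_SPAN_BP,
) -> list[NCOEvent]:
    """Final event calls for one (parent, child) from its informative sites."""
    pos = markers["pos"].to_numpy()
    out = []
    for chrom, sl in chrom_slices.items():
        inf = row.informative[sl]
        idx = np.flatnonzero(inf)
        if idx.size < 3:
            continue
        cands = find_double_switches(row.vector[sl], inf, pos[sl], window)
        for cand in cands:
            i0 = int(np.searchsorted(idx, cand.sites[0]))
            i1 = int(np.searchsorted(idx, cand.sites[-1]))
            if i0 == 0 or i1 == idx.size - 1:
                continue  # cannot bound the tract at a chromosome edge
            klass, lower, upper = classify_event(
                cand.sites, idx[i0 - 1], idx[i1 + 1], pos[sl], span_limit
            )
            off = sl.start
            ev = NCOEvent(
                family=row.family, parent=row.parent, parent_sex=row.parent_sex,
                child=row.child, chrom=chrom,
                sites=cand.sites + off, sites_b=cand.sites_b + off,
                alleles=row.received[cand.sites + off].copy(),
                alleles_b=row.received[cand.sites_b + off].copy(),
                ambiguous=cand.ambiguous,
                weight=0.5 if cand.ambiguous else 1.0,
                klass=klass, tract_lower=lower, tract_upper=upper,
            )
            out.append(ev)
    return out


# ---------------------------------------------------------------------------
# Non-standard ascertainment
# ---------------------------------------------------------------------------


def detect_nonstandard(
    ped, gm, phases: dict[str, PedigreePhase], mask: np.ndarray
) -> list[NCOEvent]:
    """Putative NCOs at ambiguously phased markers.

    At a marker where every family member except one homozygous child is
    heterozygous, the phase within the first-generation family is ambiguous
    and the site is excluded from the rate's numerator and denominator.  A
    conversion in the homozygous child can still be recognised when another
    analyzed child's own nuclear family (third generation) pins the parental
    phase and the homozygous child's received allele contradicts its
    background haplotype.  Such events are flagged ``nonstandard``; they are
    eligible for GC-transmission tallies but never for rate estimation.
    """
    from ncoscan.phase import fill_nearest

    out = []
    pos = gm.markers["pos"].to_numpy()
    sex = {ped.father: "M", ped.mother: "F"}
    for chrom, pp in phases.items():
        sl = gm.chrom_slice(chrom)
        off = sl.start
        fam1 = pp.gen1
        d_members = {m: gm.of(m)[sl] for m in
                     [ped.father, ped.mother] + ped.children}
        for p, parent_id in ((0, ped.father), (1, ped.mother)):
            dP = d_members[parent_id]
            for child in ped.analyzed:
                ci = ped.children.index(child)
                dC = d_members[child]
                others_het = np.ones(dC.shape[0], dtype=bool)
                for other in [ped.father, ped.mother] + ped.children:
                    if other != child:
                        others_het &= d_members[other] == 1
                cand = (
                    others_het
                    & ((dC == 0) | (dC == 2))
                    & mask[sl]
                )
                if not cand.any():
                    continue
                # background haplotypes must be anchored by markers other
                # than the contested (candidate) sites themselves
                reliable = (dP == 1) & ~fam1.amb[p, ci] & ~cand
                if not reliable.any():
                    continue
                bg_c = fill_nearest(fam1.trans[p, ci], reliable)
                received_v = (dC // 2).astype(np.int8)
                expected_v = np.full(dC.shape[0], -1, dtype=np.int8)
                for c2 in ped.analyzed:
                    if c2 == child:
                        continue
                    fam22 = pp.gen2[c2]
                    # regional orientation: at the ambiguous marker itself the
                    # cross-family inconsistency mask may fire precisely
                    # because of the conversion under scrutiny, so the
                    # orientation value (carried from flanking markers) is
                    # used without requiring the site to be unmasked
                    orient = pp.orient[c2]
                    hap_idx = (orient ^ p).astype(np.int64)
                    r_c2 = fam22.hap[0, hap_idx, np.arange(dC.shape[0])]
                    cj = ped.children.index(c2)
                    reliable2 = (dP == 1) & ~fam1.amb[p, cj] & ~cand
                    if not reliable2.any():
                        continue
                    bg_c2 = fill_nearest(fam1.trans[p, cj], reliable2)
                    ok = (
                        cand
                        & (expected_v < 0)
                        & (gm.of(c2)[sl] == 1)
                        & (r_c2 >= 0)
                    )
                    exp = np.where(bg_c == bg_c2, r_c2, 1 - r_c2)
                    expected_v[ok] = exp[ok].astype(np.int8)
                hits = cand & (expected_v >= 0) & (expected_v != received_v)
                for s in np.flatnonzero(hits):
                    received = int(received_v[s])
                    out.append(
                            NCOEvent(
                                family=ped.family, parent=parent_id,
                                parent_sex=sex[parent_id], child=child,
                                chrom=chrom,
                                sites=np.array([off + s]),
                                sites_b=np.empty(0, np.int64),
                                alleles=np.array([received], dtype=np.int8),
                                alleles_b=np.empty(0, np.int8),
                                ambiguous=False, weight=1.0,
                                ascertainment="nonstandard",
                                klass=CLASS_NCO, tract_lower=1,
                                tract_upper=-1,
                            )
                        )
    return out


# ---------------------------------------------------------------------------
# Event filters (pedigree-level false-positive removal)
# ---------------------------------------------------------------------------


def _overlapping(e1: NCOEvent, e2: NCOEvent) -> bool:
    if e1.chrom != e2.chrom:
        return False
    s1, s2 = e1.all_sites(), e2.all_sites()
    return bool(np.intersect1d(s1, s2).size)


def _gen3_transmission(
    event: NCOEvent, pp: PedigreePhase, orientation: str = "A"
) -> list[tuple[str, int, int]]:
    """Per grandchild: (id, #sites receiving converted allele, #determinable).

    Uses the gen2 nuclear family of the recipient: a grandchild receives the
    converted allele at a site when its allele-from-recipient equals the
    event's transmitted allele there.
    """
    child = event.child
    if child not in pp.gen2:
        return []
    fam2 = pp.gen2[child]
    gkids = pp.ped.analyzed[child][1]
    sl_off = pp.marker_offset
    sites = (event.sites if orientation == "A" else event.sites_b) - sl_off
    alleles = event.alleles if orientation == "A" else event.alleles_b
    out = []
    for gi, g in enumerate(gkids):
        bits = fam2.trans[0, gi, sites]
        amb = fam2.amb[0, gi, sites]
        hap = fam2.hap[0]
        recv = hap[bits, sites]
        ok = (~amb) & (recv >= 0)
        n_conv = int(np.sum(ok & (recv == alleles)))
        out.append((g, n_conv, int(ok.sum())))
    return out


def apply_event_filters(
    events: list[NCOEvent], phases: dict[tuple[str, str], PedigreePhase]
) -> tuple[list[NCOEvent], list[dict]]:
    """Remove likely false positives; returns (kept, audit log).

    Removed classes: events in the same interval in two or more children of
    a pedigree; events at the same site from both parents to one child;
    events whose grandchild transmission shows a partial (multi-SNP,
    therefore undetected) NCO or aberrant calls; long-range events lacking
    clean full-tract transmission to the third generation.
    """
    drop: dict[int, str] = {}
    for i, e1 in enumerate(events):
        for j in range(i + 1, len(events)):
            e2 = events[j]
            if e1.family != e2.family or not _overlapping(e1, e2):
                continue
            if e1.child != e2.child:
                drop[i] = drop[j] = "same_interval_multiple_children"
            elif e1.parent != e2.parent:
                drop[i] = drop[j] = "both_parents_same_child"
    for i, e in enumerate(events):
        if i in drop:
            continue
        pp = phases.get((e.family, e.chrom))
        if pp is None:
            continue
        orientations = ["A"] + (["B"] if e.ambiguous else [])
        full, partial = False, False
        for o in orientations:
            for _g, n_conv, n_det in _gen3_transmission(e, pp, o):
                n_sites = (e.sites if o == "A" else e.sites_b).size
                if n_det and 0 < n_conv < n_det and n_sites > 1:
                    partial = True
                if n_det == n_sites and n_conv == n_sites:
                    full = True
        if partial:
            drop[i] = "gen3_partial_tract"
        elif e.klass == CLASS_LONG and not full:
            drop[i] = "longrange_without_full_gen3_transmission"
    kept = [e for i, e in enumerate(events) if i not in drop]
    audit = [
        dict(
            family=events[i].family, parent=events[i].parent,
            child=events[i].child, chrom=events[i].chrom,
            sites=events[i].all_sites().tolist(), reason=r,
        )
        for i, r in sorted(drop.items())
    ]
    return kept, audit


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class EventCluster:
    events: list[NCOEvent]
    span_bp: int
    meiosis: tuple[str, str, str]

    @property
    def size(self) -> int:
        return len(self.events)


def cluster_events(
    events: list[NCOEvent], pos: np.ndarray, window_bp: int = CLUSTER_WINDOW_BP
) -> list[EventCluster]:
    """Transitively cluster same-meiosis events with gaps <= window_bp."""
    by_meiosis: dict[tuple, list[NCOEvent]] = {}
    for e in events:
        by_meiosis.setdefault(e.meiosis_key + (e.chrom,), []).append(e)
    clusters = []
    for key, evs in sorted(by_meiosis.items()):
        evs = sorted(evs, key=lambda e: pos[e.all_sites().min()])
        current = [evs[0]]
        for e in evs[1:]:
            prev_end = max(pos[x.all_sites()].max() for x in current)
            if pos[e.all_sites()].min() - prev_end <= window_bp:
                current.append(e)
            else:
                clusters.append(_make_cluster(current, pos, key))
                current = [e]
        clusters.append(_make_cluster(current, pos, key))
    return clusters


def _make_cluster(evs, pos, key):
    lo = min(int(pos[e.all_sites()].min()) for e in evs)
    hi = max(int(pos[e.all_sites()].max()) for e in evs)
    return EventCluster(evs, hi - lo + 1, key[:3])
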