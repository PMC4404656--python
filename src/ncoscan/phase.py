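"""Minimum-recombinant phasing of nuclear families, chained across generations.

The phasing problem: given unordered genotypes of two parents and their
children at markers along one chromosome, find ordered parental haplotypes
and per-child transmission vectors (which parental homolog each child
received at each marker) that are consistent with every genotype and
minimize the total number of transmission switches summed over children.

Formulation.  A joint state at a marker assigns one bit per (parent, child):
which *physical* haplotype of that parent the child received.  Transitions
between adjacent markers cost the Hamming distance between joint states
(each flipped bit is one recombination).  At each marker the unobserved
per-parent phase labeling (which allele sits on haplotype 0) is free: a
state is consistent when at least one of the four labelings reproduces all
child genotypes.  Exact minimization runs as a dynamic program over the
4^k joint states (k = number of children), with the min-plus Hamming
relaxation computed bit by bit, keeping per-marker work at O(4^k * k).
Forward and backward value tables give, per marker and per transmission
bit, whether both bit values occur among minimum-recombinant solutions
(the transmission is then ambiguous at that site).

Tie-breaking is deterministic: the traceback prefers continuing the
previous marker's state, then the lexicographically smallest state.  The
phase labeling of the first heterozygous marker of a chromosome is
arbitrary and fixed canonically by that rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ncoscan.pedio import MISSING, GenotypeMatrix, Pedigree, PedigreeSet

AMBIGUOUS = -2  # transmission-vector value

_INF = 1 << 28

MAX_DP_CHILDREN = 6  # joint-state DP is exponential in family size


class PhasingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# DP kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _relax(buf, nbits):
    """In-place min-plus Hamming relaxation over the state hypercube."""
    S = buf.shape[0]
    for b in range(nbits):
        bit = 1 << b
        for s in range(S):
            v = buf[s ^ bit] + 1
            if v < buf[s]:
                buf[s] = v


@njit(cache=True)
def _dp_tables(mask, k):
    """Forward/backward minimum-switch tables. mask: (M, S) uint8."""
    M, S = mask.shape
    nbits = 2 * k
    F = np.empty((M, S), np.int32)
    B = np.empty((M, S), np.int32)
    for s in range(S):
        F[0, s] = 0 if mask[0, s] else _INF
        B[M - 1, s] = 0 if mask[M - 1, s] else _INF
    buf = np.empty(S, np.int32)
    for j in range(1, M):
        for s in range(S):
            buf[s] = F[j - 1, s]
        _relax(buf, nbits)
        for s in range(S):
            F[j, s] = buf[s] if mask[j, s] else _INF
    for j in range(M - 2, -1, -1):
        for s in range(S):
            buf[s] = B[j + 1, s]
        _relax(buf, nbits)
        for s in range(S):
            B[j, s] = buf[s] if mask[j, s] else _INF
    return F, B


@njit(cache=True)
def _popcount(x):
    n = 0
    while x:
        x &= x - 1
        n += 1
    return n


@njit(cache=True)
def _traceback(F, B, mask, k):
    """Optimal state path; returns (path, total)."""
    M, S = F.shape
    total = _INF
    for s in range(S):
        if F[M - 1, s] < total:
            total = F[M - 1, s]
    path = np.zeros(M, np.int64)
    if total >= _INF:
        return path, -1
    for s in range(S):
        if F[0, s] + B[0, s] == total:
            path[0] = s
            break
    for j in range(1, M):
        prev = path[j - 1]
        fprev = F[j - 1, prev]
        chosen = -1
        if mask[j, prev] and fprev + B[j, prev] == total:
            chosen = prev  # prefer continuing the previous state
        if chosen < 0:
            for s in range(S):
                if mask[j, s] and fprev + _popcount(prev ^ s) + B[j, s] == total:
                    chosen = s
                    break
        path[j] = chosen
    return path, total


@njit(cache=True)
def _allele_marginals(F, B, mask_lab, k, total):
    """Per (marker, parent, child): minimum solution cost for each received
    allele of a heterozygous parent.

    Under labeling lam (which allele sits on haplotype 0 of each parent), a
    child whose transmission bit is t received allele (lam_p XOR t) from a
    het parent.  Received-allele ambiguity and forced alleles are read off
    these marginals; both are gauge-invariant (unchanged under a global swap
    of a parent's haplotype labels).

    Returns m: (M, 2k, 2) int32 minimum F+B over consistent (labeling,
    state) pairs with the given received allele.
    """
    M, S = F.shape
    nbits = 2 * k
    m = np.full((M, nbits, 2), _INF, np.int32)
    for j in range(M):
        for li in range(4):
            l0 = li & 1
            l1 = (li >> 1) & 1
            for s in range(S):
                if not mask_lab[li, j, s]:
                    continue
                v = F[j, s] + B[j, s]
                if v > total:
                    continue
                for b in range(nbits):
                    lam = l0 if b < k else l1
                    a = lam ^ ((s >> b) & 1)
                    if v < m[j, b, a]:
                        m[j, b, a] = v
    return m


# ---------------------------------------------------------------------------
# Mask construction
# ---------------------------------------------------------------------------


def _haplotype_values(dosage: np.ndarray) -> np.ndarray:
    """Allele on each haplotype under labeling 0 (2, M); NaN = unconstrained."""
    M = dosage.shape[0]
    hv = np.full((2, M), np.nan)
    hv[0, dosage == 0] = 0.0
    hv[1, dosage == 0] = 0.0
    hv[0, dosage == 2] = 1.0
    hv[1, dosage == 2] = 1.0
    hv[0, dosage == 1] = 0.0  # labeling 0: haplotype 0 carries allele 0
    hv[1, dosage == 1] = 1.0
    return hv


def _base_mask(d0, d1, dch) -> np.ndarray:
    """(M, S) bool: state consistency under phase labeling (0, 0)."""
    k, M = dch.shape
    S = 1 << (2 * k)
    hv0 = _haplotype_values(d0)
    hv1 = _haplotype_values(d1)
    child_ok = np.empty((k, 4, M), dtype=bool)
    for c in range(4):
        a = hv0[c & 1]
        b = hv1[(c >> 1) & 1]
        known = np.nan_to_num(a) + np.nan_to_num(b)
        n_unk = np.isnan(a).astype(np.int8) + np.isnan(b).astype(np.int8)
        for i in range(k):
            ch = dch[i].astype(float)
            ok = (ch >= known) & (ch <= known + n_unk)
            ok[dch[i] == MISSING] = True
            child_ok[i, c] = ok
    states = np.arange(S)
    mask = np.ones((M, S), dtype=bool)
    for i in range(k):
        combo = ((states >> i) & 1) + 2 * ((states >> (k + i)) & 1)
        mask &= child_ok[i, combo, :].T
    return mask


def _labeling_flips(k: int) -> np.ndarray:
    p0 = (1 << k) - 1
    return np.array([0, p0, p0 << k, p0 | (p0 << k)], dtype=np.int64)


def _consistency_mask(d0, d1, dch):
    """Mask over physical states (OR over the 4 labelings) + per-labeling masks.

    Returns (mask_phys (M,S) uint8, mask_lab (4,M,S) bool, mendel (M,) bool).
    """
    k = dch.shape[0]
    base = _base_mask(d0, d1, dch)
    S = base.shape[1]
    states = np.arange(S)
    flips = _labeling_flips(k)
    mask_lab = np.empty((4, base.shape[0], S), dtype=bool)
    for li, f in enumerate(flips):
        mask_lab[li] = base[:, states ^ f]
    mask_phys = mask_lab.any(axis=0)
    mendel = ~mask_phys.any(axis=1)
    mask_phys[mendel, :] = True  # masked marker: unconstrained; caller logs
    return mask_phys.astype(np.uint8), mask_lab, mendel


# ---------------------------------------------------------------------------
# Public phasing API
# ---------------------------------------------------------------------------


@dataclass
class FamilyPhase:
    """Phase of one nuclear family on one chromosome.

    ``hap[p, h, j]`` is the allele index on parent p's physical haplotype h
    (−1 when the labeling is unresolved at that marker); ``trans[p, i, j]``
    the haplotype of parent p received by child i; ``amb[p, i, j]`` marks
    transmissions ambiguous among minimum-recombinant solutions;
    ``received[p, i, j]`` the allele child i received from parent p (−1
    unknown; resolved from the genotype alone for homozygous children);
    ``mendel`` marks markers masked for Mendelian inconsistency.
    """

    parent0: str
    parent1: str
    children: list[str]
    hap: np.ndarray
    trans: np.ndarray
    amb: np.ndarray
    received: np.ndarray
    mendel: np.ndarray
    n_switches: int

    def child_index(self, child: str) -> int:
        return self.children.index(child)


def phase_nuclear_family_arrays(
    d0: np.ndarray, d1: np.ndarray, dch: np.ndarray,
    parent0: str = "P0", parent1: str = "P1", children: list[str] | None = None,
) -> FamilyPhase:
    """Phase a nuclear family from dosage arrays (one chromosome).

    d0, d1: (M,) parent dosages; dch: (k, M) child dosages.
    """
    k, M = dch.shape
    if k == 0 or M == 0:
        raise PhasingError("need at least one child and one marker")
    if k > MAX_DP_CHILDREN:
        raise PhasingError(
            f"{k} children exceeds exact-DP family-size limit {MAX_DP_CHILDREN}"
        )
    children = children if children is not None else [f"C{i}" for i in range(k)]
    mask, mask_lab, mendel = _consistency_mask(d0, d1, dch)
    F, B = _dp_tables(mask, k)
    path, total = _traceback(F, B, mask, k)
    marg = _allele_marginals(F, B, mask_lab.astype(np.uint8), k, np.int32(total))

    # labeling recovery for the chosen path: which labelings support it
    flips = _labeling_flips(k)
    rows = np.arange(M)
    lab_ok = np.stack(
        [mask_lab[li][rows, path] for li in range(4)]
    )  # (4, M)
    lab_ok[:, mendel] = False
    lam = np.array([[0, 1, 0, 1], [0, 0, 1, 1]], dtype=np.int8)  # (parent, labeling)

    hap = np.full((2, 2, M), -1, dtype=np.int8)
    trans = np.empty((2, k, M), dtype=np.int8)
    amb = np.empty((2, k, M), dtype=bool)
    received = np.full((2, k, M), -1, dtype=np.int8)
    for p, d in enumerate((d0, d1)):
        lp = np.where(lab_ok, lam[p][:, None], -9)  # labeling value or sentinel
        vals = np.sort(lp, axis=0)
        resolved = vals[3] >= 0
        unique = resolved & ((vals == -9) | (vals == vals[3])).all(axis=0)
        lab_p = np.where(unique, vals[3], -1).astype(np.int8)
        hom = (d == 0) | (d == 2)
        hap[p, 0, hom] = hap[p, 1, hom] = (d[hom] // 2).astype(np.int8)
        het = (d == 1) & (lab_p >= 0)
        hap[p, 0, het] = lab_p[het]
        hap[p, 1, het] = 1 - lab_p[het]
    # transmission bits: parent0 bits 0..k-1, parent1 bits k..2k-1
    for p, d in enumerate((d0, d1)):
        het = d == 1
        hom = (d == 0) | (d == 2)
        for i in range(k):
            b = p * k + i
            trans[p, i] = ((path >> b) & 1).astype(np.int8)
            can0 = marg[:, b, 0] <= total
            can1 = marg[:, b, 1] <= total
            # received allele: het parent -> forced marginal; hom parent -> allele
            r = np.full(M, -1, dtype=np.int8)
            r[het & can0 & ~can1] = 0
            r[het & can1 & ~can0] = 1
            r[hom] = (d[hom] // 2).astype(np.int8)
            a = np.zeros(M, dtype=bool)
            a[het] = (can0 & can1)[het]
            a[d == MISSING] = True
            a[mendel] = True
            r[mendel] = -1
            received[p, i] = r
            amb[p, i] = a
    return FamilyPhase(
        parent0, parent1, children, hap, trans, amb, received, mendel, int(total)
    )


def phase_nuclear_family(
    gm: GenotypeMatrix, parent0: str, parent1: str, children: list[str],
    chrom: str,
) -> FamilyPhase:
    """Phase one nuclear family on one chromosome of a genotype matrix."""
    sl = gm.chrom_slice(chrom)
    d0 = gm.of(parent0)[sl]
    d1 = gm.of(parent1)[sl]
    dch = np.vstack([gm.of(c)[sl] for c in children])
    return phase_nuclear_family_arrays(d0, d1, dch, parent0, parent1, children)


@dataclass
class PedigreePhase:
    """Three-generation phase of one pedigree on one chromosome.

    ``gen1`` is the first-generation nuclear family (parent0 = father).
    ``gen2[c]`` is the nuclear family of analyzed child c (parent0 = c,
    parent1 = partner).  ``orient[c][j]`` maps c's gen2-frame haplotype h to
    the gen1 frame (paternal haplotype = h XOR orient); ``orient_mask[c]``
    marks isolated markers with cross-family phase inconsistency (excluded
    from analysis).  ``marker_offset`` is the global index of this
    chromosome's first marker.
    """

    ped: Pedigree
    chrom: str
    gen1: FamilyPhase
    gen2: dict[str, FamilyPhase] = field(default_factory=dict)
    orient: dict[str, np.ndarray] = field(default_factory=dict)
    orient_mask: dict[str, np.ndarray] = field(default_factory=dict)
    n_inversions: dict[str, int] = field(default_factory=dict)
    marker_offset: int = 0


def _chain_orientation(
    o_def: np.ndarray, defined: np.ndarray, run_threshold: int = 10
) -> tuple[np.ndarray, np.ndarray, int]:
    """Resolve gen2->gen1 orientation with masking and inversion rules.

    o_def: per-marker observed orientation (0/1) at ``defined`` markers.
    Isolated inconsistent runs (< run_threshold successive defined markers)
    are masked; runs of >= run_threshold trigger a phase inversion from the
    start of the run (an undetected crossover between the two generations).
    Greedy left-to-right.  Returns (orientation per marker, mask, inversions).
    """
    M = o_def.shape[0]
    orient = np.zeros(M, dtype=np.int8)
    mask = np.zeros(M, dtype=bool)
    idx = np.flatnonzero(defined)
    n_inv = 0
    if idx.size == 0:
        return orient, mask, 0
    ref = int(o_def[idx[0]])  # anchored at the first resolvable het marker
    orient[: idx[0] + 1] = ref
    i = 0
    n = idx.size
    while i < n:
        j = idx[i]
        if int(o_def[j]) == ref:
            orient[j:] = ref
            i += 1
            continue
        run_end = i
        while run_end < n and int(o_def[idx[run_end]]) != ref:
            run_end += 1
        if run_end - i >= run_threshold:
            ref ^= 1
            n_inv += 1
            orient[j:] = ref
        else:
            mask[idx[i:run_end]] = True
            orient[j:] = ref
        i = run_end
    return orient, mask, n_inv


def phase_three_generation(
    peds: PedigreeSet, gm: GenotypeMatrix, ped: Pedigree, chrom: str,
    inversion_run: int = 10,
) -> PedigreePhase:
    """Phase one pedigree on one chromosome, chaining gen2 to gen1 phase."""
    if not ped.analyzable:
        raise PhasingError(f"pedigree {ped.family} is not analyzable")
    gen1 = phase_nuclear_family(gm, ped.father, ped.mother, ped.children, chrom)
    sl = gm.chrom_slice(chrom)
    out = PedigreePhase(ped, chrom, gen1, marker_offset=sl.start)
    for child, (partner, gkids) in ped.analyzed.items():
        fam2 = phase_nuclear_family(gm, child, partner, gkids, chrom)
        ci = ped.children.index(child)
        r_pat = gen1.received[0, ci]  # allele received from the gen1 father
        d_child = gm.of(child)[sl]
        h0 = fam2.hap[0, 0]
        defined = (d_child == 1) & (r_pat >= 0) & (h0 >= 0) & ~fam2.mendel
        o_def = np.zeros(d_child.shape[0], dtype=np.int8)
        o_def[defined] = (h0[defined] != r_pat[defined]).astype(np.int8)
        orient, omask, n_inv = _chain_orientation(o_def, defined, inversion_run)
        out.gen2[child] = fam2
        out.orient[child] = orient
        out.orient_mask[child] = omask
        out.n_inversions[child] = n_inv
    return out


def transmission_vector(
    pp: PedigreePhase, parent: str, child: str
) -> np.ndarray:
    """Per-marker haplotype-origin sequence for one (parent, child) pair.

    Values: 0 (parent's haplotype 0), 1 (haplotype 1), AMBIGUOUS (-2).
    Defined for gen1 parent -> gen2 child and analyzed gen2 parent ->
    grandchild pairs of this pedigree.
    """
    if parent in (pp.ped.father, pp.ped.mother) and child in pp.ped.children:
        fam, p, ci = pp.gen1, int(parent == pp.ped.mother), pp.ped.children.index(child)
    elif parent in pp.gen2 and child in pp.ped.analyzed[parent][1]:
        fam, p, ci = pp.gen2[parent], 0, pp.ped.analyzed[parent][1].index(child)
    elif any(parent == pt for pt, _ in pp.ped.analyzed.values()):
        owner = next(c for c, (pt, _) in pp.ped.analyzed.items() if pt == parent)
        fam, p, ci = pp.gen2[owner], 1, pp.ped.analyzed[owner][1].index(child)
    else:
        raise PhasingError(f"unknown (parent, child) pair ({parent}, {child})")
    v = fam.trans[p, ci].astype(np.int8).copy()
    v[fam.amb[p, ci]] = AMBIGUOUS
    return v


def fill_nearest(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid entries with the nearest previous valid value (then next)."""
    out = values.copy()
    idx = np.where(valid, np.arange(values.size), -1)
    np.maximum.accumulate(idx, out=idx)
    has_prev = idx >= 0
    out[has_prev] = values[idx[has_prev]]
    if not has_prev.all() and valid.any():
        first = values[np.flatnonzero(valid)[0]]
        out[~has_prev] = first
    return out
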