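"""Synthetic three-generation pedigrees with crossovers, NCO conversion
tracts, GC-biased transmission, genotyping error and missingness.

Model
-----
Founder haplotypes are drawn independently per marker from a per-marker
allele frequency (no linkage disequilibrium).  Each meiosis places
crossovers as a Poisson process on the genetic map (no interference) and
NCO conversion tracts as a Poisson process in bp with geometric tract
lengths (mean ``mean_tract_bp``, minimum 1 bp).  Within a tract the gamete
copies the homolog opposite the local background, so every heterozygous
marker inside a tract converts observably; the per-bp probability that a
position lies inside a tract is ``nco_rate`` (the tract *initiation*
intensity is ``nco_rate / mean_tract_bp``).

GC-biased gene conversion is modelled as a biased choice of which homolog
hosts the conversion: proposed tracts are thinned with weight 2b when the
donor homolog carries the G/C allele at a covered heterozygous AT/GC marker
and 2(1-b) when it carries the A/T allele (first ``_BIAS_CAP`` such markers;
proposal intensity is pre-inflated so the post-thinning coverage is exactly
``nco_rate``).  The marginal probability that a converted AT/GC site
transmits G or C is then exactly ``gc_bias``, while all converted sites
remain observable.  This initiation-bias formulation is statistically
equivalent, for every quantity the pipeline measures, to biased repair of
heteroduplex DNA.

Tracts never span a crossover breakpoint of the same meiosis; complex
clustered events can be emulated by ``complex_split_prob``, which splits a
tract into two sub-tracts with restored background in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ncoscan.pedio import (
    GenotypeMatrix,
    IntervalTrack,
    PedigreeSet,
    RecombinationMap,
    ROLE_GEN1,
    ROLE_GEN2,
    ROLE_GEN3,
    ROLE_PARTNER,
    MISSING,
    build_pedigree_set,
    flat_map,
    make_marker_table,
)

_BIAS_CAP = 4  # het AT/GC markers per tract entering the acceptance weight


@dataclass
class SimParams:
    """Generator settings; defaults emulate the SNP-array pedigree study design.

    ``nco_rate`` is the per-bp per-meiosis probability that a position lies
    in a conversion tract; ``mean_tract_bp`` the geometric mean tract length;
    ``gc_bias`` the probability that a converted heterozygous AT/GC site
    transmits the G/C allele.  Marker spacing ~3 kb emulates a ~1M-site
    genome-wide SNP array; 99% of markers are AT/GC-class.
    """

    n_pedigrees: int = 34
    children_per_family: int = 4
    analyzed_children: int = 2
    grandchildren_per_analyzed_child: int = 3
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr01": 30_000_000, "chr02": 20_000_000}
    )
    marker_spacing_bp: float = 3000.0
    maf_range: tuple[float, float] = (0.1, 0.9)
    frac_at_gc: float = 0.99
    cpg_fraction: float = 0.4
    rate_cm_per_mb: float = 1.0
    genetic_map: RecombinationMap | None = None
    nco_rate: float = 5.9e-6
    mean_tract_bp: float = 75.0
    gc_bias: float = 0.68
    hotspot_track: IntervalTrack | None = None
    hotspot_concentration: float = 0.0
    complex_split_prob: float = 0.0
    error_rate: float = 0.0
    missing_rate: float = 0.0

    def validate(self) -> None:
        for name in ("frac_at_gc", "cpg_fraction", "gc_bias",
                     "hotspot_concentration", "complex_split_prob",
                     "error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.nco_rate < 0 or self.mean_tract_bp < 1:
            raise ValueError("nco_rate must be >=0 and mean_tract_bp >= 1")
        if self.children_per_family < 1 or self.n_pedigrees < 1:
            raise ValueError("need >=1 pedigree and >=1 child per family")
        if self.analyzed_children > self.children_per_family:
            raise ValueError("analyzed_children exceeds children_per_family")

    def resolved_map(self) -> RecombinationMap:
        if self.genetic_map is not None:
            return self.genetic_map
        return flat_map(self.chrom_lengths, self.rate_cm_per_mb)


@dataclass
class TruthSet:
    """Ground truth: crossovers, conversion tracts, injected errors/missing.

    ``tracts`` rows: family, parent, child, chrom, start, end (1-based
    inclusive bp), converted (list of global marker indices), transmitted
    (allele index per converted marker), event (proposal id; sub-tracts of a
    split proposal share it).  ``cos`` rows: breakpoint bp (crossover lies
    between pos and pos+1).  ``errors``/``missing`` rows: marker, sample,
    original, observed.
    """

    tracts: pd.DataFrame
    cos: pd.DataFrame
    errors: pd.DataFrame
    missing: pd.DataFrame

    @staticmethod
    def _empty(cols):
        return pd.DataFrame({c: [] for c in cols})


_TRACT_COLS = ["family", "parent", "child", "chrom", "start", "end",
               "converted", "transmitted", "event"]
_CO_COLS = ["family", "parent", "child", "chrom", "pos"]
_ERR_COLS = ["marker", "sample", "original", "observed"]


def simulate_markers(params: SimParams, rng: np.random.Generator):
    """Marker table plus per-marker founder allele frequencies."""
    chroms, pos, a0, a1, cpg, freq = [], [], [], [], [], []
    for c, ln in params.chrom_lengths.items():
        n = max(2, int(round(ln / params.marker_spacing_bp)))
        p = np.unique(rng.integers(1, ln + 1, size=n + max(50, n // 10)))
        while p.size < n:  # collision shortfall; astronomically rare
            p = np.unique(np.concatenate([p, rng.integers(1, ln + 1, size=n)]))
        p = np.sort(rng.permutation(p)[:n])
        for x in p:
            chroms.append(c)
            pos.append(int(x))
            if rng.random() < params.frac_at_gc:
                pair = [rng.choice(("A", "T")), rng.choice(("G", "C"))]
                rng.shuffle(pair)
                cpg.append(rng.random() < params.cpg_fraction)
            else:
                pair = ["A", "T"] if rng.random() < 0.5 else ["C", "G"]
                cpg.append(False)
            a0.append(pair[0])
            a1.append(pair[1])
            freq.append(rng.uniform(*params.maf_range))
    ids = [f"rs_{c}_{p}" for c, p in zip(chroms, pos)]
    markers = make_marker_table(chroms, pos, ids, a0, a1, cpg)
    # make_marker_table sorts by (chrom, pos); mirror that order for freq
    order = np.lexsort((pos, chroms))
    markers["freq"] = np.asarray(freq)[order]
    return markers


def simulate_founders(
    markers: pd.DataFrame, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, 2, M) founder haplotypes; allele 1 drawn at the marker's frequency."""
    f = markers["freq"].to_numpy()
    return (rng.random((n, 2, f.size)) < f).astype(np.int8)


def simulate_meiosis(
    haps: np.ndarray,
    markers: pd.DataFrame,
    params: SimParams,
    rng: np.random.Generator,
    rmap: RecombinationMap | None = None,
):
    """One gamete from a parent's haplotype pair.

    Returns (gamete alleles (M,), co breakpoints per chrom, tract records).
    Tract records: (chrom, start, end, converted global marker idx list,
    transmitted alleles, event id).
    """
    rmap = rmap if rmap is not None else params.resolved_map()
    M = haps.shape[1]
    gamete = np.empty(M, dtype=np.int8)
    cos_out, tracts_out = [], []
    b = params.gc_bias
    fmax = 2.0 * max(b, 1.0 - b)
    inflate = fmax**_BIAS_CAP
    chrom_arr = markers["chrom"].to_numpy()
    pos_all = markers["pos"].to_numpy()
    gc_is_a1 = markers["gc_is_a1"].to_numpy()
    at_gc = (markers["snp_class"] == "AT_GC").to_numpy()
    ev = 0
    for chrom, length in params.chrom_lengths.items():
        idx = np.flatnonzero(chrom_arr == chrom)
        if idx.size == 0:
            continue
        lo = idx[0]
        pos = pos_all[idx]
        if rmap.chrom_pos[chrom][-1] < length:
            raise ValueError(f"genetic map shorter than chromosome {chrom}")
        h = haps[:, idx]
        total_cm = rmap.total_cm(chrom)
        n_co = rng.poisson(total_cm / 100.0)
        cm0 = rmap.chrom_cm[chrom][0]
        co_pos = np.sort(
            rmap.pos_at_cm(chrom, cm0 + rng.random(n_co) * total_cm)
        ).astype(np.int64)
        start_hap = int(rng.integers(2))
        seg = np.searchsorted(co_pos, pos)
        bg = (start_hap + seg) % 2
        g = h[bg, np.arange(idx.size)].copy()
        for p in co_pos:
            cos_out.append((chrom, int(p)))
        # --- conversion tracts ---
        lam = length * params.nco_rate / params.mean_tract_bp * inflate
        n_prop = rng.poisson(lam)
        for _ in range(n_prop):
            ev += 1
            tract = _propose_tract(length, co_pos, params, rng, chrom)
            if tract is None:
                continue
            pieces = _maybe_split(tract, params, rng)
            # acceptance weight over covered het AT/GC markers (all pieces)
            w = 1.0
            n_seen = 0
            for s, e in pieces:
                mi = np.searchsorted(pos, (s, e + 1))
                cover = np.arange(mi[0], mi[1])
                for m in cover:
                    if h[0, m] == h[1, m] or not at_gc[idx[m]]:
                        continue
                    if n_seen >= _BIAS_CAP:
                        break
                    donor = 1 - bg[m]
                    donor_gc = (h[donor, m] == 1) == gc_is_a1[idx[m]]
                    w *= 2.0 * b if donor_gc else 2.0 * (1.0 - b)
                    n_seen += 1
            if rng.random() >= w / inflate:
                continue
            for s, e in pieces:
                mi = np.searchsorted(pos, (s, e + 1))
                cover = np.arange(mi[0], mi[1])
                conv, trans = [], []
                for m in cover:
                    donor = 1 - bg[m]
                    g[m] = h[donor, m]
                    if h[0, m] != h[1, m]:
                        conv.append(int(lo + m))
                        trans.append(int(h[donor, m]))
                tracts_out.append((chrom, int(s), int(e), conv, trans, ev))
        gamete[idx] = g
    return gamete, cos_out, tracts_out


def _propose_tract(length, co_pos, params, rng, chrom):
    """Propose (start, end) not spanning a same-meiosis crossover."""
    for _ in range(10):
        tl = int(rng.geometric(1.0 / params.mean_tract_bp))
        if (
            params.hotspot_track is not None
            and params.hotspot_concentration > 0
            and rng.random() < params.hotspot_concentration
            and chrom in params.hotspot_track.intervals
            and len(params.hotspot_track.intervals[chrom])
        ):
            iv = params.hotspot_track.intervals[chrom]
            row = iv[rng.integers(len(iv))]
            s = int(rng.integers(row[0], row[1] + 1))
        else:
            s = int(rng.integers(1, length + 1))
        e = min(s + tl - 1, length)
        k = np.searchsorted(co_pos, s)
        if k < len(co_pos) and co_pos[k] < e:
            continue  # would span a crossover; redraw
        return s, e
    return None


def _maybe_split(tract, params, rng):
    s, e = tract
    if params.complex_split_prob <= 0 or rng.random() >= params.complex_split_prob:
        return [(s, e)]
    if e - s < 2:
        return [(s, e)]
    cut = int(rng.integers(s + 1, e))
    gap = int(rng.geometric(1.0 / params.mean_tract_bp))
    s2 = cut + gap + 1
    if s2 > e:
        return [(s, cut)]
    return [(s, cut), (s2, e)]


def inject_genotype_errors(
    gm: GenotypeMatrix, error_rate: float, rng: np.random.Generator
):
    """Perturb genotypes independently with probability ``error_rate``.

    Error mixture: het -> either homozygote (1/2 each); homozygote -> het
    (1/2) or opposite homozygote (1/2).  Returns (new matrix, error table).
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate outside [0, 1]")
    dosage = gm.dosage.copy()
    rows = []
    if error_rate > 0:
        hit = (rng.random(dosage.shape) < error_rate) & (dosage != MISSING)
        mj, sj = np.nonzero(hit)
        for m, s in zip(mj, sj):
            orig = int(dosage[m, s])
            if orig == 1:
                new = int(rng.choice((0, 2)))
            else:
                new = 1 if rng.random() < 0.5 else 2 - orig
            dosage[m, s] = new
            rows.append((int(m), gm.sample_ids[s], orig, new))
    out = GenotypeMatrix(gm.markers, dosage, list(gm.sample_ids))
    return out, pd.DataFrame(rows, columns=_ERR_COLS)


def _apply_missing(gm: GenotypeMatrix, rate: float, rng):
    dosage = gm.dosage.copy()
    rows = []
    if rate > 0:
        hit = rng.random(dosage.shape) < rate
        mj, sj = np.nonzero(hit)
        for m, s in zip(mj, sj):
            rows.append((int(m), gm.sample_ids[s], int(dosage[m, s]), MISSING))
        dosage[hit] = MISSING
    return GenotypeMatrix(gm.markers, dosage, list(gm.sample_ids)), pd.DataFrame(
        rows, columns=_ERR_COLS
    )


def simulate_pedigrees(
    params: SimParams, rng: np.random.Generator | int
):
    """Full synthetic dataset: pedigrees, genotypes and ground truth.

    Returns (PedigreeSet, GenotypeMatrix, TruthSet).  Third-generation
    gametes are produced by the same meiosis machinery as second-generation
    ones, so grandchild transmission checks behave as in real data.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    params.validate()
    markers = simulate_markers(params, rng)
    rmap = params.resolved_map()
    rows, hap_store = [], {}
    tracts, cos = [], []

    def meiose(parent_id, child_id, fam):
        gam, co, tr = simulate_meiosis(hap_store[parent_id], markers, params, rng, rmap)
        for chrom, p in co:
            cos.append((fam, parent_id, child_id, chrom, p))
        for chrom, s, e, conv, trans, ev in tr:
            tracts.append((fam, parent_id, child_id, chrom, s, e, conv, trans,
                           f"{parent_id}>{child_id}#{ev}"))
        return gam

    n_analyzed = params.analyzed_children
    for f in range(params.n_pedigrees):
        fam = f"F{f + 1:03d}"
        father, mother = f"{fam}_P1", f"{fam}_P2"
        for iid, sex in ((father, "M"), (mother, "F")):
            hap_store[iid] = simulate_founders(markers, 1, rng)[0]
            rows.append(dict(family=fam, id=iid, father="0", mother="0",
                             sex=sex, role=ROLE_GEN1))
        for c in range(params.children_per_family):
            cid = f"{fam}_C{c + 1}"
            sex = "M" if c % 2 == 0 else "F"
            hap_store[cid] = np.stack(
                [meiose(father, cid, fam), meiose(mother, cid, fam)]
            )
            rows.append(dict(family=fam, id=cid, father=father, mother=mother,
                             sex=sex, role=ROLE_GEN2))
            if c < n_analyzed and params.grandchildren_per_analyzed_child > 0:
                pid = f"{cid}P"
                psex = "F" if sex == "M" else "M"
                hap_store[pid] = simulate_founders(markers, 1, rng)[0]
                rows.append(dict(family=fam, id=pid, father="0", mother="0",
                                 sex=psex, role=ROLE_PARTNER))
                gfa, gmo = (cid, pid) if sex == "M" else (pid, cid)
                for g in range(params.grandchildren_per_analyzed_child):
                    gid = f"{cid}G{g + 1}"
                    hap_store[gid] = np.stack(
                        [meiose(gfa, gid, fam), meiose(gmo, gid, fam)]
                    )
                    rows.append(dict(family=fam, id=gid, father=gfa, mother=gmo,
                                     sex="M" if g % 2 == 0 else "F",
                                     role=ROLE_GEN3))
    individuals = pd.DataFrame(rows)
    peds = build_pedigree_set(individuals)
    sample_ids = list(individuals["id"])
    dosage = np.stack(
        [hap_store[s].sum(axis=0, dtype=np.int8) for s in sample_ids], axis=1
    )
    gm = GenotypeMatrix(markers, dosage, sample_ids)
    gm, err_df = inject_genotype_errors(gm, params.error_rate, rng)
    gm, miss_df = _apply_missing(gm, params.missing_rate, rng)
    truth = TruthSet(
        tracts=pd.DataFrame(tracts, columns=_TRACT_COLS),
        cos=pd.DataFrame(cos, columns=_CO_COLS),
        errors=err_df,
        missing=miss_df,
    )
    return peds, gm, truth


def write_truth(truth: TruthSet, path) -> None:
    """Flat TSV dump: one row per tract, crossover, error and missing call."""
    with open(path, "w") as fh:
        fh.write("kind\tfamily\tparent\tchild\tchrom\tstart\tend\tdetail\n")
        for _, r in truth.tracts.iterrows():
            conv = ",".join(map(str, r.converted))
            fh.write(f"tract\t{r.family}\t{r.parent}\t{r.child}\t{r.chrom}\t"
                     f"{r.start}\t{r.end}\tconverted={conv}\n")
        for _, r in truth.cos.iterrows():
            fh.write(f"co\t{r.family}\t{r.parent}\t{r.child}\t{r.chrom}\t"
                     f"{r.pos}\t{r.pos}\t.\n")
        for df, kind in ((truth.errors, "error"), (truth.missing, "missing")):
            for _, r in df.iterrows():
                fh.write(f"{kind}\t.\t.\t{r['sample']}\t.\t{r.marker}\t"
                         f"{r.marker}\t{r.original}>{r.observed}\n")


def scaled_params(base: SimParams, **overrides) -> SimParams:
    """Convenience copy-with-overrides."""
    return replace(base, **overrides)
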