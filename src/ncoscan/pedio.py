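"""Data model and file I/O: pedigrees, genotypes, genetic maps, interval tracks.

Conventions
-----------
* Internal coordinates are 1-based inclusive base pairs (VCF-native).  BED
  input is converted once, on read.
* Genotypes are stored as dosages of the marker's second allele ``a1``
  (0, 1, 2), with -1 for missing.
* SNP classes: ``AT_GC`` (one allele in {A,T}, the other in {G,C}),
  ``AT_AT`` (A/T), ``CG_CG`` (C/G).  Strand-ambiguous A/T and C/G SNPs are
  retained for event detection but excluded from GC-transmission tallies.
* CpG status is an input annotation (VCF ``CPG`` INFO flag or simulator
  truth), not recomputed from a reference sequence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

SNP_AT_GC = "AT_GC"
SNP_AT_AT = "AT_AT"
SNP_CG_CG = "CG_CG"
SNP_OTHER = "other"

_AT = frozenset("AT")
_GC = frozenset("GC")
_BASES = frozenset("ACGT")

ROLE_GEN1 = "gen1"
ROLE_GEN2 = "gen2"
ROLE_PARTNER = "gen2_partner"
ROLE_GEN3 = "gen3"


class InputError(ValueError):
    """Structurally invalid input; message carries the offending location."""


def classify_snp(a0: str, a1: str) -> str:
    """Classify a biallelic SNP by the strand classes of its two alleles."""
    if a0 not in _BASES or a1 not in _BASES or a0 == a1:
        raise InputError(f"invalid allele pair {a0!r}/{a1!r}")
    pair = {a0, a1}
    if pair == _AT:
        return SNP_AT_AT
    if pair == _GC:
        return SNP_CG_CG
    if len(pair & _AT) == 1 and len(pair & _GC) == 1:
        return SNP_AT_GC
    return SNP_OTHER  # unreachable for ACGT pairs, kept for non-simple input


@dataclass(frozen=True)
class Marker:
    """A single biallelic SNP marker."""

    chrom: str
    pos: int
    id: str
    a0: str
    a1: str
    cpg: bool = False

    @property
    def snp_class(self) -> str:
        return classify_snp(self.a0, self.a1)


def make_marker_table(
    chrom, pos, ids, a0, a1, cpg=None
) -> pd.DataFrame:
    """Assemble and validate the marker table used across the package.

    Returns a DataFrame sorted by (chrom, pos) with columns
    ``chrom, pos, id, a0, a1, snp_class, cpg, gc_is_a1``.
    """
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chrom, dtype=str),
            "pos": pd.Series(pos, dtype=np.int64),
            "id": pd.Series(ids, dtype=str),
            "a0": pd.Series(a0, dtype=str),
            "a1": pd.Series(a1, dtype=str),
        }
    )
    df["snp_class"] = [classify_snp(x, y) for x, y in zip(df.a0, df.a1)]
    df["cpg"] = False if cpg is None else np.asarray(cpg, dtype=bool)
    df["gc_is_a1"] = [y in _GC for y in df.a1]
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    for c, sub in df.groupby("chrom", sort=False):
        dup = sub.pos.duplicated()
        if dup.any():
            p = int(sub.pos[dup].iloc[0])
            raise InputError(f"duplicate marker position {c}:{p}")
    return df


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------


@dataclass
class Pedigree:
    """One three-generation pedigree within a :class:`PedigreeSet`."""

    family: str
    father: str  # gen1
    mother: str  # gen1
    children: list[str] = field(default_factory=list)  # gen2, by pedigree order
    # analyzed gen2 child id -> (partner id, [grandchild ids])
    analyzed: dict[str, tuple[str, list[str]]] = field(default_factory=dict)
    analyzable: bool = True
    reasons: list[str] = field(default_factory=list)

    @property
    def members(self) -> list[str]:
        out = [self.father, self.mother, *self.children]
        for child, (partner, gkids) in self.analyzed.items():
            out.append(partner)
            out.extend(gkids)
        return out


@dataclass
class PedigreeSet:
    """All pedigrees plus per-individual metadata.

    ``individuals`` has one row per person: family, id, father, mother,
    sex ('M'/'F'), role.  ``prdm9_ab_only`` maps gen1 parent ids to a
    config-supplied boolean (True when the parent is inferred to carry only
    PRDM9 A/B alleles).
    """

    individuals: pd.DataFrame
    pedigrees: list[Pedigree]
    prdm9_ab_only: dict[str, bool] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.individuals["id"])

    def analyzable(self) -> list[Pedigree]:
        return [p for p in self.pedigrees if p.analyzable]

    def sex_of(self, iid: str) -> str:
        row = self.individuals.loc[self.individuals["id"] == iid]
        return str(row["sex"].iloc[0])


_SEX_CODE = {"1": "M", "2": "F", "M": "M", "F": "F"}


def build_pedigree_set(individuals: pd.DataFrame) -> PedigreeSet:
    """Derive pedigree structure and 'analyzed'/'analyzable' flags.

    A pedigree is analyzable when both gen1 parents are present, it has at
    least three gen2 children, at least one grandchild, and both parents of
    every included grandchild are genotyped members.  A gen2 child is
    'analyzed' only when its partner and at least one of their children are
    present.
    """
    ids = set(individuals["id"])
    for _, row in individuals.iterrows():
        for p in (row["father"], row["mother"]):
            if p != "0" and p not in ids:
                raise InputError(
                    f"individual {row['id']}: parent {p} not in pedigree file"
                )
    peds = []
    for fam, sub in individuals.groupby("family", sort=False):
        gen1 = sub[sub.role == ROLE_GEN1]
        reasons = []
        if len(gen1) != 2:
            reasons.append(f"expected 2 gen1 parents, found {len(gen1)}")
            peds.append(
                Pedigree(fam, "", "", analyzable=False, reasons=reasons)
            )
            continue
        sexes = dict(zip(gen1.sex, gen1.id))
        if set(sexes) != {"M", "F"}:
            raise InputError(f"family {fam}: gen1 parents must be one M, one F")
        father, mother = sexes["M"], sexes["F"]
        children = [
            r["id"]
            for _, r in sub.iterrows()
            if {r["father"], r["mother"]} == {father, mother}
        ]
        ped = Pedigree(fam, father, mother, children, reasons=reasons)
        sub_ids = set(sub["id"])
        n_grandkids = 0
        for child in children:
            gkids = [
                r["id"]
                for _, r in sub.iterrows()
                if child in (r["father"], r["mother"]) and r.role == ROLE_GEN3
            ]
            if not gkids:
                continue
            partners = set()
            ok = True
            for g in gkids:
                row = sub[sub["id"] == g].iloc[0]
                other = row["father"] if row["mother"] == child else row["mother"]
                if other == "0" or other not in sub_ids:
                    reasons.append(f"grandchild {g}: missing second parent")
                    ok = False
                    break
                partners.add(other)
            if not ok:
                ped.analyzable = False
                continue
            if len(partners) != 1:
                # multiple partners: keep the couple with the most children
                best = max(
                    partners,
                    key=lambda p: sum(
                        1
                        for g in gkids
                        if p
                        in sub[sub["id"] == g].iloc[0][["father", "mother"]].values
                    ),
                )
                gkids = [
                    g
                    for g in gkids
                    if best in sub[sub["id"] == g].iloc[0][["father", "mother"]].values
                ]
                partners = {best}
            partner = partners.pop()
            ped.analyzed[child] = (partner, gkids)
            n_grandkids += len(gkids)
        if len(children) < 3:
            ped.analyzable = False
            reasons.append(f"only {len(children)} gen2 children (need >=3)")
        if n_grandkids == 0:
            ped.analyzable = False
            reasons.append("no grandchild with both parents present")
        peds.append(ped)
    return PedigreeSet(individuals=individuals.reset_index(drop=True), pedigrees=peds)


def read_pedigree(path) -> PedigreeSet:
    """Read the PED-like pedigree file.

    One whitespace-delimited row per individual:
    ``family id father mother sex role`` with sex in {1,2,M,F} and role in
    {gen1, gen2, gen2_partner, gen3}.  '#' lines are comments.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise InputError(f"{path}:{lineno}: expected 6 columns")
            fam, iid, fa, mo, sex, role = parts
            if sex not in _SEX_CODE:
                raise InputError(f"{path}:{lineno}: bad sex code {sex!r}")
            if role not in (ROLE_GEN1, ROLE_GEN2, ROLE_PARTNER, ROLE_GEN3):
                raise InputError(f"{path}:{lineno}: unknown role {role!r}")
            rows.append(
                dict(family=fam, id=iid, father=fa, mother=mo,
                     sex=_SEX_CODE[sex], role=role)
            )
    return build_pedigree_set(pd.DataFrame(rows))


def write_pedigree(peds: PedigreeSet, path) -> None:
    sex_out = {"M": "1", "F": "2"}
    with open(path, "w") as fh:
        fh.write("# family id father mother sex role\n")
        for _, r in peds.individuals.iterrows():
            fh.write(
                f"{r['family']}\t{r['id']}\t{r['father']}\t{r['mother']}\t"
                f"{sex_out[r['sex']]}\t{r['role']}\n"
            )


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """markers x individuals dosage matrix (dosage of allele ``a1``; -1 missing)."""

    markers: pd.DataFrame
    dosage: np.ndarray  # int8, shape (n_markers, n_samples)
    sample_ids: list[str]

    def __post_init__(self):
        self._index = {s: i for i, s in enumerate(self.sample_ids)}
        self._slices: dict[str, slice] = {}

    def col(self, sample: str) -> int:
        return self._index[sample]

    def of(self, sample: str) -> np.ndarray:
        return self.dosage[:, self._index[sample]]

    def chrom_slice(self, chrom: str) -> slice:
        if chrom not in self._slices:
            idx = np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())
            self._slices[chrom] = (
                slice(0, 0) if idx.size == 0
                else slice(int(idx[0]), int(idx[-1]) + 1)
            )
        return self._slices[chrom]

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))


def read_genotypes(path, peds: PedigreeSet) -> GenotypeMatrix:
    """Load biallelic SNVs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNV records are skipped (count logged).  Missing
    pedigree samples and unsorted records are fatal.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    vcf_samples = set(vcf.samples)
    for s in peds.sample_ids:
        if s not in vcf_samples:
            raise InputError(f"sample {s} missing from VCF {path}")
    order = [vcf.samples.index(s) for s in peds.sample_ids]
    chroms, pos, ids, a0, a1, cpg, rows = [], [], [], [], [], [], []
    skipped = 0
    last = {}
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            skipped += 1
            continue
        if v.CHROM in last and v.POS < last[v.CHROM]:
            raise InputError(f"VCF not sorted at {v.CHROM}:{v.POS}")
        last[v.CHROM] = v.POS
        chroms.append(v.CHROM)
        pos.append(v.POS)
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        a0.append(v.REF)
        a1.append(v.ALT[0])
        cpg.append(bool(v.INFO.get("CPG", False)))
        gt = np.asarray(v.gt_types)[order].astype(np.int8)  # 0/1/2, 3=missing
        gt[gt == 3] = MISSING
        rows.append(gt)
    if skipped:
        logger.info("read_genotypes: skipped %d non-biallelic-SNV records", skipped)
    markers = make_marker_table(chroms, pos, ids, a0, a1, cpg)
    dosage = (
        np.vstack(rows)
        if rows
        else np.empty((0, len(peds.sample_ids)), dtype=np.int8)
    )
    # make_marker_table may reorder across chromosomes; realign dosage rows
    key = pd.DataFrame({"chrom": chroms, "pos": pos})
    key["row"] = np.arange(len(key))
    key = key.sort_values(["chrom", "pos"], kind="stable")
    dosage = dosage[key["row"].to_numpy()]
    gm = GenotypeMatrix(markers, dosage.astype(np.int8), peds.sample_ids)
    gm.n_skipped = skipped
    return gm


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the genotype matrix as an uncompressed VCF 4.2 text file."""
    m = gm.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CPG,Number=0,Type=Flag,Description="CpG context">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(m["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(len(m)):
            info = "CPG" if m["cpg"].iat[j] else "."
            gts = "\t".join(gt_str[int(d)] for d in gm.dosage[j])
            fh.write(
                f"{m['chrom'].iat[j]}\t{m['pos'].iat[j]}\t{m['id'].iat[j]}\t"
                f"{m['a0'].iat[j]}\t{m['a1'].iat[j]}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Genetic maps
# ---------------------------------------------------------------------------


@dataclass
class RecombinationMap:
    """Per-chromosome genetic map anchors: bp position, cM/Mb rate, cumulative cM."""

    chrom_pos: dict[str, np.ndarray]
    chrom_rate: dict[str, np.ndarray]  # cM/Mb local rate to next anchor
    chrom_cm: dict[str, np.ndarray]
    map_kind: str = "LD_based"

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_pos)

    def total_cm(self, chrom: str) -> float:
        cm = self.chrom_cm[chrom]
        return float(cm[-1] - cm[0]) if cm.size else 0.0

    def cm_at(self, chrom: str, pos) -> np.ndarray:
        """Cumulative cM at bp position(s), linearly interpolated.

        Positions outside the anchor span return NaN (dropped downstream).
        """
        pos = np.atleast_1d(np.asarray(pos, dtype=float))
        xp, fp = self.chrom_pos[chrom], self.chrom_cm[chrom]
        out = np.interp(pos, xp, fp)
        out[(pos < xp[0]) | (pos > xp[-1])] = np.nan
        return out

    def pos_at_cm(self, chrom: str, cm) -> np.ndarray:
        """Inverse interpolation: bp position at cumulative cM (for simulation)."""
        cm = np.atleast_1d(np.asarray(cm, dtype=float))
        xp, fp = self.chrom_cm[chrom], self.chrom_pos[chrom]
        # np.interp requires increasing xp; flat cM segments collapse leftwards
        return np.interp(cm, xp, fp)


def flat_map(chrom_lengths: dict[str, int], rate_cm_mb: float = 1.0) -> RecombinationMap:
    """Uniform-rate map over each chromosome (1..length bp)."""
    pos, rate, cm = {}, {}, {}
    for c, ln in chrom_lengths.items():
        pos[c] = np.array([1.0, float(ln)])
        rate[c] = np.array([rate_cm_mb, rate_cm_mb])
        cm[c] = np.array([0.0, rate_cm_mb * (ln - 1) / 1e6])
    return RecombinationMap(pos, rate, cm)


def read_genetic_map(path) -> RecombinationMap:
    """Read a HapMap-style map: columns ``chrom pos rate(cM/Mb) cM``.

    The cumulative cM column must be non-decreasing (fatal, with line number);
    it is cross-checked against the rate column at 1e-6 cM tolerance and wins
    on disagreement (warning logged).
    """
    chroms, pos, rate, cm = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if lineno == 1 and not _is_float(parts[1]):
                continue  # header
            if len(parts) < 4:
                raise InputError(f"{path}:{lineno}: expected 4 columns")
            chroms.append(parts[0])
            pos.append(float(parts[1]))
            rate.append(float(parts[2]))
            cm.append(float(parts[3]))
            if len(cm) >= 2 and chroms[-2] == chroms[-1] and cm[-1] < cm[-2] - 1e-12:
                raise InputError(f"{path}:{lineno}: decreasing cM column")
    cpos, crate, ccm = {}, {}, {}
    df = pd.DataFrame({"chrom": chroms, "pos": pos, "rate": rate, "cm": cm})
    for c, sub in df.groupby("chrom", sort=False):
        p = sub["pos"].to_numpy()
        if np.any(np.diff(p) <= 0):
            raise InputError(f"{path}: positions not increasing on {c}")
        cpos[c] = p
        crate[c] = sub["rate"].to_numpy()
        ccm[c] = sub["cm"].to_numpy()
        derived = ccm[c][0] + np.concatenate(
            ([0.0], np.cumsum(crate[c][:-1] * np.diff(p) / 1e6))
        )
        if np.max(np.abs(derived - ccm[c])) > 1e-6:
            logger.warning(
                "map %s chrom %s: cM column not re-derivable from rates; "
                "using cM column",
                path,
                c,
            )
    return RecombinationMap(cpos, crate, ccm)


def write_genetic_map(rmap: RecombinationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition\trate_cM_Mb\tmap_cM\n")
        for c in rmap.chromosomes:
            for p, r, m in zip(rmap.chrom_pos[c], rmap.chrom_rate[c], rmap.chrom_cm[c]):
                fh.write(f"{c}\t{p:.0f}\t{r:.10g}\t{m:.10g}\n")


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Interval tracks
# ---------------------------------------------------------------------------


@dataclass
class IntervalTrack:
    """Genomic intervals, stored 1-based inclusive, sorted by start per chromosome."""

    label: str
    intervals: dict[str, np.ndarray]  # (n, 2) int64 [lo, hi] inclusive

    def __post_init__(self):
        self._maxhi = {}
        for c, iv in self.intervals.items():
            order = np.argsort(iv[:, 0], kind="stable")
            iv = iv[order]
            self.intervals[c] = iv
            self._maxhi[c] = np.maximum.accumulate(iv[:, 1]) if len(iv) else iv[:, 1]

    def contains(self, chrom: str, pos) -> np.ndarray:
        """Boolean: does any interval contain each 1-based position."""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if chrom not in self.intervals or not len(self.intervals[chrom]):
            return np.zeros(pos.shape, dtype=bool)
        lo = self.intervals[chrom][:, 0]
        idx = np.searchsorted(lo, pos, side="right")
        out = np.zeros(pos.shape, dtype=bool)
        nz = idx > 0
        out[nz] = self._maxhi[chrom][idx[nz] - 1] >= pos[nz]
        return out

    @property
    def n_intervals(self) -> int:
        return sum(len(v) for v in self.intervals.values())

    def total_bp(self) -> int:
        return int(
            sum((iv[:, 1] - iv[:, 0] + 1).sum() for iv in self.intervals.values())
        )


def read_intervals(path, label: str = "track") -> IntervalTrack:
    """Read a BED file (0-based half-open) into a 1-based inclusive track."""
    iv: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise InputError(f"{path}:{lineno}: start >= end")
            iv.setdefault(chrom, []).append((start + 1, end))
    return IntervalTrack(
        label, {c: np.asarray(v, dtype=np.int64) for c, v in iv.items()}
    )


def write_intervals(track: IntervalTrack, path) -> None:
    with open(path, "w") as fh:
        for c in track.intervals:
            for lo, hi in track.intervals[c]:
                fh.write(f"{c}\t{lo - 1}\t{hi}\n")


def empty_track(label: str = "empty") -> IntervalTrack:
    return IntervalTrack(label, {})


# ---------------------------------------------------------------------------
# Config / report serialization
# ---------------------------------------------------------------------------


def read_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InputError(f"{path}: config must be a mapping")
    return cfg


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
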