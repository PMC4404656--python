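"""Recombination-rate annotation, bin-stratified NCO rate estimation with a
block bootstrap, genome-wide extrapolations, and the clustered-event
probability calculation.

The NCO coverage rate R is the probability that a base pair lies in a
conversion tract in one meiosis.  Because SNP-array content is enriched for
high-recombination regions relative to the genome, the rate is estimated
within recombination-rate bins (annotated from a genetic map as the cM
spanned by the 10 kb around each site divided by 0.01 Mb) and combined as

    R = sum_b w_b * n_b / m_b

where n_b is the (ascertainment-weighted) count of converted informative
sites in bin b, m_b the informative-site exposure, and w_b the fraction of
the mappable genome in the bin.  Confidence intervals come from a block
bootstrap over contiguous genomic blocks, with n_b, m_b and w_b all
recomputed per resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ncoscan.pedio import RecombinationMap

DEFAULT_BIN_EDGES = (0.0, 0.1, 0.5, 1.0, 3.0, 10.0, np.inf)
RATE_WINDOW_BP = 10_000


def annotate_rate(
    chrom: str, pos, rmap: RecombinationMap, window_bp: int = RATE_WINDOW_BP
) -> np.ndarray:
    """cM/Mb at site(s): map cM spanned by the surrounding window / window size.

    Sites whose window extends beyond the map's anchor span get NaN and are
    excluded from downstream tallies.
    """
    pos = np.atleast_1d(np.asarray(pos, dtype=float))
    half = window_bp / 2.0
    lo = rmap.cm_at(chrom, pos - half)
    hi = rmap.cm_at(chrom, pos + half)
    return (hi - lo) / (window_bp / 1e6)


def bin_index(rates: np.ndarray, bin_edges=DEFAULT_BIN_EDGES) -> np.ndarray:
    """Half-open bin assignment [lo, hi); NaN rates get -1.

    Rates are rounded to 1e-6 cM/Mb first so that interpolation jitter does
    not scatter exact-edge values across neighbouring bins.
    """
    edges = np.asarray(bin_edges, dtype=float)
    rates = np.round(np.asarray(rates, dtype=float), 6)
    idx = np.searchsorted(edges, rates, side="right") - 1
    idx[np.isnan(rates)] = -1
    idx[idx >= len(edges) - 1] = -1 if not np.isinf(edges[-1]) else len(edges) - 2
    return idx.astype(np.int64)


def bin_weights(
    rmap: RecombinationMap,
    chrom_lengths: dict[str, int],
    bin_edges=DEFAULT_BIN_EDGES,
    grid_bp: int = 1000,
) -> np.ndarray:
    """w_b: fraction of mappable genome bp whose annotated rate is in bin b.

    Evaluated on a regular grid (default 1 kb); positions outside the map
    span are excluded from the weights.
    """
    nb = len(bin_edges) - 1
    counts = np.zeros(nb, dtype=np.int64)
    for chrom, ln in chrom_lengths.items():
        if chrom not in rmap.chrom_pos:
            continue
        grid = np.arange(1, ln + 1, grid_bp, dtype=float)
        r = annotate_rate(chrom, grid, rmap)
        b = bin_index(r, bin_edges)
        for k in range(nb):
            counts[k] += int(np.sum(b == k))
    total = counts.sum()
    if total == 0:
        raise ValueError("genetic map covers none of the genome")
    return counts / total


@dataclass
class RateEstimate:
    R: float
    n_b: np.ndarray
    m_b: np.ndarray
    w_b: np.ndarray
    bin_edges: tuple
    ci95: tuple[float, float] | None = None
    bootstrap_reps: int = 0
    block_size_bp: int = 0

    def per_bin_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(self.m_b > 0, self.n_b / np.maximum(self.m_b, 1), 0.0)
        return r

    def to_dict(self) -> dict:
        return dict(
            R=self.R, ci95=self.ci95, n_b=self.n_b.tolist(),
            m_b=self.m_b.tolist(), w_b=self.w_b.tolist(),
            bin_edges=list(self.bin_edges), bootstrap_reps=self.bootstrap_reps,
            block_size_bp=self.block_size_bp,
        )


def _combine(n_b, m_b, w_b) -> float:
    ok = m_b > 0
    return float(np.sum(w_b[ok] * n_b[ok] / m_b[ok]))


def estimate_rate(
    nco_bins: np.ndarray,
    nco_weights: np.ndarray,
    info_bins: np.ndarray,
    info_exposure: np.ndarray,
    w_b: np.ndarray,
    bin_edges=DEFAULT_BIN_EDGES,
) -> RateEstimate:
    """Bin-stratified weighted NCO coverage rate.

    nco_bins/nco_weights: bin index and ascertainment weight per converted
    site (ambiguous orientations carry 0.5 each); info_bins/info_exposure:
    bin index and informative-row multiplicity per marker.  Sites with bin
    -1 (outside the map) are dropped from numerator and denominator alike.
    """
    nb = len(bin_edges) - 1
    n_b = np.zeros(nb)
    m_b = np.zeros(nb)
    ok = nco_bins >= 0
    np.add.at(n_b, nco_bins[ok], nco_weights[ok])
    ok = info_bins >= 0
    np.add.at(m_b, info_bins[ok], info_exposure[ok].astype(float))
    if m_b.sum() == 0:
        raise ValueError("no informative sites with a rate annotation")
    return RateEstimate(_combine(n_b, m_b, np.asarray(w_b)), n_b, m_b,
                        np.asarray(w_b), tuple(bin_edges))


def block_ids(chroms: np.ndarray, pos: np.ndarray, block_size_bp: float):
    """Contiguous-block label per site; blocks partition each chromosome."""
    keys = [f"{c}:{int(p // block_size_bp)}" for c, p in zip(chroms, pos)]
    uniq = sorted(set(keys))
    lut = {k: i for i, k in enumerate(uniq)}
    return np.array([lut[k] for k in keys]), len(uniq), lut


def bootstrap_rate(
    nco_blocks: np.ndarray,
    nco_bins: np.ndarray,
    nco_weights: np.ndarray,
    info_blocks: np.ndarray,
    info_bins: np.ndarray,
    info_exposure: np.ndarray,
    grid_blocks: np.ndarray,
    grid_bins: np.ndarray,
    n_blocks: int,
    reps: int,
    rng: np.random.Generator,
    bin_edges=DEFAULT_BIN_EDGES,
) -> tuple[float, float, np.ndarray]:
    """Percentile 95% CI for R from a block bootstrap.

    Genomic blocks are resampled with replacement (same count); per-bin NCO
    counts, informative exposure and genome-composition weights are all
    recomputed per resample from per-block tallies.  ``grid_blocks`` /
    ``grid_bins`` carry the genome-composition grid used for the weights.
    """
    nb = len(bin_edges) - 1
    n_blk = np.zeros((n_blocks, nb))
    m_blk = np.zeros((n_blocks, nb))
    g_blk = np.zeros((n_blocks, nb))
    ok = nco_bins >= 0
    np.add.at(n_blk, (nco_blocks[ok], nco_bins[ok]), nco_weights[ok])
    ok = info_bins >= 0
    np.add.at(m_blk, (info_blocks[ok], info_bins[ok]),
              info_exposure[ok].astype(float))
    ok = grid_bins >= 0
    np.add.at(g_blk, (grid_blocks[ok], grid_bins[ok]), 1.0)
    draws = rng.integers(0, n_blocks, size=(reps, n_blocks))
    out = np.empty(reps)
    for r in range(reps):
        idx = draws[r]
        n_b = n_blk[idx].sum(axis=0)
        m_b = m_blk[idx].sum(axis=0)
        g_b = g_blk[idx].sum(axis=0)
        w_b = g_b / g_b.sum() if g_b.sum() > 0 else g_b
        out[r] = _combine(n_b, m_b, w_b)
    lo, hi = np.percentile(out, [2.5, 97.5])
    return float(lo), float(hi), out


@dataclass
class ExtrapolationResult:
    """Genome-wide consequences of a coverage rate R.

    sites_per_gen = R*G bp converted per generation; events_per_gen =
    R*G/l conversion tracts; het_sites_per_gen = R*G*pi variable sites hit.
    """

    R: float
    G: float
    l: float  # noqa: E741 - field name mirrors the tract-length symbol
    pi: float
    sites_per_gen: float = field(init=False)
    events_per_gen: float = field(init=False)
    het_sites_per_gen: float = field(init=False)

    def __post_init__(self):
        self.sites_per_gen = self.R * self.G
        self.events_per_gen = self.R * self.G / self.l
        self.het_sites_per_gen = self.R * self.G * self.pi


def extrapolate(R: float, G: float = 2.9e9, l: float = 75.0, pi: float = 1e-3):  # noqa: E741
    """Per-generation NCO footprint for coverage rate R (defaults: euchromatic
    genome length 2.9 Gb, 75 bp mean tract, heterozygosity 1e-3)."""
    if min(R, G, l, pi) < 0 or l == 0:
        raise ValueError("parameters must be positive")
    return ExtrapolationResult(R, G, l, pi)


def rate_from_sperm_params(
    nco_to_co_ratio: float, co_rate_per_bp: float, mean_tract_bp: float
) -> float:
    """Coverage rate implied by sperm-typing parameters.

    R = (NCO events / CO events) * (CO rate per bp) * (mean tract length);
    the genome length cancels.  1.2 cM/Mb corresponds to 1.2e-8 per bp.
    """
    return nco_to_co_ratio * co_rate_per_bp * mean_tract_bp


@dataclass
class ClusterProbability:
    d_cm: float
    c_cm_mb: float
    R: float
    l: float  # noqa: E741
    window_bp: float
    r: float = field(init=False)
    P: float = field(init=False)

    def __post_init__(self):
        # genetic length d rescales the genome-average initiation rate R/l:
        # expected initiations in the window = (d / c, in bp) * R / l
        self.r = (self.d_cm / self.c_cm_mb) * 1e6 * self.R / self.l
        self.P = self.r**2


def cluster_probability(
    d_cm: float, R: float, c_cm_mb: float = 1.2, l: float = 75.0,  # noqa: E741
    window_bp: float = 1e5,
) -> ClusterProbability:
    """Probability of two independent NCO initiations in a window of genetic
    length d cM (no interference assumed): P = r^2."""
    if d_cm < 0:
        raise ValueError("d_cm must be >= 0")
    return ClusterProbability(d_cm, c_cm_mb, R, l, window_bp)


def map_consistency_test(
    nco_bins: np.ndarray,
    nco_weights: np.ndarray,
    info_bins: np.ndarray,
    info_exposure: np.ndarray,
    info_rates: np.ndarray,
    bin_edges=DEFAULT_BIN_EDGES,
) -> tuple[float, float]:
    """Chi-square test that NCO sites follow the map.

    Expected NCO counts per bin are proportional to the informative-site
    exposure times the mean annotated recombination rate of that exposure
    (the map-proportional null).  Returns (statistic, p) with
    df = n_bins - 1.
    """
    nb = len(bin_edges) - 1
    obs = np.zeros(nb)
    ok = nco_bins >= 0
    np.add.at(obs, nco_bins[ok], nco_weights[ok])
    exp = np.zeros(nb)
    ok = info_bins >= 0
    np.add.at(exp, info_bins[ok], info_exposure[ok] * info_rates[ok])
    keep = exp > 0
    exp = exp[keep] / exp[keep].sum() * obs.sum()
    obs = obs[keep]
    stat = float(np.sum((obs - exp) ** 2 / exp))
    df = keep.sum() - 1
    return stat, float(stats.chi2.sf(stat, df))
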