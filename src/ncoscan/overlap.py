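"""Hotspot-overlap of NCO events and its permutation significance test.

An event overlaps a track (e.g. DSB hotspots) when any of its converted
sites lies inside an interval.  Significance is assessed by permutation:
for each observed event, a random informative site is drawn and the same
number of adjacent informative sites (in the informative-site ordering of
one parent-child transmission on one chromosome) taken as a pseudo-event;
the overlap proportion of each permuted set is compared with the observed
one.  Permuted sites are drawn only from informative rows — the same
exposure set that could have yielded real events — and, by default, from
the same chromosome as the observed event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ncoscan.pedio import IntervalTrack

logger = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    n_events: int
    n_overlapping: float
    n_perm: int = 0
    p_value: float | None = None
    p_is_bound: bool = False

    @property
    def proportion(self) -> float:
        return self.n_overlapping / self.n_events if self.n_events else 0.0

    def to_dict(self) -> dict:
        return dict(
            n_events=self.n_events, n_overlapping=self.n_overlapping,
            proportion=self.proportion, n_perm=self.n_perm,
            p_value=self.p_value, p_is_bound=self.p_is_bound,
        )


def _event_hits(events, track: IntervalTrack, markers) -> np.ndarray:
    pos = markers["pos"].to_numpy()
    hits = np.zeros(len(events), dtype=bool)
    for i, e in enumerate(events):
        s = e.all_sites()
        hits[i] = bool(track.contains(e.chrom, pos[s]).any())
    return hits


def event_overlap(events, track: IntervalTrack, markers) -> OverlapResult:
    """Fraction of events with >=1 converted site inside the track.

    The caller restricts ``events`` to the analysis set (typically
    unambiguous events, optionally male-only or PRDM9-A/B-only
    transmitters).
    """
    hits = _event_hits(events, track, markers)
    return OverlapResult(len(events), int(hits.sum()))


def permutation_test(
    events,
    table,
    track: IntervalTrack,
    n_perm: int,
    rng: np.random.Generator,
    preserve_chrom: bool = True,
) -> OverlapResult:
    """Permutation p-value for the observed overlap proportion.

    p = (1 + #{permutations with overlap >= observed}) / (1 + n_perm);
    the add-one estimator never returns 0, and a zero-exceedance result is
    reported as the bound p < 1/n_perm.
    """
    if not events:
        raise ValueError("no events to test")
    obs = _event_hits(events, track, table.markers).sum()
    markers = table.markers
    pos = markers["pos"].to_numpy()
    chrom_arr = markers["chrom"].to_numpy()
    # informative-site pools: per (family, parent, child, chromosome) runs,
    # concatenated; in_track flags with prefix sums for O(1) window queries
    pool_sites: dict[str, list[np.ndarray]] = {}
    for (fam, par, ch), row in table.rows.items():
        idx = np.flatnonzero(row.informative)
        if idx.size == 0:
            continue
        for chrom in np.unique(chrom_arr[idx]):
            sub = idx[chrom_arr[idx] == chrom]
            pool_sites.setdefault(chrom, []).append(sub)
    pools = {}
    for chrom, runs in pool_sites.items():
        lengths = np.array([r.size for r in runs])
        cat = np.concatenate(runs)
        run_id = np.repeat(np.arange(len(runs)), lengths)
        inside = track.contains(chrom, pos[cat]).astype(np.int64)
        csum = np.concatenate(([0], np.cumsum(inside)))
        pools[chrom] = (cat, run_id, csum)
    if preserve_chrom:
        ev_pools = [e.chrom for e in events]
    else:
        all_cat = np.concatenate([p[0] for p in pools.values()])
        offs = np.cumsum([0] + [p[1].max() + 1 for p in pools.values()][:-1])
        all_run = np.concatenate(
            [p[1] + o for p, o in zip(pools.values(), offs)]
        )
        all_in = np.concatenate(
            [np.diff(p[2]) for p in pools.values()]
        )
        csum = np.concatenate(([0], np.cumsum(all_in)))
        pools = {"*": (all_cat, all_run, csum)}
        ev_pools = ["*" for _ in events]
    sizes = [e.sites.size for e in events]
    n_resampled = 0
    hit_counts = np.zeros(n_perm, dtype=np.int64)
    for e_i, (chrom, s) in enumerate(zip(ev_pools, sizes)):
        if chrom not in pools:
            raise ValueError(f"no informative sites on {chrom}")
        cat, run_id, csum = pools[chrom]
        N = cat.size
        need = n_perm
        hits_e = np.empty(0, dtype=bool)
        while need > 0:
            starts = rng.integers(0, N, size=need + need // 4 + 8)
            valid = starts + s - 1 < N
            valid &= run_id[np.minimum(starts + s - 1, N - 1)] == run_id[starts]
            n_resampled += int((~valid).sum())
            starts = starts[valid][:need]
            h = (csum[starts + s] - csum[starts]) > 0
            hits_e = np.concatenate([hits_e, h])
            need = n_perm - hits_e.size
        hit_counts += hits_e[:n_perm]
    exceed = int(np.sum(hit_counts >= obs))
    p = (1 + exceed) / (1 + n_perm)
    if n_resampled:
        logger.debug("permutation_test: %d draws resampled", n_resampled)
    return OverlapResult(len(events), int(obs), n_perm, p, exceed == 0)
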