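"""End-to-end analysis: phase pedigrees, ascertain informative sites, call
and filter NCO events."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ncoscan import ascertain as _asc
from ncoscan import detect as _detect
from ncoscan.pedio import GenotypeMatrix, IntervalTrack, PedigreeSet
from ncoscan.phase import phase_three_generation

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    scan_window: int = _detect.SCAN_WINDOW
    span_limit_bp: int = _detect.NCO_SPAN_BP
    cluster_window_bp: int = _detect.CLUSTER_WINDOW_BP
    inversion_run: int = 10
    exclusion: IntervalTrack | None = None
    call_nonstandard: bool = True


@dataclass
class AnalysisResult:
    peds: PedigreeSet
    gm: GenotypeMatrix
    table: _asc.InformativeSiteTable
    events: list[_detect.NCOEvent]
    removed: list[dict]
    phases: dict[tuple[str, str], object] = field(default_factory=dict)

    def standard_events(self) -> list[_detect.NCOEvent]:
        return [e for e in self.events if e.ascertainment == "standard"]

    def nco_site_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """(marker indices, weights) of standard-ascertainment NCO sites."""
        idx, wt = [], []
        for e in self.standard_events():
            if e.klass != _detect.CLASS_NCO:
                continue
            s, w = e.site_weights()
            idx.append(s)
            wt.append(w)
        if not idx:
            return np.empty(0, np.int64), np.empty(0)
        return np.concatenate(idx), np.concatenate(wt)

    def clusters(self, window_bp: int | None = None):
        pos = self.gm.markers["pos"].to_numpy()
        return _detect.cluster_events(
            self.events, pos, window_bp or _detect.CLUSTER_WINDOW_BP
        )


def analyze(
    peds: PedigreeSet,
    gm: GenotypeMatrix,
    config: AnalysisConfig | None = None,
    families: list[str] | None = None,
) -> AnalysisResult:
    """Run the full detection pipeline over every analyzable pedigree."""
    cfg = config or AnalysisConfig()
    table = _asc.InformativeSiteTable(gm.markers)
    all_events: list[_detect.NCOEvent] = []
    phases_flat: dict[tuple[str, str], object] = {}
    chrom_slices = {c: gm.chrom_slice(c) for c in gm.chromosomes}
    for ped in peds.analyzable():
        if families is not None and ped.family not in families:
            continue
        phases = {
            chrom: phase_three_generation(
                peds, gm, ped, chrom, cfg.inversion_run
            )
            for chrom in gm.chromosomes
        }
        for chrom, pp in phases.items():
            phases_flat[(ped.family, chrom)] = pp
        mask, candidates = _asc.pedigree_site_qc(
            ped, gm, phases, cfg.exclusion, cfg.scan_window
        )
        _asc.ascertain_informative(peds, gm, ped, phases, mask, candidates, table)
        for parent_id in (ped.father, ped.mother):
            for child in ped.analyzed:
                row = table.rows[(ped.family, parent_id, child)]
                all_events.extend(
                    _detect.assemble_events(
                        row, gm.markers, chrom_slices,
                        cfg.scan_window, cfg.span_limit_bp,
                    )
                )
        if cfg.call_nonstandard:
            ns = _detect.detect_nonstandard(ped, gm, phases, mask)
            all_events.extend(_merge_nonstandard(ns, all_events, gm))
    kept, removed = _detect.apply_event_filters(all_events, phases_flat)
    return AnalysisResult(peds, gm, table, kept, removed, phases_flat)


def _merge_nonstandard(ns_events, events, gm):
    """Attach non-standard sites falling inside an existing event's tract
    bounds to that event (mixed ascertainment); return the rest."""
    pos = gm.markers["pos"].to_numpy()
    out = []
    for n in ns_events:
        host = None
        npos = pos[n.sites[0]]
        for e in events:
            if e.ascertainment != "standard" or e.meiosis_key != n.meiosis_key:
                continue
            if e.chrom != n.chrom:
                continue
            lo = pos[e.sites].min() - e.tract_upper
            hi = pos[e.sites].max() + e.tract_upper
            if lo <= npos <= hi:
                host = e
                break
        if host is not None:
            host.meta.setdefault("nonstandard_sites", []).append(
                (int(n.sites[0]), int(n.alleles[0]))
            )
        else:
            out.append(n)
    return out
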