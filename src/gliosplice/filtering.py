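"""Significance filtering, cross-sample consolidation and protein-impact
classification of alternative-splicing events.

The significance filter keeps events with p <= 0.05, at least one read
supporting each of inclusion and exclusion, at least 10 total supporting
reads, and |dPSI| >= 0.10 (treated - control); all comparisons inclusive
and all thresholds configurable. Events are matched across samples when
their intervals reciprocally overlap by >= 95% on the same chromosome and
strand and share the same event class.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from scipy import stats

from .config import PipelineConfig
from .events import ImpactCall, SpliceEvent, TranscriptModel, ValidationError

STOP_CODONS = {"TAA", "TAG", "TGA"}
# tolerance so a dPSI computed as e.g. 0.6 - 0.5 still counts as >= 0.10
_DPSI_EPS = 1e-12
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def filter_significant(events: Sequence[SpliceEvent],
                       config: Optional[PipelineConfig] = None) -> List[SpliceEvent]:
    """Keep events passing every significance threshold (all inclusive)."""
    cfg = config or PipelineConfig()
    return [
        ev for ev in events
        if ev.p_value <= cfg.p_max
        and ev.inclusion_reads >= cfg.min_inc_reads
        and ev.exclusion_reads >= cfg.min_exc_reads
        and ev.total_reads >= cfg.min_total_reads
        and abs(ev.delta_psi) >= cfg.min_abs_dpsi - _DPSI_EPS
    ]


def reciprocal_overlap(a: SpliceEvent, b: SpliceEvent,
                       min_fraction: float = 0.95) -> Tuple[float, float, bool]:
    """Overlap fraction of each interval and whether the pair matches.

    Match requires overlap/len >= ``min_fraction`` for *both* intervals,
    identical chromosome and identical strand. Lengths are half-open.
    """
    if a.length <= 0 or b.length <= 0:
        raise ValidationError("reciprocal_overlap: zero-length interval")
    if a.chrom != b.chrom:
        return 0.0, 0.0, False
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    frac_a = ov / a.length
    frac_b = ov / b.length
    match = (frac_a >= min_fraction and frac_b >= min_fraction
             and a.strand == b.strand)
    return frac_a, frac_b, match


@dataclass
class ConsolidatedEvent:
    """A group of matched events (one per sample), keyed by a representative.

    The representative is the record from the first sample in input order;
    per-sample dPSI values are retained alongside.
    """

    representative: SpliceEvent
    members: Dict[str, SpliceEvent]

    @property
    def delta_psi_by_sample(self) -> Dict[str, float]:
        return {s: ev.delta_psi for s, ev in self.members.items()}


def consolidate(tables: Dict[str, Sequence[SpliceEvent]],
                config: Optional[PipelineConfig] = None) -> List[ConsolidatedEvent]:
    """Events present (by reciprocal-overlap match within class) in ALL samples.

    ``tables`` maps sample name to its filtered event list; iteration order
    defines which sample supplies the representative record.
    """
    cfg = config or PipelineConfig()
    names = list(tables)
    if len(names) < 2:
        raise ValueError("consolidate requires at least two sample tables")
    first, rest = names[0], names[1:]
    # index other samples by (chrom, strand, class) for fast candidate lookup
    index: Dict[str, Dict[tuple, List[SpliceEvent]]] = {}
    for name in rest:
        d: Dict[tuple, List[SpliceEvent]] = {}
        for ev in tables[name]:
            d.setdefault((ev.chrom, ev.strand, ev.event_class), []).append(ev)
        index[name] = d

    out: List[ConsolidatedEvent] = []
    for anchor in tables[first]:
        members = {first: anchor}
        key = (anchor.chrom, anchor.strand, anchor.event_class)
        for name in rest:
            best, best_ov = None, -1.0
            for cand in index[name].get(key, []):
                fa, fb, ok = reciprocal_overlap(anchor, cand,
                                                cfg.min_reciprocal_overlap)
                if ok and min(fa, fb) > best_ov:
                    best, best_ov = cand, min(fa, fb)
            if best is None:
                members = None
                break
            members[name] = best
        if members is not None:
            out.append(ConsolidatedEvent(representative=anchor, members=members))
    return out


def consolidation_summary(groups: Sequence[ConsolidatedEvent]) -> Dict[str, int]:
    return {
        "n_events": len(groups),
        "n_genes": len({g.representative.gene for g in groups}),
    }


# ---------------------------------------------------------------------------
# Protein-impact classification
# ---------------------------------------------------------------------------

def _contained_in_exon(event: SpliceEvent, tx: TranscriptModel,
                       strictly_inside: bool = False) -> bool:
    for s, e in tx.exons:
        if strictly_inside:
            if s < event.start and event.end < e:
                return True
        elif s <= event.start and event.end <= e:
            return True
    return False


def _overlaps_any_exon(event: SpliceEvent, tx: TranscriptModel) -> bool:
    return any(min(event.end, e) > max(event.start, s) for s, e in tx.exons)


def _maps_to_transcripts(event: SpliceEvent,
                         transcripts: Sequence[TranscriptModel]) -> bool:
    """Complete-inclusion / complete-exclusion mapping.

    A retained intron maps when some transcript carries it strictly inside a
    single exon (the retained form sits between two flanking exonic chunks).
    Exon-centred classes map when some transcript contains the segment
    within an exon (inclusion form) and another shows no exonic overlap at
    all (exclusion form).
    """
    same_gene = [t for t in transcripts if t.gene == event.gene] or list(transcripts)
    if event.event_class == "RI":
        return any(_contained_in_exon(event, t, strictly_inside=True)
                   for t in same_gene)
    included = any(_contained_in_exon(event, t) for t in same_gene)
    excluded = any(not _overlaps_any_exon(event, t) for t in same_gene)
    return included and excluded


def _scan_stop_in_frame(segment: str, frame_offset: int) -> bool:
    """Whether any full codon inside the segment, in the given frame, is a stop."""
    start = (3 - frame_offset) % 3
    for i in range(start, len(segment) - 2, 3):
        if segment[i:i + 3].upper() in STOP_CODONS:
            return True
    return False


def classify_impact(event: SpliceEvent,
                    transcripts: Sequence[TranscriptModel],
                    segment_sequence: Optional[str] = None) -> ImpactCall:
    """Predict the ORF impact of including the event segment.

    A mapped event whose length is not a multiple of 3 shifts the reading
    frame; a multiple-of-3 segment preserves frame unless a supplied
    sequence reveals an in-frame stop codon (frame anchored at the mapping
    transcript's coding start). Unmapped events are ``unknown``.
    """
    if not _maps_to_transcripts(event, transcripts):
        return ImpactCall(event.event_id, "unknown", "no_transcript_match")
    if event.length % 3 != 0:
        return ImpactCall(event.event_id, "disruptive_frameshift", "length_mod3")
    if segment_sequence is not None:
        if len(segment_sequence) != event.length:
            raise ValidationError(
                f"segment sequence length {len(segment_sequence)} != event "
                f"length {event.length}")
        coding = [t for t in transcripts
                  if t.gene == event.gene and t.coding_start is not None]
        for tx in coding:
            seq = segment_sequence
            if event.strand == "-":
                seq = seq.translate(_COMPLEMENT)[::-1]
                frame_offset = (tx.coding_start - event.end) % 3
            else:
                frame_offset = (event.start - tx.coding_start) % 3
            if _scan_stop_in_frame(seq, frame_offset):
                return ImpactCall(event.event_id, "disruptive_frameshift",
                                  "stop_codon")
    return ImpactCall(event.event_id, "in_frame_preserving", "length_mod3")


def direction_disruption_test(events: Sequence[SpliceEvent],
                              calls: Dict[str, ImpactCall],
                              alternative: str = "two-sided"
                              ) -> Tuple[List[List[int]], float, float]:
    """2x2 association of dPSI direction with predicted ORF disruption.

    Rows: dPSI > 0 / dPSI < 0; columns: disruptive / non-disruptive.
    Returns (table, odds_ratio, p) from Fisher's exact test. A table with a
    zero margin is degenerate: p = 1 with a warning.
    """
    table = [[0, 0], [0, 0]]
    for ev in events:
        call = calls[ev.event_id]
        if call.call == "unknown":
            raise ValueError(f"event {ev.event_id}: impact call is unknown")
        if ev.delta_psi == 0:
            raise ValueError(f"event {ev.event_id}: dPSI is zero")
        i = 0 if ev.delta_psi > 0 else 1
        j = 0 if call.call == "disruptive_frameshift" else 1
        table[i][j] += 1
    margins = [table[0][0] + table[0][1], table[1][0] + table[1][1],
               table[0][0] + table[1][0], table[0][1] + table[1][1]]
    if 0 in margins:
        warnings.warn("degenerate 2x2 table (zero margin); p set to 1")
        return table, float("nan"), 1.0
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return table, float(odds), float(p)
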