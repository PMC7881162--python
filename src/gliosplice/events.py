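"""Core domain types for alternative-splicing events.

Coordinates are stored 0-based half-open throughout the package (BED
convention); dialect readers in :mod:`gliosplice.io` convert on input.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

EVENT_CLASSES = ("CE", "RI", "MXE", "A3SS", "A5SS")
STRANDS = ("+", "-")

_DPSI_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when a record violates a domain invariant."""


@dataclass
class SpliceEvent:
    """One alternative-splicing event with condition PSIs and read support.

    ``delta_psi`` is treated-minus-control and must be consistent with the
    two PSI fields to within 1e-9.
    """

    event_id: str
    gene: str
    event_class: str
    chrom: str
    start: int  # 0-based
    end: int    # exclusive
    strand: str
    p_value: float
    inclusion_reads: int
    exclusion_reads: int
    psi_treated: float
    psi_control: float
    delta_psi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.delta_psi is None:
            self.delta_psi = self.psi_treated - self.psi_control
        self.validate()

    def validate(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValidationError(
                f"event {self.event_id}: unknown event_class {self.event_class!r}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"event {self.event_id}: bad strand {self.strand!r}")
        if not self.start < self.end:
            raise ValidationError(
                f"event {self.event_id}: start must be < end ({self.start}, {self.end})"
            )
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"event {self.event_id}: p_value outside [0,1]")
        for name in ("psi_treated", "psi_control"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"event {self.event_id}: {name}={v} outside [0,1]")
        if self.inclusion_reads < 0 or self.exclusion_reads < 0:
            raise ValidationError(f"event {self.event_id}: negative read count")
        if abs(self.delta_psi - (self.psi_treated - self.psi_control)) > _DPSI_TOL:
            raise ValidationError(
                f"event {self.event_id}: delta_psi inconsistent with condition PSIs"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def total_reads(self) -> int:
        return self.inclusion_reads + self.exclusion_reads


@dataclass
class ImpactCall:
    """Predicted protein impact of one event.

    ``call`` is ``unknown`` if and only if the event could not be mapped to
    any transcript model (``basis == "no_transcript_match"``).
    """

    event_id: str
    call: str    # disruptive_frameshift | in_frame_preserving | unknown
    basis: str   # length_mod3 | stop_codon | no_transcript_match

    def __post_init__(self) -> None:
        if (self.call == "unknown") != (self.basis == "no_transcript_match"):
            raise ValidationError(
                "ImpactCall: call must be 'unknown' exactly when basis is "
                "'no_transcript_match'"
            )


@dataclass
class TranscriptModel:
    """A transcript as an ordered chain of genomic exons.

    ``coding_start`` is the genomic position of the first coding base
    (0-based, on the + strand reading direction), used to establish reading
    frame for stop-codon scans.
    """

    transcript_id: str
    gene: str
    strand: str
    exons: Sequence[tuple[int, int]] = field(default_factory=list)
    coding_start: Optional[int] = None
    is_canonical: bool = False

    def __post_init__(self) -> None:
        prev_end = None
        for s, e in self.exons:
            if not s < e:
                raise ValidationError(
                    f"transcript {self.transcript_id}: malformed exon ({s}, {e})"
                )
            if prev_end is not None and s < prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons not sorted/disjoint"
                )
            prev_end = e
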