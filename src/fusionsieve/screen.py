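"""Filter cascade for candidate fusion calls.

Candidate fusions from an RNA-seq fusion caller are screened through four
filters before cross-caller validation:

1. in-frame: the junction preserves the reading frame (equal phases);
2. not-in-normal: the ordered gene pair is never called in a normal sample;
3. spanning-read support: junction-spanning reads >= ``min_spanning``
   (default 10);
4. intrachromosomal distance: breakpoints on the same chromosome must be at
   least ``min_intrachrom_distance`` apart (default 100 kb, inclusive) —
   closer same-chromosome pairs are overwhelmingly transcriptional
   read-through rather than genomic rearrangement. Interchromosomal calls
   bypass this filter.

Filters are evaluated independently and every flag is recorded, so the audit
table reconstructs the screening funnel; the survivor set is therefore
independent of filter order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .model import FusionCall, FusionClassification, GenomicBreakpoint, ValidationError


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the screening cascade. All boundaries are inclusive."""

    min_spanning: int = 10
    min_intrachrom_distance: int = 100_000
    require_in_frame: bool = True
    require_absent_in_normal: bool = True
    orientation_sensitive_normal_match: bool = True

    def __post_init__(self) -> None:
        if self.min_spanning < 0:
            raise ValidationError("min_spanning must be >= 0")
        if self.min_intrachrom_distance < 0:
            raise ValidationError("min_intrachrom_distance must be >= 0")


def compute_mid_distance(
    bp1: GenomicBreakpoint, bp2: GenomicBreakpoint
) -> Optional[int]:
    """Genomic separation of two breakpoints: |pos1 - pos2| on a shared
    chromosome, None for interchromosomal pairs. Symmetric, non-negative."""
    if bp1.chrom != bp2.chrom:
        return None
    return abs(bp1.pos - bp2.pos)


def absent_in_normal(
    call: FusionCall,
    normal_calls: Sequence[FusionCall],
    orientation_sensitive: bool = True,
) -> bool:
    """True iff no normal-sample call involves the same gene pair.

    Matching is at gene-pair level (breakpoint jitter between samples would
    defeat exact-position matching). With ``orientation_sensitive`` (default)
    only the same ordered (donor, acceptor) pair counts; the reciprocal
    orientation is treated as a distinct event.
    """
    pair = (call.donor_gene, call.acceptor_gene)
    for nc in normal_calls:
        npair = (nc.donor_gene, nc.acceptor_gene)
        if npair == pair:
            return False
        if not orientation_sensitive and npair == (pair[1], pair[0]):
            return False
    return True


@dataclass
class ScreenResult:
    """Audit of one screening run: every call classified, partitioned into
    survivors / rejected / unresolvable (conservation: the three parts sum
    to the input)."""

    classifications: list[FusionClassification]
    survivors: list[FusionCall]
    rejected: list[FusionCall]
    unresolvable: list[FusionCall]
    failure_reasons: dict[tuple, tuple[str, ...]] = field(default_factory=dict)

    @property
    def funnel(self) -> dict[str, int]:
        return {
            "input": len(self.survivors) + len(self.rejected) + len(self.unresolvable),
            "survivors": len(self.survivors),
            "rejected": len(self.rejected),
            "unresolvable": len(self.unresolvable),
        }


def apply_screen(
    calls: Sequence[FusionCall],
    normal_calls: Sequence[FusionCall] = (),
    frames: Optional[Mapping[tuple, Optional[bool]]] = None,
    config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """Run the full cascade over ``calls``.

    ``frames`` optionally maps ``call.key`` to a recomputed in-frame verdict
    (from transcript-model phase analysis); calls not covered there fall back
    to the caller-reported phase pair. A call with no frame information at
    all, while ``require_in_frame`` is set, cannot be audited and is returned
    as unresolvable rather than silently rejected.
    """
    frames = frames or {}
    classifications: list[FusionClassification] = []
    survivors: list[FusionCall] = []
    rejected: list[FusionCall] = []
    unresolvable: list[FusionCall] = []
    failure_reasons: dict[tuple, tuple[str, ...]] = {}

    for call in calls:
        in_frame = frames.get(call.key, call.in_frame)
        mid = compute_mid_distance(call.bp_donor, call.bp_acceptor)
        cls = FusionClassification(
            sample_id=call.sample_id,
            donor_gene=call.donor_gene,
            acceptor_gene=call.acceptor_gene,
            in_frame=in_frame,
            absent_in_normal=absent_in_normal(
                call, normal_calls, config.orientation_sensitive_normal_match
            ),
            spanning_pass=call.spanning_reads >= config.min_spanning,
            distance_pass=(mid is None or mid >= config.min_intrachrom_distance),
            mid_distance=mid,
        )
        classifications.append(cls)

        if config.require_in_frame and in_frame is None:
            unresolvable.append(call)
            failure_reasons[call.key] = ("frame unresolvable",)
            continue

        reasons = []
        if config.require_in_frame and not in_frame:
            reasons.append("out of frame")
        if config.require_absent_in_normal and not cls.absent_in_normal:
            reasons.append("seen in normal tissue")
        if not cls.spanning_pass:
            reasons.append("insufficient spanning reads")
        if not cls.distance_pass:
            reasons.append("intrachromosomal distance below threshold")
        if reasons:
            rejected.append(call)
            failure_reasons[call.key] = tuple(reasons)
        else:
            survivors.append(call)

    return ScreenResult(
        classifications=classifications,
        survivors=survivors,
        rejected=rejected,
        unresolvable=unresolvable,
        failure_reasons=failure_reasons,
    )
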