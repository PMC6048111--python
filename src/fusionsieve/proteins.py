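"""Fusion coding-sequence reconstruction: reading-frame compatibility and
protein-domain retention.

The donor contributes its coding sequence up to and including the donor
breakpoint (the last retained base); the acceptor contributes from its
breakpoint (the first retained base) to its stop. With

* ``L_d`` = retained donor coding length (bases) and
* ``D_a`` = discarded acceptor 5' coding length (bases),

the junction phases are ``L_d mod 3`` and ``D_a mod 3``; the chimeric
transcript is translated in the donor's frame, so the acceptor's native
codon boundaries are preserved if and only if the two phases are equal —
that is the in-frame test. Fusion-call tables label the same quantity as an
ordered pair such as ``2->0`` (donor phase -> acceptor phase).

Domain retention is then a pure amino-acid-interval computation on each
native protein: a domain wholly inside the retained segment is retained,
wholly outside is lost, and a straddling domain is truncated with fraction
retained-aa / domain-length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .model import ProteinDomain, TranscriptModel, ValidationError


# ------------------------------------------------------------- coordinates

def genomic_to_cds(tx: TranscriptModel, pos: int) -> Optional[int]:
    """Map a genomic position to its 0-based CDS offset (coding bases 5'->3'
    in transcript orientation), or None when the position is not a coding
    base of this transcript."""
    intervals = tx.cds_intervals
    if tx.strand == "-":
        offset = 0
        for s, e in reversed(intervals):
            if s <= pos <= e:
                return offset + (e - pos)
            offset += e - s + 1
        return None
    offset = 0
    for s, e in intervals:
        if s <= pos <= e:
            return offset + (pos - s)
        offset += e - s + 1
    return None


def cds_to_genomic(tx: TranscriptModel, offset: int) -> int:
    """Inverse of :func:`genomic_to_cds` for offsets in [0, cds_length)."""
    if not (0 <= offset < tx.cds_length):
        raise ValidationError(
            f"{tx.transcript_id}: CDS offset {offset} outside [0, {tx.cds_length})"
        )
    intervals = tx.cds_intervals
    if tx.strand == "-":
        for s, e in reversed(intervals):
            length = e - s + 1
            if offset < length:
                return e - offset
            offset -= length
    else:
        for s, e in intervals:
            length = e - s + 1
            if offset < length:
                return s + offset
            offset -= length
    raise AssertionError("unreachable")  # pragma: no cover


def describe_position(tx: TranscriptModel, pos: int) -> str:
    """Where a non-coding position falls: UTR, intron (with nearest exon),
    or off-transcript. Used for out-of-CDS diagnostics."""
    if not any(s <= pos <= e for s, e in tx.exons):
        inside_span = tx.exons[0][0] <= pos <= tx.exons[-1][1]
        if not inside_span:
            return f"outside transcript span of {tx.transcript_id}"
        nearest = min(
            range(len(tx.exons)),
            key=lambda i: min(abs(pos - tx.exons[i][0]), abs(pos - tx.exons[i][1])),
        )
        return f"intronic in {tx.transcript_id} (nearest exon index {nearest})"
    if pos < tx.cds_start or pos > tx.cds_end:
        genomic_5p = pos < tx.cds_start
        five_prime = genomic_5p if tx.strand == "+" else not genomic_5p
        return f"{'5' if five_prime else '3'}'UTR of {tx.transcript_id}"
    return f"coding in {tx.transcript_id}"


def _in_5p_utr(tx: TranscriptModel, pos: int) -> bool:
    exonic = any(s <= pos <= e for s, e in tx.exons)
    if not exonic:
        return False
    if tx.strand == "+":
        return pos < tx.cds_start
    return pos > tx.cds_end


# ------------------------------------------------------------------ phases

@dataclass(frozen=True)
class PhaseResult:
    """Junction phases and the in-frame verdict for one fusion."""

    donor_phase: Optional[int]
    acceptor_phase: Optional[int]
    in_frame: bool
    promoter_swap: bool = False
    reason: Optional[str] = None

    @property
    def label(self) -> Optional[str]:
        """The 'd->a' phase-pair label used in fusion reports."""
        if self.donor_phase is None or self.acceptor_phase is None:
            return None
        return f"{self.donor_phase}->{self.acceptor_phase}"


def junction_phases(
    donor_tx: TranscriptModel,
    donor_pos: int,
    acceptor_tx: TranscriptModel,
    acceptor_pos: int,
) -> PhaseResult:
    """Compute (donor phase, acceptor phase, in-frame) for a fusion junction.

    The donor breakpoint is the last retained base, the acceptor breakpoint
    the first retained base (both inclusive). Breakpoints outside the coding
    region make the corresponding phase undefined and the fusion
    not-in-frame, with two special cases on exonic UTR breakpoints:

    * donor breakpoint in the donor's 5'UTR: no donor coding sequence is
      contributed; the fusion is a promoter-swap candidate, flagged as such
      and called in-frame only when the acceptor phase is 0 (the acceptor
      open reading frame starts intact at a codon boundary);
    * acceptor breakpoint in the acceptor's 5'UTR: nothing of the acceptor
      CDS is discarded, so the acceptor phase is 0.
    """
    # acceptor side first (the donor UTR case needs it)
    acc_offset = genomic_to_cds(acceptor_tx, acceptor_pos)
    if acc_offset is not None:
        acceptor_phase: Optional[int] = acc_offset % 3
    elif _in_5p_utr(acceptor_tx, acceptor_pos):
        acceptor_phase = 0
    else:
        return PhaseResult(
            None, None, in_frame=False,
            reason=f"acceptor breakpoint {describe_position(acceptor_tx, acceptor_pos)}",
        )

    don_offset = genomic_to_cds(donor_tx, donor_pos)
    if don_offset is not None:
        donor_phase = (don_offset + 1) % 3  # breakpoint base is retained
        return PhaseResult(
            donor_phase, acceptor_phase, in_frame=(donor_phase == acceptor_phase)
        )
    if _in_5p_utr(donor_tx, donor_pos):
        return PhaseResult(
            0, acceptor_phase,
            in_frame=(acceptor_phase == 0),
            promoter_swap=True,
            reason="donor breakpoint upstream of CDS: promoter-swap candidate",
        )
    return PhaseResult(
        None, acceptor_phase, in_frame=False,
        reason=f"donor breakpoint {describe_position(donor_tx, donor_pos)}",
    )


# ----------------------------------------------------------------- domains

@dataclass(frozen=True)
class DomainStatus:
    """Retention status of one protein domain in the fusion product."""

    domain: ProteinDomain
    status: str  # retained | lost | truncated
    fraction: float  # retained aa / domain length, in [0, 1]


def domain_retention(
    side: str,
    breakpoint_aa: int,
    domains: Sequence[ProteinDomain],
    protein_length: Optional[int] = None,
) -> list[DomainStatus]:
    """Classify each domain of a fusion partner as retained / lost /
    truncated.

    ``breakpoint_aa`` is the junction in 1-based amino-acid coordinates on
    the native protein: for the donor, residues 1..breakpoint_aa are
    retained; for the acceptor, residues breakpoint_aa..protein_length.
    The three statuses are mutually exclusive and exhaustive.
    """
    if side not in ("donor", "acceptor"):
        raise ValidationError(f"side must be donor or acceptor, got {side!r}")
    out = []
    for dom in domains:
        if protein_length is not None and dom.end_aa > protein_length:
            raise ValidationError(
                f"{dom.gene}/{dom.name}: domain end {dom.end_aa} beyond "
                f"protein length {protein_length}"
            )
        if side == "donor":
            lo, hi = 1, breakpoint_aa
        else:
            lo, hi = breakpoint_aa, protein_length if protein_length else dom.end_aa
        overlap = max(0, min(hi, dom.end_aa) - max(lo, dom.start_aa) + 1)
        if overlap == dom.length:
            out.append(DomainStatus(dom, "retained", 1.0))
        elif overlap == 0:
            out.append(DomainStatus(dom, "lost", 0.0))
        else:
            out.append(DomainStatus(dom, "truncated", overlap / dom.length))
    return out


# ----------------------------------------------------------- fusion protein

@dataclass
class FusionProtein:
    """Reconstructed chimeric protein for one fusion junction."""

    donor_gene: str
    acceptor_gene: str
    donor_segment_aa: int
    acceptor_segment_aa: int
    phases: PhaseResult
    donor_domains: list[DomainStatus]
    acceptor_domains: list[DomainStatus]

    @property
    def in_frame(self) -> bool:
        return self.phases.in_frame

    @property
    def total_aa(self) -> int:
        return self.donor_segment_aa + self.acceptor_segment_aa

    @property
    def retained_domains(self) -> dict[tuple[str, str], DomainStatus]:
        return {
            (ds.domain.gene, ds.domain.name): ds
            for ds in self.donor_domains + self.acceptor_domains
        }

    def min_retained_fraction(self, gene: str) -> Optional[float]:
        """Smallest retained fraction over the domains annotated on
        ``gene``; None when the gene has no annotated domains."""
        fracs = [
            ds.fraction
            for ds in self.donor_domains + self.acceptor_domains
            if ds.domain.gene == gene
        ]
        return min(fracs) if fracs else None


def build_fusion_protein(
    donor_tx: TranscriptModel,
    donor_pos: int,
    acceptor_tx: TranscriptModel,
    acceptor_pos: int,
    domains: Sequence[ProteinDomain] = (),
) -> FusionProtein:
    """Reconstruct the fusion protein: segment lengths, phases, per-domain
    retention.

    The hybrid junction codon (when the donor phase is non-zero) is counted
    on the donor side, so for in-frame fusions
    ``total_aa = donor_segment_aa + acceptor_segment_aa`` equals the
    translated chimera length.
    """
    phases = junction_phases(donor_tx, donor_pos, acceptor_tx, acceptor_pos)

    don_offset = genomic_to_cds(donor_tx, donor_pos)
    retained_donor_nt = (don_offset + 1) if don_offset is not None else 0
    donor_segment_aa = math.ceil(retained_donor_nt / 3)

    acc_offset = genomic_to_cds(acceptor_tx, acceptor_pos)
    discarded_acceptor_nt = acc_offset if acc_offset is not None else 0
    retained_acceptor_nt = max(acceptor_tx.cds_length - discarded_acceptor_nt, 0)
    if phases.in_frame:
        hybrid_fill = (3 - retained_donor_nt % 3) % 3
        acceptor_segment_aa = max(retained_acceptor_nt - hybrid_fill, 0) // 3
    else:
        acceptor_segment_aa = retained_acceptor_nt // 3

    donor_bp_aa = donor_segment_aa  # last (possibly hybrid) donor residue
    acceptor_bp_aa = discarded_acceptor_nt // 3 + 1  # first retained residue

    donor_domains = domain_retention(
        "donor",
        donor_bp_aa,
        [d for d in domains if d.gene == donor_tx.gene],
        protein_length=donor_tx.protein_length,
    )
    acceptor_domains = domain_retention(
        "acceptor",
        acceptor_bp_aa,
        [d for d in domains if d.gene == acceptor_tx.gene],
        protein_length=acceptor_tx.protein_length,
    )

    return FusionProtein(
        donor_gene=donor_tx.gene,
        acceptor_gene=acceptor_tx.gene,
        donor_segment_aa=donor_segment_aa,
        acceptor_segment_aa=acceptor_segment_aa,
        phases=phases,
        donor_domains=donor_domains,
        acceptor_domains=acceptor_domains,
    )
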