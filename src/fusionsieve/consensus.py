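"""Cross-caller consensus: breakpoint-tolerant grouping and the 2-of-3 rule.

Different fusion callers report slightly different junction coordinates for
the same event (sub-exon jitter; occasionally kb-scale discrepancies between
short-read evidence and confirmatory sequencing). Calls are therefore grouped
by (sample, ordered gene pair) with both breakpoints within a configurable
tolerance, and a group is *validated* when at least ``min_support`` distinct
callers contributed to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .model import FusionCall, ValidationError

DEFAULT_TOLERANCE = 50  # bp; absorbs sub-exon breakpoint jitter between callers


@dataclass
class ConsensusGroup:
    """Calls from distinct callers judged to describe one fusion event."""

    sample_id: str
    donor_gene: str
    acceptor_gene: str
    member_calls: tuple[FusionCall, ...]

    def __post_init__(self) -> None:
        if not self.member_calls:
            raise ValidationError("consensus group needs >= 1 member call")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.sample_id, self.donor_gene, self.acceptor_gene)

    @property
    def callers(self) -> tuple[str, ...]:
        return tuple(sorted({c.caller_id for c in self.member_calls}))

    @property
    def support(self) -> int:
        return len(self.callers)

    @property
    def breakpoint_spread(self) -> int:
        """Max pairwise breakpoint distance (donor or acceptor side) within
        the group."""
        spread = 0
        members = self.member_calls
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                spread = max(
                    spread,
                    abs(a.bp_donor.pos - b.bp_donor.pos),
                    abs(a.bp_acceptor.pos - b.bp_acceptor.pos),
                )
        return spread

    @property
    def representative(self) -> FusionCall:
        """Deterministic representative: highest spanning-read count, ties
        broken by caller id."""
        return max(self.member_calls, key=lambda c: (c.spanning_reads, c.caller_id))


def _within(a: FusionCall, b: FusionCall, tolerance: int) -> bool:
    return (
        a.bp_donor.chrom == b.bp_donor.chrom
        and a.bp_acceptor.chrom == b.bp_acceptor.chrom
        and abs(a.bp_donor.pos - b.bp_donor.pos) <= tolerance
        and abs(a.bp_acceptor.pos - b.bp_acceptor.pos) <= tolerance
    )


def group_calls(
    calls: Sequence[FusionCall], tolerance: int = DEFAULT_TOLERANCE
) -> list[ConsensusGroup]:
    """Group calls sharing (sample, donor, acceptor) whose breakpoints agree
    within ``tolerance`` bp on both sides.

    Groups are the transitive closure of the pairwise within-tolerance
    relation (union-find), which makes the grouping independent of input
    order. Tolerance 0 degenerates to exact breakpoint matching, and groups
    at a smaller tolerance always refine groups at a larger one.
    """
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")

    by_key: dict[tuple, list[FusionCall]] = {}
    for call in calls:
        by_key.setdefault(call.key, []).append(call)

    groups: list[ConsensusGroup] = []
    for key in sorted(by_key):
        members = sorted(
            by_key[key],
            key=lambda c: (c.bp_donor.pos, c.bp_acceptor.pos, c.caller_id),
        )
        # union-find over this key's calls
        parent = list(range(len(members)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if _within(members[i], members[j], tolerance):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri

        clusters: dict[int, list[FusionCall]] = {}
        for i, call in enumerate(members):
            clusters.setdefault(find(i), []).append(call)
        for root in sorted(clusters):
            groups.append(
                ConsensusGroup(
                    sample_id=key[0],
                    donor_gene=key[1],
                    acceptor_gene=key[2],
                    member_calls=tuple(clusters[root]),
                )
            )
    return groups


def cross_validate(
    groups: Sequence[ConsensusGroup], min_support: int = 2
) -> list[ConsensusGroup]:
    """Retain groups supported by at least ``min_support`` distinct callers
    (default: the 2-of-3 rule)."""
    if min_support < 1:
        raise ValidationError("min_support must be >= 1")
    return [g for g in groups if g.support >= min_support]
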