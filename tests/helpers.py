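"""Shared test utilities: independent toy-locus construction and brute-force
oracles.

The locus builder starts from a known coding sequence and scatters it across
exons itself, keeping its own list of where every coding base landed — so
tests can derive breakpoint coordinates and expected results without going
through the package's coordinate arithmetic.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from fusionsieve.model import TranscriptModel

SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """A stop-free coding sequence of ``n_codons`` codons."""
    return "".join(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons))


def build_locus(
    rng: np.random.Generator,
    cds: str,
    strand: str,
    gene: str = "TOY",
    chrom: str = "chrT",
):
    """Scatter ``cds`` over 1-4 exons with UTRs and introns.

    Returns (TranscriptModel, pos_of_offset) where pos_of_offset[i] is the
    genomic position of CDS base i (0-based, transcript orientation). The
    minus-strand layout is the plus-strand one reflected through a constant,
    so the bookkeeping never reuses the package's strand logic.
    """
    n = len(cds)
    n_exons = int(rng.integers(1, 5))
    # split points inside the CDS
    if n_exons > 1:
        cuts = sorted(rng.choice(np.arange(1, n), size=n_exons - 1, replace=False))
    else:
        cuts = []
    chunks = np.diff([0, *cuts, n])

    utr5 = int(rng.integers(5, 40))
    utr3 = int(rng.integers(5, 40))
    origin = int(rng.integers(1_000, 5_000))

    exons = []
    pos_of_offset = []
    cursor = origin
    for k, chunk in enumerate(chunks):
        lead = utr5 if k == 0 else 0
        trail = utr3 if k == len(chunks) - 1 else 0
        exon_start = cursor
        coding_start = exon_start + lead
        pos_of_offset.extend(range(coding_start, coding_start + int(chunk)))
        exon_end = coding_start + int(chunk) - 1 + trail
        exons.append((exon_start, exon_end))
        cursor = exon_end + 1 + int(rng.integers(50, 500))

    cds_start = pos_of_offset[0]
    cds_end = pos_of_offset[-1]

    if strand == "-":
        mirror = cursor + 10_000
        exons = sorted((mirror - e, mirror - s) for s, e in exons)
        pos_of_offset = [mirror - p for p in pos_of_offset]
        cds_start, cds_end = mirror - cds_end, mirror - cds_start

    tx = TranscriptModel(
        gene=gene,
        transcript_id=f"{gene}.t1",
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_start=cds_start,
        cds_end=cds_end,
    )
    assert tx.cds_length == n
    return tx, pos_of_offset


CODON_TABLE = {}


def _codon_table():
    if not CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            CODON_TABLE[stop] = "*"
    return CODON_TABLE


def translate(nt: str) -> str:
    """Brute-force codon walk (standard code), ignoring any trailing
    partial codon."""
    table = _codon_table()
    return "".join(
        table[nt[i:i + 3]] for i in range(0, len(nt) - len(nt) % 3, 3)
    )


def fused_frame_oracle(donor_cds: str, ld: int, acceptor_cds: str, da: int) -> bool:
    """Translation oracle for frame preservation.

    Concatenates the retained pieces and checks whether the acceptor's
    native C-terminal peptide survives in the chimera's translation — true
    exactly when the acceptor's codon boundaries are preserved downstream
    of the junction. Requires >= 18 retained acceptor bases so the tail
    peptide is unambiguous.
    """
    assert len(acceptor_cds) - da >= 18
    fused = donor_cds[:ld] + acceptor_cds[da:]
    native_tail = translate(acceptor_cds)[-5:]
    return translate(fused).endswith(native_tail)


def exact_overlap_mid_p(mut: list[bool], k: int, observed: int) -> float:
    """Exhaustive label-permutation mid-p: enumerate every size-k carrier
    subset, half weight on ties."""
    n = len(mut)
    below = ties = total = 0
    for subset in itertools.combinations(range(n), k):
        stat = sum(1 for i in subset if mut[i])
        total += 1
        if stat < observed:
            below += 1
        elif stat == observed:
            ties += 1
    return (below + 0.5 * ties) / total


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration: sum the
    probabilities of all tables (same margins) no more probable than the
    observed one."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def p_of(x: int) -> float:
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = p_of(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(p_of(x) for x in range(lo, hi + 1) if p_of(x) <= p_obs * (1 + 1e-9))
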