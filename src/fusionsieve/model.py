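"""Core domain types for the fusion-gene prioritization pipeline.

Conventions
-----------
* All genomic coordinates are 1-based and inclusive, matching the way
  breakpoints are reported in fusion-call tables (``chr2: 29446394``).
  Readers converting from 0-based half-open inputs do so at the boundary.
* A fusion is oriented: the *donor* contributes the 5' part of the chimeric
  transcript, the *acceptor* the 3' part.
* Junction *phase* is the number of coding bases modulo 3 accumulated up to
  the junction on each partner; equal phases mean the reading frame is
  preserved across the junction (an in-frame fusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence


class ValidationError(ValueError):
    """An object violates a documented invariant."""


class FileFormatError(ValueError):
    """An input table is malformed; the message names the offending column/line."""


VALID_STRANDS = frozenset({"+", "-"})

VARIANT_EFFECTS = frozenset(
    {"frameshift", "non-synonymous", "stop-gain", "stop-loss", "other"}
)

MSI_LEVELS = ("MSS", "MSI-L", "MSI-H")
HISTOLOGY_LEVELS = ("well", "moderately", "poorly", "mucinous")
INVASION_LEVELS = ("T1", "T2", "T3", "T4")
LOCATION_LEVELS = ("right", "left")
SEX_LEVELS = ("male", "female")


@dataclass(frozen=True)
class GenomicBreakpoint:
    """A single fusion breakpoint: chromosome, 1-based position, strand."""

    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("breakpoint chrom must be non-empty")
        if self.pos < 1:
            raise ValidationError(f"breakpoint pos must be >= 1, got {self.pos}")
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"breakpoint strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class FusionCall:
    """One caller's candidate fusion junction in one sample."""

    sample_id: str
    caller_id: str
    donor_gene: str
    acceptor_gene: str
    bp_donor: GenomicBreakpoint
    bp_acceptor: GenomicBreakpoint
    spanning_reads: int
    frame_shift: Optional[tuple[int, int]] = None  # (donor phase, acceptor phase)

    def __post_init__(self) -> None:
        if self.donor_gene == self.acceptor_gene:
            raise ValidationError(
                f"donor and acceptor genes must differ, both {self.donor_gene!r}"
            )
        if self.spanning_reads < 0:
            raise ValidationError("spanning_reads must be >= 0")
        if self.frame_shift is not None:
            d, a = self.frame_shift
            if d not in (0, 1, 2) or a not in (0, 1, 2):
                raise ValidationError(f"junction phases must be in {{0,1,2}}, got {self.frame_shift}")

    @property
    def key(self) -> tuple[str, str, str]:
        """Sample + ordered gene pair: the identity used for matching calls."""
        return (self.sample_id, self.donor_gene, self.acceptor_gene)

    @property
    def in_frame(self) -> Optional[bool]:
        if self.frame_shift is None:
            return None
        return self.frame_shift[0] == self.frame_shift[1]


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one transcript, enabling genomic<->CDS<->protein
    coordinate conversion.

    ``exons`` are 1-based inclusive (start, end) intervals sorted by genomic
    position and non-overlapping; ``cds_start``/``cds_end`` are the genomic
    bounds of the coding region (stop codon excluded), both inside the exon
    union. The coding length must be a positive multiple of 3 for the protein
    length to be well defined; a minimum of one codon is enforced.
    """

    gene: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"transcript strand must be + or -, got {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValidationError(f"{self.transcript_id}: transcript needs >= 1 exon")
        prev_end = 0
        for start, end in exons:
            if start < 1 or end < start:
                raise ValidationError(f"{self.transcript_id}: bad exon interval ({start}, {end})")
            if start <= prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons must be sorted and non-overlapping"
                )
            prev_end = end
        if self.cds_start > self.cds_end:
            raise ValidationError(f"{self.transcript_id}: cds_start > cds_end")
        if not (self._covered(self.cds_start) and self._covered(self.cds_end)):
            raise ValidationError(f"{self.transcript_id}: CDS bounds must lie inside exons")
        if self.cds_length < 3:
            raise ValidationError(f"{self.transcript_id}: CDS shorter than one codon")

    def _covered(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    @property
    def cds_intervals(self) -> tuple[tuple[int, int], ...]:
        """Exon pieces intersected with [cds_start, cds_end], genomic order."""
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 <= e2:
                out.append((s2, e2))
        return tuple(out)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3


@dataclass(frozen=True)
class ProteinDomain:
    """A named protein region in 1-based inclusive amino-acid coordinates."""

    gene: str
    name: str
    start_aa: int
    end_aa: int

    def __post_init__(self) -> None:
        if not (1 <= self.start_aa <= self.end_aa):
            raise ValidationError(
                f"{self.gene}/{self.name}: need 1 <= start_aa <= end_aa, "
                f"got ({self.start_aa}, {self.end_aa})"
            )

    @property
    def length(self) -> int:
        return self.end_aa - self.start_aa + 1


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic single-nucleotide/indel call with the quality fields the
    hard-filter cascade consumes (depths, Fisher-strand, qual-by-depth,
    population allele frequency)."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    total_depth: Optional[int] = None
    alt_depth: Optional[int] = None
    effect: Optional[str] = None
    region: Optional[str] = None  # exon / intron / UTR
    fs: Optional[float] = None
    qd: Optional[float] = None
    pop_maf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.total_depth is not None and self.total_depth < 0:
            raise ValidationError("total_depth must be >= 0")
        if self.alt_depth is not None:
            if self.alt_depth < 0:
                raise ValidationError("alt_depth must be >= 0")
            if self.total_depth is not None and self.alt_depth > self.total_depth:
                raise ValidationError(
                    f"{self.sample_id} {self.chrom}:{self.pos}: alt_depth "
                    f"{self.alt_depth} exceeds total_depth {self.total_depth}"
                )
        if self.effect is not None and self.effect not in VARIANT_EFFECTS:
            raise ValidationError(f"unknown variant effect {self.effect!r}")
        if self.pop_maf is not None and not (0.0 <= self.pop_maf <= 1.0):
            raise ValidationError(f"pop_maf must be in [0,1], got {self.pop_maf}")

    @property
    def vaf(self) -> Optional[float]:
        """Variant allele fraction (alt depth / total depth)."""
        if self.total_depth in (None, 0) or self.alt_depth is None:
            return None
        return self.alt_depth / self.total_depth


@dataclass
class ExpressionMatrix:
    """Gene x sample FPKM matrix with tumour/normal class labels.

    ``values`` is a pandas DataFrame (index: gene symbols, columns: sample
    ids), all entries non-negative. ``sample_class`` maps every column to
    'tumour' or 'normal'; ``pairing`` optionally maps tumour samples to their
    matched normals.
    """

    values: "pandas.DataFrame"  # noqa: F821 - imported lazily by io
    sample_class: dict[str, str]
    pairing: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            bad = self.values[(self.values < 0).any(axis=1)].index[0]
            raise ValidationError(f"negative FPKM for gene {bad!r}")
        missing = [c for c in self.values.columns if c not in self.sample_class]
        if missing:
            raise ValidationError(f"samples without tumour/normal class: {missing}")
        bad_cls = {v for v in self.sample_class.values()} - {"tumour", "normal"}
        if bad_cls:
            raise ValidationError(f"sample classes must be tumour/normal, got {bad_cls}")

    def samples(self, cls: Optional[str] = None) -> list[str]:
        if cls is None:
            return list(self.values.columns)
        return [c for c in self.values.columns if self.sample_class[c] == cls]


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient clinicopathological covariates and overall survival."""

    sample_id: str
    age: float
    size_cm: float
    sex: str
    location: str
    histology: str
    invasion_depth: str
    perineural: bool
    lymphovascular: bool
    lymph_node: bool
    msi_status: str
    os_months: float
    os_event: bool

    def __post_init__(self) -> None:
        checks = [
            ("sex", self.sex, SEX_LEVELS),
            ("location", self.location, LOCATION_LEVELS),
            ("histology", self.histology, HISTOLOGY_LEVELS),
            ("invasion_depth", self.invasion_depth, INVASION_LEVELS),
            ("msi_status", self.msi_status, MSI_LEVELS),
        ]
        for name, value, levels in checks:
            if value not in levels:
                raise ValidationError(
                    f"{self.sample_id}: {name} must be one of {levels}, got {value!r}"
                )
        if self.os_months < 0:
            raise ValidationError(f"{self.sample_id}: os_months must be >= 0")


@dataclass
class FusionClassification:
    """Per-fusion audit record accumulated across pipeline stages.

    Filter flags are all recorded (no short-circuiting) so the audit trail
    reconstructs the screening funnel; ``mid_distance`` is None for
    interchromosomal fusions. ``function_category`` holds the annotated roles
    of the partner genes; ``reasons`` enumerates which oncogenicity clauses
    fired.
    """

    sample_id: str
    donor_gene: str
    acceptor_gene: str
    in_frame: Optional[bool] = None
    absent_in_normal: Optional[bool] = None
    spanning_pass: Optional[bool] = None
    distance_pass: Optional[bool] = None
    mid_distance: Optional[int] = None
    consensus_support: Optional[int] = None
    supporting_callers: tuple[str, ...] = ()
    outlier_donor: Optional[bool] = None
    outlier_acceptor: Optional[bool] = None
    function_category: frozenset[str] = frozenset()
    oncogenic: Optional[bool] = None
    reasons: tuple[str, ...] = ()

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.sample_id, self.donor_gene, self.acceptor_gene)

    @property
    def high_expression_label(self) -> str:
        """Human-readable outlier summary: '', 'Donor', 'Acceptor',
        or 'Donor and acceptor'."""
        d = bool(self.outlier_donor)
        a = bool(self.outlier_acceptor)
        if d and a:
            return "Donor and acceptor"
        if d:
            return "Donor"
        if a:
            return "Acceptor"
        return ""

    def validate(self) -> None:
        if self.consensus_support is not None and not (1 <= self.consensus_support <= 3):
            raise ValidationError("consensus_support must be in 1..3")
        if self.oncogenic:
            has_evidence = (
                bool(self.outlier_donor)
                or bool(self.outlier_acceptor)
                or bool(self.function_category)
            )
            if not has_evidence:
                raise ValidationError(
                    f"{self.key}: oncogenic verdict without outlier or function evidence"
                )


@dataclass(frozen=True)
class GeneFunctionAnnotation:
    """Cancer-relevant roles of a gene: any subset of kinase / oncogene /
    suppressor."""

    gene: str
    categories: frozenset[str]

    VALID = frozenset({"kinase", "oncogene", "suppressor"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", frozenset(self.categories))
        bad = self.categories - self.VALID
        if bad:
            raise ValidationError(f"{self.gene}: unknown function categories {sorted(bad)}")


@dataclass
class RowError:
    """A malformed input row, reported with its 1-based line number."""

    line: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line}: {self.message}"
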