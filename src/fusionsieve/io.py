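"""Readers and writers for every external table the pipeline touches.

All tabular formats are plain tab-separated text with a header row. Fusion
calls, domains, variants, expression and clinical tables round-trip exactly
(write then read reproduces field-identical objects). Transcript models are
read from / written to GTF (exon + CDS features only). A VCF route for
variants (INFO keys FS/QD, plus annotation keys) is provided through pysam.

Loading never silently drops rows: with ``on_error='collect'`` every reader
returns ``(records, errors)`` where each error carries the 1-based line
number, and parsed + errored rows account for every input row; with the
default ``on_error='raise'`` the first malformed row aborts the load with a
:class:`~fusionsieve.model.FileFormatError` naming the line.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import pandas as pd

from .model import (
    ClinicalRecord,
    ExpressionMatrix,
    FileFormatError,
    FusionCall,
    GeneFunctionAnnotation,
    GenomicBreakpoint,
    ProteinDomain,
    RowError,
    SomaticVariant,
    TranscriptModel,
    ValidationError,
)

PathLike = Union[str, Path]

FUSION_CALL_COLUMNS = [
    "sample", "caller", "donor_gene", "acceptor_gene",
    "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2",
    "spanning_reads", "frame",
]

VARIANT_COLUMNS = [
    "sample", "gene", "chrom", "pos", "ref", "alt",
    "total_depth", "alt_depth", "effect", "region", "fs", "qd", "pop_maf",
]

CLINICAL_COLUMNS = [
    "sample", "age", "size_cm", "sex", "location", "histology",
    "invasion_depth", "perineural", "lymphovascular", "lymph_node",
    "msi_status", "os_months", "os_event",
]


def _open_rows(path: PathLike, required: Sequence[str]):
    """Yield (line_number, row_dict) from a TSV with a header row."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise FileFormatError(
                f"{path}: missing mandatory column(s) {', '.join(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            yield lineno, row


def _parse_frame(token: str) -> Optional[tuple[int, int]]:
    """Parse a 'd->a' phase-pair label ('' or '.' means unknown)."""
    token = token.strip()
    if token in ("", ".", "NA"):
        return None
    sep = "->" if "->" in token else None
    if sep is None:
        raise ValueError(f"frame label must look like '2->0', got {token!r}")
    d, a = token.split(sep)
    return (int(d), int(a))


def _format_frame(frame: Optional[tuple[int, int]]) -> str:
    if frame is None:
        return "."
    return f"{frame[0]}->{frame[1]}"


def _collecting_reader(path, required, parse_row, on_error):
    records, errors = [], []
    for lineno, row in _open_rows(path, required):
        try:
            records.append(parse_row(row))
        except (ValueError, ValidationError, KeyError) as exc:
            if on_error == "raise":
                raise FileFormatError(f"{path}: line {lineno}: {exc}") from exc
            errors.append(RowError(lineno, str(exc)))
    if on_error == "raise":
        return records
    return records, errors


# ---------------------------------------------------------------- fusion calls

def read_fusion_calls(
    path: PathLike,
    caller_id: Optional[str] = None,
    on_error: str = "raise",
):
    """Read a fusion-call TSV; ``caller_id`` (when given) is stamped on every
    call, overriding the file's ``caller`` column."""

    def parse(row) -> FusionCall:
        return FusionCall(
            sample_id=row["sample"],
            caller_id=caller_id if caller_id is not None else row["caller"],
            donor_gene=row["donor_gene"],
            acceptor_gene=row["acceptor_gene"],
            bp_donor=GenomicBreakpoint(row["chrom1"], int(row["pos1"]), row["strand1"]),
            bp_acceptor=GenomicBreakpoint(row["chrom2"], int(row["pos2"]), row["strand2"]),
            spanning_reads=int(row["spanning_reads"]),
            frame_shift=_parse_frame(row.get("frame", "")),
        )

    return _collecting_reader(path, FUSION_CALL_COLUMNS, parse, on_error)


def write_fusion_calls(calls: Sequence[FusionCall], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(FUSION_CALL_COLUMNS)
        for c in calls:
            w.writerow([
                c.sample_id, c.caller_id, c.donor_gene, c.acceptor_gene,
                c.bp_donor.chrom, c.bp_donor.pos, c.bp_donor.strand,
                c.bp_acceptor.chrom, c.bp_acceptor.pos, c.bp_acceptor.strand,
                c.spanning_reads, _format_frame(c.frame_shift),
            ])


# ----------------------------------------------------------------- transcripts

def read_transcripts(path: PathLike, on_error: str = "raise"):
    """Read transcript models from a GTF restricted to exon and CDS features.

    Records are grouped by the ``transcript_id`` attribute; ``gene`` comes
    from ``gene_name`` (falling back to ``gene_id``). The CDS genomic bounds
    are the min/max over CDS features. Invariants are enforced per transcript;
    with ``on_error='collect'`` a failing transcript is reported (line number
    of its first record) instead of aborting.
    """
    by_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FileFormatError(f"{path}: line {lineno}: expected 9 GTF fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            attr = {}
            for part in attrs.strip().strip(";").split(";"):
                part = part.strip()
                if not part:
                    continue
                k, _, v = part.partition(" ")
                attr[k] = v.strip().strip('"')
            tx_id = attr.get("transcript_id")
            if not tx_id:
                raise FileFormatError(f"{path}: line {lineno}: missing transcript_id")
            rec = by_tx.setdefault(
                tx_id,
                {
                    "gene": attr.get("gene_name", attr.get("gene_id", tx_id)),
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "cds": [],
                    "line": lineno,
                },
            )
            interval = (int(start), int(end))
            if feature == "exon":
                rec["exons"].append(interval)
            else:
                rec["cds"].append(interval)

    transcripts, errors = [], []
    for tx_id, rec in by_tx.items():
        try:
            if not rec["cds"]:
                raise ValidationError(f"{tx_id}: no CDS features")
            transcripts.append(
                TranscriptModel(
                    gene=rec["gene"],
                    transcript_id=tx_id,
                    chrom=rec["chrom"],
                    strand=rec["strand"],
                    exons=tuple(sorted(rec["exons"])),
                    cds_start=min(s for s, _ in rec["cds"]),
                    cds_end=max(e for _, e in rec["cds"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            if on_error == "raise":
                raise FileFormatError(f"{path}: transcript {tx_id}: {exc}") from exc
            errors.append(RowError(rec["line"], str(exc)))
    if on_error == "raise":
        return transcripts
    return transcripts, errors


def write_transcripts(transcripts: Sequence[TranscriptModel], path: PathLike) -> None:
    """Write transcript models as GTF exon + CDS features."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = f'gene_id "{tx.gene}"; gene_name "{tx.gene}"; transcript_id "{tx.transcript_id}";'
            for s, e in tx.exons:
                fh.write(
                    f"{tx.chrom}\tfusionsieve\texon\t{s}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
            for s, e in tx.cds_intervals:
                fh.write(
                    f"{tx.chrom}\tfusionsieve\tCDS\t{s}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


def pick_representative_transcripts(
    transcripts: Sequence[TranscriptModel],
    chooser: Optional[Callable[[Sequence[TranscriptModel]], TranscriptModel]] = None,
) -> dict[str, TranscriptModel]:
    """One transcript per gene symbol (the join key across tables).

    Default rule: the transcript with the longest CDS; ties break on
    transcript_id for determinism. Pass ``chooser`` to override.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene, []).append(tx)
    if chooser is None:
        chooser = lambda txs: max(txs, key=lambda t: (t.cds_length, t.transcript_id))
    return {gene: chooser(txs) for gene, txs in by_gene.items()}


# -------------------------------------------------------------------- domains

def read_domains(path: PathLike, on_error: str = "raise"):
    def parse(row) -> ProteinDomain:
        return ProteinDomain(
            gene=row["gene"], name=row["name"],
            start_aa=int(row["start_aa"]), end_aa=int(row["end_aa"]),
        )

    return _collecting_reader(path, ["gene", "name", "start_aa", "end_aa"], parse, on_error)


def write_domains(domains: Sequence[ProteinDomain], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "name", "start_aa", "end_aa"])
        for d in domains:
            w.writerow([d.gene, d.name, d.start_aa, d.end_aa])


# ------------------------------------------------------------- gene functions

def read_gene_functions(path: PathLike, on_error: str = "raise"):
    """TSV with columns gene, categories (comma-separated subset of
    kinase/oncogene/suppressor; empty means no annotated role)."""

    def parse(row) -> GeneFunctionAnnotation:
        cats = [c.strip() for c in row["categories"].split(",") if c.strip()]
        return GeneFunctionAnnotation(gene=row["gene"], categories=frozenset(cats))

    return _collecting_reader(path, ["gene", "categories"], parse, on_error)


def write_gene_functions(
    annotations: Sequence[GeneFunctionAnnotation], path: PathLike
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "categories"])
        for a in annotations:
            w.writerow([a.gene, ",".join(sorted(a.categories))])


# ------------------------------------------------------------------- variants

def _opt_float(token: str) -> Optional[float]:
    token = (token or "").strip()
    if token in ("", ".", "NA"):
        return None
    return float(token)


def _opt_str(token: str) -> Optional[str]:
    token = (token or "").strip()
    return None if token in ("", ".", "NA") else token


def _opt_int(token: str) -> Optional[int]:
    token = (token or "").strip()
    if token in ("", ".", "NA"):
        return None
    return int(token)


def read_variants(path: PathLike, on_error: str = "raise"):
    """Read somatic variants from the flat TSV format (see VARIANT_COLUMNS)."""

    def parse(row) -> SomaticVariant:
        return SomaticVariant(
            sample_id=row["sample"], gene=row["gene"], chrom=row["chrom"],
            pos=int(row["pos"]), ref=row["ref"], alt=row["alt"],
            total_depth=_opt_int(row["total_depth"]),
            alt_depth=_opt_int(row["alt_depth"]),
            effect=_opt_str(row["effect"]),
            region=_opt_str(row["region"]),
            fs=_opt_float(row["fs"]), qd=_opt_float(row["qd"]),
            pop_maf=_opt_float(row["pop_maf"]),
        )

    return _collecting_reader(path, VARIANT_COLUMNS, parse, on_error)


def write_variants(variants: Sequence[SomaticVariant], path: PathLike) -> None:
    def fmt(v):
        return "." if v is None else v

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(VARIANT_COLUMNS)
        for v in variants:
            w.writerow([
                v.sample_id, v.gene, v.chrom, v.pos, v.ref, v.alt,
                fmt(v.total_depth), fmt(v.alt_depth), fmt(v.effect),
                fmt(v.region), fmt(v.fs), fmt(v.qd), fmt(v.pop_maf),
            ])


def read_variants_vcf(path: PathLike, sample_id: Optional[str] = None):
    """Read variants from a VCF via pysam.

    Expects INFO keys DP (depth), AD or AO (alt depth), FS, QD, and the
    annotation keys GENE, EFFECT, REGION, POP_MAF when present. For
    multi-sample VCFs the record is attributed to ``sample_id`` (required
    then); single-sample VCFs may omit it.
    """
    import pysam  # deferred: only the VCF route needs it

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        sid = sample_id or (samples[0] if samples else "sample")
        for rec in vcf:
            info = rec.info
            alt = rec.alts[0] if rec.alts else "."
            out.append(
                SomaticVariant(
                    sample_id=sid,
                    gene=str(info.get("GENE", ".")),
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref or ".",
                    alt=alt,
                    total_depth=info.get("DP"),
                    alt_depth=info.get("AD") if not isinstance(info.get("AD"), tuple)
                    else info.get("AD")[0],
                    effect=info.get("EFFECT"),
                    region=info.get("REGION"),
                    fs=info.get("FS"),
                    qd=info.get("QD"),
                    pop_maf=info.get("POP_MAF"),
                )
            )
    return out


# ----------------------------------------------------------------- expression

def read_expression(
    path: PathLike,
    class_path: Optional[PathLike] = None,
) -> ExpressionMatrix:
    """Read a gene x sample FPKM matrix (first column ``gene``).

    Sample classes come from a two-column TSV (sample, class) when
    ``class_path`` is given; otherwise samples whose id ends in ``_N`` are
    classed normal (and paired with the same-prefix tumour), the rest tumour.
    """
    df = pd.read_csv(path, sep="\t", index_col="gene")
    if df.isna().any().any():
        raise FileFormatError(f"{path}: expression matrix contains missing values")
    if class_path is not None:
        cls_df = pd.read_csv(class_path, sep="\t")
        sample_class = dict(zip(cls_df["sample"], cls_df["class"]))
    else:
        sample_class = {
            c: ("normal" if c.endswith("_N") else "tumour") for c in df.columns
        }
    pairing = {}
    for c in df.columns:
        if sample_class.get(c) == "tumour" and f"{c}_N" in df.columns:
            pairing[c] = f"{c}_N"
    try:
        return ExpressionMatrix(values=df, sample_class=sample_class,
                                pairing=pairing or None)
    except ValidationError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


def write_expression(expr: ExpressionMatrix, path: PathLike) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


# ------------------------------------------------------------------- clinical

def _parse_bool(token: str) -> bool:
    token = token.strip().lower()
    if token in ("1", "true", "yes"):
        return True
    if token in ("0", "false", "no"):
        return False
    raise ValueError(f"expected a boolean, got {token!r}")


def read_clinical(path: PathLike, on_error: str = "raise"):
    def parse(row) -> ClinicalRecord:
        return ClinicalRecord(
            sample_id=row["sample"],
            age=float(row["age"]),
            size_cm=float(row["size_cm"]),
            sex=row["sex"],
            location=row["location"],
            histology=row["histology"],
            invasion_depth=row["invasion_depth"],
            perineural=_parse_bool(row["perineural"]),
            lymphovascular=_parse_bool(row["lymphovascular"]),
            lymph_node=_parse_bool(row["lymph_node"]),
            msi_status=row["msi_status"],
            os_months=float(row["os_months"]),
            os_event=_parse_bool(row["os_event"]),
        )

    return _collecting_reader(path, CLINICAL_COLUMNS, parse, on_error)


def write_clinical(records: Sequence[ClinicalRecord], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CLINICAL_COLUMNS)
        for r in records:
            w.writerow([
                r.sample_id, r.age, r.size_cm, r.sex, r.location, r.histology,
                r.invasion_depth, int(r.perineural), int(r.lymphovascular),
                int(r.lymph_node), r.msi_status, r.os_months, int(r.os_event),
            ])
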