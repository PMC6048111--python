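"""Synthetic cohort generator.

Builds a complete, internally consistent bundle of pipeline inputs — toy
genome and transcript models, three callers' fusion-call tables, normal
tissue calls, an FPKM expression matrix, somatic-variant tables, gene
function/panel annotations and clinical records — with the statistical
structure the analysis assumes:

* planted fusions are detected independently by each caller (Bernoulli
  sensitivity) with Gaussian breakpoint jitter, exercising the
  breakpoint-tolerant 2-of-3 consensus logic;
* read-through artifacts are adjacent-gene calls closer than 100 kb, so the
  intrachromosomal distance filter has real work to do; further artifact
  flavours violate the spanning-read, frame and not-in-normal filters;
* carriers of expression-driven fusions have the acceptor (sometimes also
  donor) gene at ``outlier_multiplier`` x the gene's cohort median FPKM;
* oncogene-panel mutations are depleted in fusion carriers
  (``exclusivity_strength`` vs ``background_mutation_rate``), planting the
  mutual-exclusivity signal;
* MSI-H status is enriched in carriers by an odds multiplier, and carriers
  have smaller tumours by ``size_effect_cm``.

A fixed seed makes the whole bundle byte-identical across runs. The
ground-truth manifest records every planted fusion with its expected fate
at each pipeline stage, enabling stage-wise recovery metrics
(:func:`ground_truth_compare`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as fio
from .model import (
    ClinicalRecord,
    ExpressionMatrix,
    FusionCall,
    GeneFunctionAnnotation,
    GenomicBreakpoint,
    ProteinDomain,
    SomaticVariant,
    TranscriptModel,
    ValidationError,
)
from .proteins import cds_to_genomic

CALLERS = ("caller1", "caller2", "caller3")  # caller1 is the primary screen

FUSION_TYPES = ("kinase_acceptor", "suppressor_truncation", "outlier_only", "passenger")
TYPE_WEIGHTS = (0.3, 0.2, 0.3, 0.2)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the cohort the pipeline is designed for: 147 tumours
    with 47 matched normals, ~25 true fusions concentrated in ~19 carriers,
    70% of junctions in frame, spanning-read support well above the
    screening threshold, 10-fold expression activation of driven partner
    genes, strong fusion/oncogene-mutation exclusivity (5% vs 40% mutation
    probability) and 3.5-fold MSI-H odds enrichment in carriers.
    """

    seed: int = 0
    n_patients: int = 147
    n_normals: int = 47
    n_genes: int = 60
    n_true_fusions: int = 25
    caller_sensitivity: tuple[float, float, float] = (0.95, 0.85, 0.85)
    breakpoint_jitter_sd: float = 5.0
    artifact_rate: float = 1.0  # false calls per tumour sample (Poisson mean)
    frac_in_frame: float = 0.7
    spanning_mean: float = 60.0
    spanning_shape: float = 8.0
    outlier_multiplier: float = 10.0
    expression_sigma: float = 0.8  # lognormal spread of FPKM around gene median
    donor_boost_prob: float = 0.3
    exclusivity_strength: float = 0.05  # oncogene mutation prob in carriers
    background_mutation_rate: float = 0.4  # ... and in non-carriers
    suppressor_mutation_rate: float = 0.5
    junk_variant_rate: float = 3.0  # filter-violating variants per patient
    msi_base_rate: float = 0.10
    msi_enrichment: float = 3.5  # odds multiplier for MSI-H in carriers
    size_effect_cm: float = 1.0
    survival_mean_months: float = 180.0
    survival_hr_carriers: float = 1.0
    censor_low: float = 60.0
    censor_high: float = 130.0
    single_caller_fusions: int = 0  # first k planted fusions seen by caller1 only

    def __post_init__(self) -> None:
        probs = (
            *self.caller_sensitivity, self.frac_in_frame, self.donor_boost_prob,
            self.exclusivity_strength, self.background_mutation_rate,
            self.suppressor_mutation_rate, self.msi_base_rate,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValidationError("probabilities must be in [0,1]")
        if min(self.n_patients, self.n_genes, self.n_true_fusions) < 1:
            raise ValidationError("counts must be positive")
        if self.n_normals > self.n_patients:
            raise ValidationError("n_normals cannot exceed n_patients")
        if not (0 <= self.single_caller_fusions <= self.n_true_fusions):
            raise ValidationError("single_caller_fusions out of range")

    @property
    def bundle_id(self) -> str:
        payload = repr(dataclasses.astuple(self)).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def noiseless(config: SimConfig = SimConfig()) -> SimConfig:
    """The deterministic limit of a configuration: perfect callers, no
    artifacts, no breakpoint jitter, no expression spread."""
    return dataclasses.replace(
        config,
        caller_sensitivity=(1.0, 1.0, 1.0),
        breakpoint_jitter_sd=0.0,
        artifact_rate=0.0,
        expression_sigma=0.0,
        junk_variant_rate=0.0,
    )


@dataclass
class PlantedFusion:
    """Ground truth for one planted fusion event."""

    sample_id: str
    donor_gene: str
    acceptor_gene: str
    fusion_type: str
    in_frame: bool
    donor_phase: int
    acceptor_phase: int
    bp_donor: GenomicBreakpoint
    bp_acceptor: GenomicBreakpoint
    spanning: int
    detected_by: tuple[str, ...]
    boost_donor: bool
    boost_acceptor: bool

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.sample_id, self.donor_gene, self.acceptor_gene)

    @property
    def oncogenic_truth(self) -> bool:
        return self.in_frame and self.fusion_type != "passenger"

    def expected_fate(self, min_spanning: int = 10, min_distance: int = 100_000):
        mid = (
            abs(self.bp_donor.pos - self.bp_acceptor.pos)
            if self.bp_donor.chrom == self.bp_acceptor.chrom
            else None
        )
        screen = (
            bool(self.detected_by)
            and self.in_frame
            and self.spanning >= min_spanning
            and (mid is None or mid >= min_distance)
        )
        validated = screen and len(self.detected_by) >= 2
        return {
            "screen_pass": screen,
            "validated": validated,
            "oncogenic_called": validated and self.oncogenic_truth,
        }


@dataclass
class SyntheticCohort:
    """In-memory bundle of everything the generator planted."""

    config: SimConfig
    transcripts: list[TranscriptModel]
    domains: list[ProteinDomain]
    functions: list[GeneFunctionAnnotation]
    panels: dict[str, str]
    calls: dict[str, list[FusionCall]]  # caller -> tumour-sample calls
    normal_calls: list[FusionCall]
    expression: ExpressionMatrix
    variants: list[SomaticVariant]
    normal_variants: list[SomaticVariant]
    clinical: list[ClinicalRecord]
    fusions: list[PlantedFusion]
    mutation_truth: dict[str, dict[str, bool]]  # patient -> panel -> mutated

    @property
    def tumour_samples(self) -> list[str]:
        return [r.sample_id for r in self.clinical]

    @property
    def carriers(self) -> list[str]:
        return sorted({f.sample_id for f in self.fusions})

    def manifest(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        return {
            "bundle_id": self.config.bundle_id,
            "seed": self.config.seed,
            "config": cfg,
            "fusions": [
                {
                    "sample": f.sample_id,
                    "donor": f.donor_gene,
                    "acceptor": f.acceptor_gene,
                    "type": f.fusion_type,
                    "in_frame": f.in_frame,
                    "phases": [f.donor_phase, f.acceptor_phase],
                    "bp_donor": [f.bp_donor.chrom, f.bp_donor.pos, f.bp_donor.strand],
                    "bp_acceptor": [
                        f.bp_acceptor.chrom, f.bp_acceptor.pos, f.bp_acceptor.strand
                    ],
                    "spanning": f.spanning,
                    "detected_by": list(f.detected_by),
                    "oncogenic": f.oncogenic_truth,
                    "boost_donor": f.boost_donor,
                    "boost_acceptor": f.boost_acceptor,
                    **f.expected_fate(),
                }
                for f in self.fusions
            ],
            "carriers": self.carriers,
            "mutation_truth": self.mutation_truth,
        }


# --------------------------------------------------------------- toy genome

def _build_genome(rng: np.random.Generator, n_genes: int):
    """Lay ~3 genes per synthetic chromosome with 10-50 kb intergenic gaps;
    returns (transcripts, adjacent same-chromosome gene-name pairs)."""
    transcripts: list[TranscriptModel] = []
    adjacent: list[tuple[str, str]] = []
    genes_per_chrom = 3
    gi = 0
    chrom_idx = 0
    while gi < n_genes:
        chrom_idx += 1
        chrom = f"chrS{chrom_idx}"
        cursor = 10_000 + int(rng.integers(0, 5_000))
        prev_gene = None
        for _ in range(genes_per_chrom):
            if gi >= n_genes:
                break
            gene = f"SG{gi + 1:03d}"
            n_ex = int(rng.integers(3, 9))
            exon_lens = rng.integers(120, 301, size=n_ex)
            intron_lens = rng.integers(500, 5_001, size=max(n_ex - 1, 1))
            exons = []
            pos = cursor
            for k in range(n_ex):
                exons.append((pos, pos + int(exon_lens[k]) - 1))
                if k < n_ex - 1:
                    pos = exons[-1][1] + 1 + int(intron_lens[k])
            cds_start = exons[0][0] + int(rng.integers(10, 60))
            cds_end = exons[-1][1] - int(rng.integers(10, 60))
            length = sum(
                max(0, min(e, cds_end) - max(s, cds_start) + 1) for s, e in exons
            )
            cds_end -= length % 3
            strand = "+" if rng.random() < 0.5 else "-"
            transcripts.append(
                TranscriptModel(
                    gene=gene,
                    transcript_id=f"{gene}.t1",
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(exons),
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
            if prev_gene is not None:
                adjacent.append((prev_gene, gene))
            prev_gene = gene
            cursor = exons[-1][1] + int(rng.integers(10_000, 50_001))
            gi += 1
    return transcripts, adjacent


def _assign_roles(rng: np.random.Generator, gene_names: Sequence[str]):
    """Disjoint gene pools: mutation panels, kinase acceptors, suppressor
    donors; the rest unannotated."""
    order = list(rng.permutation(np.array(gene_names, dtype=object)))
    n = len(order)
    n_panel = min(8, max(2, n // 8))
    n_kin = min(6, max(2, n // 10))
    n_sup = min(4, max(1, n // 15))
    onc_panel = order[:n_panel]
    sup_panel = order[n_panel:2 * n_panel]
    kinases = order[2 * n_panel:2 * n_panel + n_kin]
    suppressors = order[2 * n_panel + n_kin:2 * n_panel + n_kin + n_sup]
    plain = order[2 * n_panel + n_kin + n_sup:]
    return onc_panel, sup_panel, kinases, suppressors, plain


# ----------------------------------------------------------------- planting

def _pick_phase_offset(
    rng: np.random.Generator, cds_len: int, target_phase: Optional[int], lo: int, hi: int
) -> int:
    """A CDS offset in [lo, hi) congruent to target_phase mod 3 (or any)."""
    base = int(rng.integers(lo, max(hi, lo + 3)))
    if target_phase is None:
        return min(base, cds_len - 4)
    off = base + (target_phase - base) % 3
    return min(off, cds_len - 4)


def _plant_fusions(
    rng: np.random.Generator,
    config: SimConfig,
    tx_by_gene: dict[str, TranscriptModel],
    kinases: Sequence[str],
    suppressors: Sequence[str],
    plain: Sequence[str],
    carriers: Sequence[str],
) -> list[PlantedFusion]:
    n = config.n_true_fusions
    counts = np.floor(np.asarray(TYPE_WEIGHTS) * n).astype(int)
    while counts.sum() < n:
        counts[int(rng.integers(0, len(counts)))] += 1
    types = [t for t, c in zip(FUSION_TYPES, counts) for _ in range(c)]
    types = list(rng.permutation(np.array(types, dtype=object)))

    used_keys: set[tuple] = set()
    fusions: list[PlantedFusion] = []
    for i, ftype in enumerate(types):
        # each carrier gets one fusion first; extras land on random carriers
        sample = (
            carriers[i] if i < len(carriers)
            else carriers[int(rng.integers(0, len(carriers)))]
        )
        for _attempt in range(40):
            if ftype == "kinase_acceptor":
                donor = str(rng.choice(np.array(plain, dtype=object)))
                acceptor = str(rng.choice(np.array(kinases, dtype=object)))
            elif ftype == "suppressor_truncation":
                donor = str(rng.choice(np.array(suppressors, dtype=object)))
                acceptor = str(rng.choice(np.array(plain, dtype=object)))
            else:
                donor, acceptor = (
                    str(g) for g in rng.choice(np.array(plain, dtype=object), 2, replace=False)
                )
            if donor == acceptor or (sample, donor, acceptor) in used_keys:
                continue
            dtx, atx = tx_by_gene[donor], tx_by_gene[acceptor]
            if dtx.chrom == atx.chrom:
                # avoid read-through-like placements; require a far pair
                if abs(dtx.cds_start - atx.cds_start) < 300_000:
                    continue
            break
        else:  # pragma: no cover - generator config too tight
            raise ValidationError("could not place a fusion pair; increase n_genes")
        used_keys.add((sample, donor, acceptor))

        in_frame = bool(rng.random() < config.frac_in_frame)
        if ftype == "suppressor_truncation":
            # breakpoint near mid-protein so downstream suppressor domains drop
            ld = max(30, (dtx.cds_length // 2) - int(rng.integers(0, 30)))
        else:
            ld = int(rng.integers(30, max(int(dtx.cds_length * 0.6), 33)))
        donor_phase = ld % 3
        if in_frame:
            target = donor_phase
        else:
            target = (donor_phase + 1 + int(rng.integers(0, 2))) % 3
        da = _pick_phase_offset(
            rng, atx.cds_length, target, 3, max(int(atx.cds_length * 0.4), 6)
        )
        acceptor_phase = da % 3

        bp_d = GenomicBreakpoint(dtx.chrom, cds_to_genomic(dtx, ld - 1), dtx.strand)
        bp_a = GenomicBreakpoint(atx.chrom, cds_to_genomic(atx, da), atx.strand)

        spanning = int(
            rng.negative_binomial(
                config.spanning_shape,
                config.spanning_shape / (config.spanning_shape + config.spanning_mean),
            )
        )
        spanning = max(spanning, 1)

        if i < config.single_caller_fusions:
            detected = (CALLERS[0],)
        else:
            detected = tuple(
                c for c, s in zip(CALLERS, config.caller_sensitivity)
                if rng.random() < s
            )

        boost_acceptor = ftype in ("kinase_acceptor", "outlier_only")
        boost_donor = boost_acceptor and rng.random() < config.donor_boost_prob

        fusions.append(
            PlantedFusion(
                sample_id=sample,
                donor_gene=donor,
                acceptor_gene=acceptor,
                fusion_type=str(ftype),
                in_frame=in_frame,
                donor_phase=donor_phase,
                acceptor_phase=acceptor_phase,
                bp_donor=bp_d,
                bp_acceptor=bp_a,
                spanning=spanning,
                detected_by=detected,
                boost_donor=boost_donor,
                boost_acceptor=boost_acceptor,
            )
        )
    return fusions


def _jitter(rng: np.random.Generator, bp: GenomicBreakpoint, sd: float) -> GenomicBreakpoint:
    if sd <= 0:
        return bp
    shift = int(round(rng.normal(0.0, sd)))
    return GenomicBreakpoint(bp.chrom, max(1, bp.pos + shift), bp.strand)


def _random_exonic_bp(
    rng: np.random.Generator, tx: TranscriptModel, near: Optional[str] = None
) -> GenomicBreakpoint:
    """A coding-region breakpoint; ``near`` = 'start'/'end' biases toward the
    genomic CDS boundary (used for read-through pairs)."""
    if near == "end":
        off = tx.cds_length - 1 - int(rng.integers(0, min(60, tx.cds_length - 1)))
    elif near == "start":
        off = int(rng.integers(0, min(60, tx.cds_length - 1)))
    else:
        off = int(rng.integers(3, tx.cds_length - 3))
    pos = cds_to_genomic(tx, off)
    return GenomicBreakpoint(tx.chrom, pos, tx.strand)


def _frame_pair(rng: np.random.Generator, in_frame: bool) -> tuple[int, int]:
    d = int(rng.integers(0, 3))
    if in_frame:
        return (d, d)
    return (d, (d + 1 + int(rng.integers(0, 2))) % 3)


def _artifact_calls(
    rng: np.random.Generator,
    config: SimConfig,
    tx_by_gene: dict[str, TranscriptModel],
    adjacent: Sequence[tuple[str, str]],
    plain: Sequence[str],
    tumour_samples: Sequence[str],
    planted_keys: set[tuple],
    normal_pairs: Sequence[tuple[str, str]],
) -> dict[str, list[FusionCall]]:
    """Per-caller artifact calls: read-throughs (< 100 kb), low-spanning,
    out-of-frame, and seen-in-normal gene pairs."""
    out: dict[str, list[FusionCall]] = {c: [] for c in CALLERS}
    kinds = ("readthrough", "low_spanning", "out_of_frame", "in_normal")
    for sample in tumour_samples:
        for _ in range(int(rng.poisson(config.artifact_rate))):
            kind = kinds[int(rng.integers(0, len(kinds)))]
            for _attempt in range(20):
                if kind == "readthrough" and adjacent:
                    donor, acceptor = adjacent[int(rng.integers(0, len(adjacent)))]
                    bp_d = _random_exonic_bp(rng, tx_by_gene[donor], near="end")
                    bp_a = _random_exonic_bp(rng, tx_by_gene[acceptor], near="start")
                    spanning = max(1, int(rng.poisson(25)))
                    frame = _frame_pair(rng, True)
                elif kind == "in_normal" and normal_pairs:
                    donor, acceptor = normal_pairs[int(rng.integers(0, len(normal_pairs)))]
                    bp_d = _random_exonic_bp(rng, tx_by_gene[donor])
                    bp_a = _random_exonic_bp(rng, tx_by_gene[acceptor])
                    spanning = max(1, int(rng.poisson(25)))
                    frame = _frame_pair(rng, True)
                else:
                    donor, acceptor = (
                        str(g)
                        for g in rng.choice(np.array(plain, dtype=object), 2, replace=False)
                    )
                    if tx_by_gene[donor].chrom == tx_by_gene[acceptor].chrom:
                        continue
                    bp_d = _random_exonic_bp(rng, tx_by_gene[donor])
                    bp_a = _random_exonic_bp(rng, tx_by_gene[acceptor])
                    if kind == "low_spanning":
                        spanning = int(rng.integers(1, 10))
                        frame = _frame_pair(rng, True)
                    else:
                        spanning = max(1, int(rng.poisson(25)))
                        frame = _frame_pair(rng, False)
                if (sample, donor, acceptor) not in planted_keys:
                    break
            else:
                continue
            caller = CALLERS[int(rng.integers(0, len(CALLERS)))]
            out[caller].append(
                FusionCall(
                    sample_id=sample,
                    caller_id=caller,
                    donor_gene=donor,
                    acceptor_gene=acceptor,
                    bp_donor=bp_d,
                    bp_acceptor=bp_a,
                    spanning_reads=spanning,
                    frame_shift=frame,
                )
            )
    return out


# -------------------------------------------------------------- main entry

def simulate(config: SimConfig = SimConfig()) -> SyntheticCohort:
    """Generate the full synthetic cohort in memory (deterministic in
    ``config.seed``)."""
    rng = np.random.default_rng(config.seed)

    transcripts, adjacent = _build_genome(rng, config.n_genes)
    tx_by_gene = {t.gene: t for t in transcripts}
    gene_names = [t.gene for t in transcripts]
    onc_panel, sup_panel, kinases, suppressors, plain = _assign_roles(rng, gene_names)

    panels = {g: "oncogene" for g in onc_panel}
    panels.update({g: "suppressor" for g in sup_panel})

    functions = (
        [GeneFunctionAnnotation(g, frozenset({"kinase", "oncogene"})) for g in kinases]
        + [GeneFunctionAnnotation(g, frozenset({"suppressor"})) for g in suppressors]
    )

    # domains: retained kinase domains downstream, suppressor domains around
    # and beyond the mid-protein breakpoint, occasional decoys elsewhere
    domains: list[ProteinDomain] = []
    for g in kinases:
        p = tx_by_gene[g].protein_length
        domains.append(ProteinDomain(g, "PK", max(p // 2, 2), max(p - 5, p // 2 + 1)))
    for g in suppressors:
        p = tx_by_gene[g].protein_length
        domains.append(ProteinDomain(g, "SUP", 1, max(int(p * 0.55), 2)))
        domains.append(ProteinDomain(g, "C2", min(int(p * 0.7), p - 2), p - 1))
    for g in plain:
        if rng.random() < 0.5:
            p = tx_by_gene[g].protein_length
            s = int(rng.integers(1, max(p - 20, 2)))
            domains.append(ProteinDomain(g, "DOM", s, min(s + 40, p)))

    tumour_samples = [f"S{i + 1:03d}" for i in range(config.n_patients)]
    normal_samples = [f"{s}_N" for s in tumour_samples[: config.n_normals]]

    n_carriers = max(1, int(round(config.n_true_fusions * 0.78)))
    n_carriers = min(n_carriers, config.n_patients)
    carriers = sorted(
        str(s) for s in rng.choice(np.array(tumour_samples, dtype=object),
                                   n_carriers, replace=False)
    )

    fusions = _plant_fusions(rng, config, tx_by_gene, kinases, suppressors, plain, carriers)
    planted_keys = {f.key for f in fusions}
    planted_pairs = {(f.donor_gene, f.acceptor_gene) for f in fusions}

    # gene pairs that also occur in normal tissue (germline/read-through echo)
    normal_pair_pool = [
        (a, b) for a, b in zip(plain[::2], plain[1::2])
        if a != b and (a, b) not in planted_pairs
    ]
    normal_pairs = normal_pair_pool[:2]

    # --- caller tables -------------------------------------------------
    calls: dict[str, list[FusionCall]] = {c: [] for c in CALLERS}
    for f in fusions:
        for caller in f.detected_by:
            calls[caller].append(
                FusionCall(
                    sample_id=f.sample_id,
                    caller_id=caller,
                    donor_gene=f.donor_gene,
                    acceptor_gene=f.acceptor_gene,
                    bp_donor=_jitter(rng, f.bp_donor, config.breakpoint_jitter_sd),
                    bp_acceptor=_jitter(rng, f.bp_acceptor, config.breakpoint_jitter_sd),
                    spanning_reads=f.spanning,
                    frame_shift=(f.donor_phase, f.acceptor_phase),
                )
            )
    artifacts = _artifact_calls(
        rng, config, tx_by_gene, adjacent, plain, tumour_samples,
        planted_keys, normal_pairs,
    )
    for caller in CALLERS:
        calls[caller].extend(artifacts[caller])

    normal_calls: list[FusionCall] = []
    for j, (donor, acceptor) in enumerate(normal_pairs):
        sample = normal_samples[j % len(normal_samples)] if normal_samples else "N001"
        normal_calls.append(
            FusionCall(
                sample_id=sample,
                caller_id=CALLERS[0],
                donor_gene=donor,
                acceptor_gene=acceptor,
                bp_donor=_random_exonic_bp(rng, tx_by_gene[donor]),
                bp_acceptor=_random_exonic_bp(rng, tx_by_gene[acceptor]),
                spanning_reads=max(1, int(rng.poisson(15))),
                frame_shift=_frame_pair(rng, True),
            )
        )

    # --- expression ----------------------------------------------------
    all_samples = tumour_samples + normal_samples
    medians = np.exp(rng.normal(1.0, 1.0, size=len(gene_names)))
    values = medians[:, None] * np.exp(
        rng.normal(0.0, config.expression_sigma, size=(len(gene_names), len(all_samples)))
    )
    expr_df = pd.DataFrame(values, index=gene_names, columns=all_samples)
    gene_median = dict(zip(gene_names, medians))
    for f in fusions:
        if f.boost_acceptor:
            expr_df.at[f.acceptor_gene, f.sample_id] = (
                config.outlier_multiplier * gene_median[f.acceptor_gene]
            )
        if f.boost_donor:
            expr_df.at[f.donor_gene, f.sample_id] = (
                config.outlier_multiplier * gene_median[f.donor_gene]
            )
    expression = ExpressionMatrix(
        values=expr_df,
        sample_class={
            s: ("normal" if s.endswith("_N") else "tumour") for s in all_samples
        },
        pairing={s: f"{s}_N" for s in tumour_samples[: config.n_normals]},
    )

    # --- somatic variants ----------------------------------------------
    carrier_set = set(carriers)
    variants: list[SomaticVariant] = []
    normal_variants: list[SomaticVariant] = []
    mutation_truth: dict[str, dict[str, bool]] = {}

    def clean_variant(sample: str, gene: str) -> SomaticVariant:
        tx = tx_by_gene[gene]
        depth = 10 + int(rng.poisson(70))
        alt = max(int(rng.binomial(depth, 0.35)), max(2, int(np.ceil(0.03 * depth))))
        alt = min(alt, depth)
        return SomaticVariant(
            sample_id=sample, gene=gene, chrom=tx.chrom,
            pos=int(rng.integers(tx.cds_start, tx.cds_end + 1)),
            ref="A", alt="T",
            total_depth=depth, alt_depth=alt,
            effect=str(rng.choice(
                np.array(["non-synonymous", "frameshift", "stop-gain"], dtype=object),
                p=[0.8, 0.1, 0.1],
            )),
            region="exon",
            fs=float(np.round(rng.uniform(0.0, 20.0), 3)),
            qd=float(np.round(rng.uniform(3.0, 30.0), 3)),
            pop_maf=0.0,
        )

    junk_makers = (
        lambda s, g, tx: dataclasses.replace(clean_variant(s, g), total_depth=5, alt_depth=2),
        lambda s, g, tx: dataclasses.replace(clean_variant(s, g), alt_depth=1),
        lambda s, g, tx: dataclasses.replace(
            clean_variant(s, g), total_depth=200, alt_depth=2),  # VAF 1%
        lambda s, g, tx: dataclasses.replace(clean_variant(s, g), region="intron"),
        lambda s, g, tx: dataclasses.replace(clean_variant(s, g), effect="other"),
        lambda s, g, tx: dataclasses.replace(clean_variant(s, g), pop_maf=0.05),
        lambda s, g, tx: dataclasses.replace(clean_variant(s, g), fs=45.0),
        lambda s, g, tx: dataclasses.replace(clean_variant(s, g), qd=1.0),
    )

    for sample in tumour_samples:
        is_carrier = sample in carrier_set
        onc_p = config.exclusivity_strength if is_carrier else config.background_mutation_rate
        onc_mut = bool(rng.random() < onc_p)
        sup_mut = bool(rng.random() < config.suppressor_mutation_rate)
        mutation_truth[sample] = {"oncogene": onc_mut, "suppressor": sup_mut}
        if onc_mut and len(onc_panel):
            for g in rng.choice(np.array(onc_panel, dtype=object),
                                int(rng.integers(1, 3)), replace=False):
                variants.append(clean_variant(sample, str(g)))
        if sup_mut and len(sup_panel):
            for g in rng.choice(np.array(sup_panel, dtype=object),
                                int(rng.integers(1, 3)), replace=False):
                variants.append(clean_variant(sample, str(g)))
        for _ in range(int(rng.poisson(config.junk_variant_rate))):
            gene = str(rng.choice(np.array(gene_names, dtype=object)))
            maker = junk_makers[int(rng.integers(0, len(junk_makers)))]
            variants.append(maker(sample, gene, tx_by_gene[gene]))

    # a germline echo: sites shared with matched normals get filtered out
    shared = [v for v in variants if v.region == "intron"][:4]
    for v in shared:
        normal_variants.append(
            dataclasses.replace(v, sample_id=f"{v.sample_id}_N", region="exon")
        )

    # --- clinical -------------------------------------------------------
    msi_odds = config.msi_base_rate / (1.0 - config.msi_base_rate)
    msi_p_carrier = (msi_odds * config.msi_enrichment) / (
        1.0 + msi_odds * config.msi_enrichment
    )
    clinical: list[ClinicalRecord] = []
    for sample in tumour_samples:
        is_carrier = sample in carrier_set
        msi_h = rng.random() < (msi_p_carrier if is_carrier else config.msi_base_rate)
        msi = "MSI-H" if msi_h else ("MSS" if rng.random() < 0.9 else "MSI-L")
        size = rng.normal(5.8, 2.2) - (config.size_effect_cm if is_carrier else 0.0)
        hazard = (1.0 / config.survival_mean_months) * (
            config.survival_hr_carriers if is_carrier else 1.0
        )
        event_t = rng.exponential(1.0 / hazard)
        censor_t = rng.uniform(config.censor_low, config.censor_high)
        clinical.append(
            ClinicalRecord(
                sample_id=sample,
                age=float(np.round(np.clip(rng.normal(60.0, 12.0), 25.0, 92.0), 1)),
                size_cm=float(np.round(max(size, 0.5), 1)),
                sex="male" if rng.random() < 0.52 else "female",
                location="right" if rng.random() < 0.38 else "left",
                histology=str(rng.choice(
                    np.array(["well", "moderately", "poorly", "mucinous"], dtype=object),
                    p=[0.18, 0.74, 0.06, 0.02],
                )),
                invasion_depth=str(rng.choice(
                    np.array(["T1", "T2", "T3", "T4"], dtype=object),
                    p=[0.01, 0.11, 0.73, 0.15],
                )),
                perineural=bool(rng.random() < 0.40),
                lymphovascular=bool(rng.random() < 0.21),
                lymph_node=bool(rng.random() < 0.51),
                msi_status=msi,
                os_months=float(np.round(min(event_t, censor_t), 1)),
                os_event=bool(event_t <= censor_t),
            )
        )

    return SyntheticCohort(
        config=config,
        transcripts=transcripts,
        domains=domains,
        functions=functions,
        panels=panels,
        calls=calls,
        normal_calls=normal_calls,
        expression=expression,
        variants=variants,
        normal_variants=normal_variants,
        clinical=clinical,
        fusions=fusions,
        mutation_truth=mutation_truth,
    )


def generate(config: SimConfig, out_dir) -> dict[str, Path]:
    """Write the complete input bundle plus the ground-truth manifest to
    ``out_dir``; identical seeds produce byte-identical bundles."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate(config)

    paths: dict[str, Path] = {}

    def record(name: str, filename: str) -> Path:
        paths[name] = out / filename
        return paths[name]

    for caller in CALLERS:
        fio.write_fusion_calls(cohort.calls[caller], record(f"calls_{caller}", f"calls_{caller}.tsv"))
    fio.write_fusion_calls(cohort.normal_calls, record("normal_calls", "normal_calls.tsv"))
    fio.write_transcripts(cohort.transcripts, record("transcripts", "transcripts.gtf"))
    fio.write_domains(cohort.domains, record("domains", "domains.tsv"))
    fio.write_gene_functions(cohort.functions, record("gene_functions", "gene_functions.tsv"))
    with open(record("panels", "panels.tsv"), "w") as fh:
        fh.write("gene\tpanel\n")
        for gene in sorted(cohort.panels):
            fh.write(f"{gene}\t{cohort.panels[gene]}\n")
    fio.write_expression(cohort.expression, record("expression", "expression.tsv"))
    fio.write_variants(cohort.variants, record("variants", "variants.tsv"))
    fio.write_variants(cohort.normal_variants, record("normal_variants", "normal_variants.tsv"))
    fio.write_clinical(cohort.clinical, record("clinical", "clinical.tsv"))
    with open(record("manifest", "manifest.json"), "w") as fh:
        json.dump(cohort.manifest(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


# ------------------------------------------------------------ truth recovery

@dataclass
class StageRecovery:
    tp: int
    fn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 1.0

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else 1.0


@dataclass
class RecoveryMetrics:
    """Stage-wise confusion counts of pipeline output against the planted
    manifest, plus overall recovery of true oncogenic fusions."""

    stages: dict[str, StageRecovery]
    oncogenic_recovery: float  # sensitivity vs biological truth labels


def _stage(expected: set, observed: set) -> StageRecovery:
    return StageRecovery(
        tp=len(expected & observed),
        fn=len(expected - observed),
        fp=len(observed - expected),
    )


def ground_truth_compare(result, manifest: dict) -> RecoveryMetrics:
    """Compare a pipeline run against the generator manifest.

    ``result`` is a :class:`fusionsieve.pipeline.PipelineResult` from the
    same bundle; mismatched bundles are refused (the manifest's bundle id
    must match the one the pipeline recorded).
    """
    if getattr(result, "bundle_id", None) is not None:
        if result.bundle_id != manifest.get("bundle_id"):
            raise ValidationError(
                "pipeline result and manifest come from different bundles"
            )

    def key(f: dict) -> tuple:
        return (f["sample"], f["donor"], f["acceptor"])

    fus = manifest["fusions"]
    expected_screen = {key(f) for f in fus if f["screen_pass"]}
    expected_validated = {key(f) for f in fus if f["validated"]}
    expected_oncogenic = {key(f) for f in fus if f["oncogenic_called"]}
    truth_oncogenic = {key(f) for f in fus if f["oncogenic"]}

    observed_screen = {c.key for c in result.screen.survivors}
    observed_validated = {g.key for g in result.validated}
    observed_oncogenic = {
        c.key for c in result.classifications if c.oncogenic
    }

    stages = {
        "screen": _stage(expected_screen, observed_screen),
        "consensus": _stage(expected_validated, observed_validated),
        "oncogenic": _stage(expected_oncogenic, observed_oncogenic),
    }
    onc_recovery = (
        len(truth_oncogenic & observed_oncogenic) / len(truth_oncogenic)
        if truth_oncogenic else 1.0
    )
    return RecoveryMetrics(stages=stages, oncogenic_recovery=onc_recovery)
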