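"""End-to-end orchestration: screen -> consensus -> protein/domains ->
expression outliers -> oncogenicity -> mutation exclusivity -> clinical
statistics, with a funnel summary and reproducible reports.

The pipeline consumes the file bundle formats of :mod:`fusionsieve.io`
(natively produced by :mod:`fusionsieve.simulate`) and emits, when an
output directory is given: the per-stage funnel counts, a fusion report
mirroring the classic characterisation-table layout (one row per validated
fusion with phases, mid distance, support, expression label, function and
verdict), the binary mutation matrix, the clinical association table, and
a machine-readable run log holding every threshold and the seed — enough
to repeat the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io as fio
from .consensus import ConsensusGroup, cross_validate, group_calls
from .exclusivity import (
    ExclusivityResult,
    MutationMatrix,
    SnvFilterConfig,
    SnvFilterResult,
    build_matrix,
    exclusivity_test,
    filter_snvs,
)
from .model import FusionClassification, ValidationError
from .oncogenicity import DEFAULT_TRUNCATION_THRESHOLD, call_oncogenic
from .outliers import OutlierConfig, outlier_flag
from .proteins import FusionProtein, build_fusion_protein, junction_phases
from .screen import ScreenConfig, ScreenResult, apply_screen


@dataclass(frozen=True)
class RunConfig:
    """Paths plus every stage's tunables for one pipeline run."""

    bundle_dir: str
    out_dir: Optional[str] = None
    callers: tuple[str, ...] = ("caller1", "caller2", "caller3")
    screen: ScreenConfig = ScreenConfig()
    consensus_tolerance: int = 50
    min_support: int = 2
    outlier: OutlierConfig = OutlierConfig()
    snv_filter: SnvFilterConfig = SnvFilterConfig()
    truncation_threshold: float = DEFAULT_TRUNCATION_THRESHOLD
    oncogenicity_rule: str = "disjunctive"
    n_perm: int = 10_000
    seed: int = 0

    def input_path(self, name: str) -> Path:
        return Path(self.bundle_dir) / name


@dataclass
class PipelineResult:
    config: RunConfig
    screen: ScreenResult
    groups: list[ConsensusGroup]
    validated: list[ConsensusGroup]
    classifications: list[FusionClassification]
    fusion_proteins: dict[tuple, FusionProtein]
    snv_result: Optional[SnvFilterResult]
    mutation_matrix: Optional[MutationMatrix]
    fusion_vector: Optional[pd.Series]
    exclusivity: Optional[ExclusivityResult]
    clinical_report: Optional[pd.DataFrame]
    survival: Optional[object]
    funnel: dict[str, int]
    bundle_id: Optional[str] = None

    @property
    def oncogenic(self) -> list[FusionClassification]:
        return [c for c in self.classifications if c.oncogenic]

    @property
    def carriers(self) -> list[str]:
        return sorted({g.sample_id for g in self.validated})


def _compute_frames(calls, tx_by_gene):
    """In-frame verdict per call key.

    A caller-reported phase pair is authoritative when present (callers
    annotate frames from their own transcript models); otherwise the phase
    is recomputed from the bundle's transcripts. Calls naming a gene with
    no transcript model and carrying no label stay unresolved.
    """
    frames: dict[tuple, Optional[bool]] = {}
    for call in calls:
        if call.key in frames and frames[call.key] is not None:
            continue
        if call.frame_shift is not None:
            frames[call.key] = call.in_frame
            continue
        dtx = tx_by_gene.get(call.donor_gene)
        atx = tx_by_gene.get(call.acceptor_gene)
        if dtx is None or atx is None:
            frames[call.key] = None
            continue
        frames[call.key] = junction_phases(
            dtx, call.bp_donor.pos, atx, call.bp_acceptor.pos
        ).in_frame
    return frames


def run_all(config: RunConfig) -> PipelineResult:
    """Execute every stage over a file bundle; see the module docstring."""
    bundle = Path(config.bundle_dir)
    if not bundle.is_dir():
        raise ValidationError(f"bundle directory {bundle} does not exist")

    transcripts = fio.read_transcripts(config.input_path("transcripts.gtf"))
    tx_by_gene = fio.pick_representative_transcripts(transcripts)
    domains = fio.read_domains(config.input_path("domains.tsv"))
    functions = {
        a.gene: a for a in fio.read_gene_functions(config.input_path("gene_functions.tsv"))
    }

    calls = []
    for caller in config.callers:
        calls.extend(
            fio.read_fusion_calls(config.input_path(f"calls_{caller}.tsv"), caller_id=caller)
        )
    normal_path = config.input_path("normal_calls.tsv")
    normal_calls = fio.read_fusion_calls(normal_path) if normal_path.exists() else []

    # 1) screen every call through the filter cascade
    frames = _compute_frames(calls, tx_by_gene)
    screen_result = apply_screen(calls, normal_calls, frames, config.screen)

    # 2) cross-caller consensus on the survivors
    groups = group_calls(screen_result.survivors, config.consensus_tolerance)
    validated = cross_validate(groups, config.min_support)

    # 3) fusion proteins + per-fusion classification for validated groups
    # keyed classification must describe a *surviving* call of that key
    surviving_ids = {id(c) for c in screen_result.survivors}
    screen_cls = {}
    for call, cls in zip(calls, screen_result.classifications):
        if id(call) in surviving_ids or call.key not in screen_cls:
            screen_cls[call.key] = cls
    fusion_proteins: dict[tuple, FusionProtein] = {}
    classifications: list[FusionClassification] = []
    for grp in validated:
        cls = screen_cls[grp.key]
        cls.consensus_support = grp.support
        cls.supporting_callers = grp.callers
        rep = grp.representative
        dtx, atx = tx_by_gene.get(grp.donor_gene), tx_by_gene.get(grp.acceptor_gene)
        if dtx is not None and atx is not None:
            fusion_proteins[grp.key] = build_fusion_protein(
                dtx, rep.bp_donor.pos, atx, rep.bp_acceptor.pos, domains
            )
        classifications.append(cls)

    # 4) expression outliers on validated fusions
    expr_path = config.input_path("expression.tsv")
    expr = fio.read_expression(expr_path) if expr_path.exists() else None
    if expr is not None:
        for cls in classifications:
            for attr, gene in (("outlier_donor", cls.donor_gene),
                               ("outlier_acceptor", cls.acceptor_gene)):
                if gene in expr.values.index and cls.sample_id in expr.values.columns:
                    setattr(
                        cls, attr,
                        outlier_flag(expr, gene, cls.sample_id, config.outlier).flag,
                    )

    # 5) oncogenicity verdicts
    for cls in classifications:
        call_oncogenic(
            cls, functions, fusion_proteins.get(cls.key),
            config.truncation_threshold, config.oncogenicity_rule,
        )

    # 6) somatic-mutation exclusivity
    snv_result = mutation_matrix = fusion_vector = excl = None
    clinical_report = survival = None
    clinical_path = config.input_path("clinical.tsv")
    clinical = fio.read_clinical(clinical_path) if clinical_path.exists() else []
    patients = [r.sample_id for r in clinical] or None
    variants_path = config.input_path("variants.tsv")
    if variants_path.exists():
        variants = fio.read_variants(variants_path)
        nv_path = config.input_path("normal_variants.tsv")
        normal_variants = fio.read_variants(nv_path) if nv_path.exists() else []
        snv_result = filter_snvs(variants, normal_variants, config.snv_filter)
        panels_path = config.input_path("panels.tsv")
        panels = {}
        if panels_path.exists():
            pdf = pd.read_csv(panels_path, sep="\t")
            panels = dict(zip(pdf["gene"], pdf["panel"]))
        carriers = {g.sample_id for g in validated}
        mutation_matrix, fusion_vector = build_matrix(
            snv_result.survivors, carriers, panels, patients=patients
        )
        excl = exclusivity_test(
            mutation_matrix, fusion_vector, panel="oncogene",
            n_perm=config.n_perm, seed=config.seed,
        )

    # 7) clinical associations + survival
    if clinical:
        from .clinical import association_report, survival_comparison

        carriers = {g.sample_id for g in validated}
        fus_map = {r.sample_id: (r.sample_id in carriers) for r in clinical}
        clinical_report = association_report(clinical, fus_map)
        survival = survival_comparison(clinical, fus_map)

    funnel = {
        "input_calls": len(calls),
        "screen_survivor_calls": len(screen_result.survivors),
        "screen_rejected_calls": len(screen_result.rejected),
        "screen_unresolvable_calls": len(screen_result.unresolvable),
        "candidate_fusions": len(groups),
        "validated_fusions": len(validated),
        "oncogenic_fusions": sum(1 for c in classifications if c.oncogenic),
    }

    bundle_id = None
    manifest_path = config.input_path("manifest.json")
    if manifest_path.exists():
        with open(manifest_path) as fh:
            bundle_id = json.load(fh).get("bundle_id")

    result = PipelineResult(
        config=config,
        screen=screen_result,
        groups=groups,
        validated=validated,
        classifications=classifications,
        fusion_proteins=fusion_proteins,
        snv_result=snv_result,
        mutation_matrix=mutation_matrix,
        fusion_vector=fusion_vector,
        exclusivity=excl,
        clinical_report=clinical_report,
        survival=survival,
        funnel=funnel,
        bundle_id=bundle_id,
    )
    if config.out_dir is not None:
        write_reports(result, config.out_dir)
    return result


# ------------------------------------------------------------------ reports

def fusion_report_frame(result: PipelineResult) -> pd.DataFrame:
    """One row per validated fusion, mirroring the classic fusion
    characterisation table."""
    rows = []
    for cls in result.classifications:
        fp = result.fusion_proteins.get(cls.key)
        rows.append({
            "sample": cls.sample_id,
            "donor_gene": cls.donor_gene,
            "acceptor_gene": cls.acceptor_gene,
            "in_frame_shift": (
                fp.phases.label if fp is not None and fp.phases.label else "."
            ),
            "mid_distance": cls.mid_distance if cls.mid_distance is not None else ".",
            "support": cls.consensus_support,
            "callers": ",".join(cls.supporting_callers),
            "high_expression": cls.high_expression_label,
            "function": ",".join(sorted(cls.function_category)),
            "oncogenic": bool(cls.oncogenic),
            "reasons": "; ".join(cls.reasons),
        })
    return pd.DataFrame(rows)


def write_reports(result: PipelineResult, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["funnel"] = out / "funnel.json"
    with open(paths["funnel"], "w") as fh:
        json.dump(result.funnel, fh, indent=2, sort_keys=True)
        fh.write("\n")

    paths["fusion_report"] = out / "fusion_report.tsv"
    fusion_report_frame(result).to_csv(paths["fusion_report"], sep="\t", index=False)

    if result.mutation_matrix is not None:
        paths["mutation_matrix"] = out / "mutation_matrix.tsv"
        result.mutation_matrix.calls.to_csv(paths["mutation_matrix"], sep="\t",
                                            index_label="patient")
    if result.exclusivity is not None:
        paths["exclusivity"] = out / "exclusivity.json"
        with open(paths["exclusivity"], "w") as fh:
            json.dump(dataclasses.asdict(result.exclusivity), fh, indent=2,
                      sort_keys=True)
            fh.write("\n")
    if result.clinical_report is not None:
        paths["clinical"] = out / "clinical_report.tsv"
        result.clinical_report.to_csv(paths["clinical"], sep="\t", index=False)

    cfg = dataclasses.asdict(result.config)
    cfg["bundle_id"] = result.bundle_id
    paths["run_log"] = out / "run_log.json"
    with open(paths["run_log"], "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return paths
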