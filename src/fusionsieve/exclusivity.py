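"""Somatic-SNV hard filtering, the patient x gene mutation matrix, and the
fusion/mutation mutual-exclusivity test.

Filter cascade (all boundaries inclusive unless noted):

1. read depth at the position >= ``min_depth`` (10);
2. alt-supporting read depth >= ``min_alt_depth`` (2);
3. variant allele fraction >= ``min_vaf`` (3%);
4. region is exonic;
5. effect is frameshift / non-synonymous / stop-gain / stop-loss;
6. population minor allele frequency <= ``max_pop_maf`` (1%) — higher
   frequencies are treated as likely germline;
7. strand-bias / quality hard filter: Fisher Strand > 30 or Qual By Depth
   < 2 removes a variant (the standard GATK hard-filter direction);
8. not seen in a matched-normal sample (same sample pairing, same site).

A variant missing a field an enabled filter needs is unevaluable and
counted separately; attrition is attributed to the first failing filter in
the order above, so input = survivors + per-filter removals + unevaluable.

Mutual exclusivity between fusion status and mutations in an oncogene panel
is tested by label permutation: the statistic is the number of
fusion-positive patients carrying at least one panel mutation, and the
one-sided p-value (small overlap = exclusivity) is estimated by permuting
the fusion labels across patients with the mutation matrix fixed. The
overlap statistic is a small integer, so ties between permutations and the
observed value are massive; the default p-value therefore applies the
standard mid-p tie correction (half weight on ties), which restores
near-nominal type-I error for this discrete test. The strictly valid
(conservative) add-one form p = (1 + #{perm stat <= observed}) / (1 +
n_perm) is available as ``tie_correction='add-one'``. Both are add-one
smoothed, lie in (0, 1], and are reproducible under a fixed seed.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import SomaticVariant, ValidationError

DEFAULT_EFFECTS = frozenset({"frameshift", "non-synonymous", "stop-gain", "stop-loss"})


@dataclass(frozen=True)
class SnvFilterConfig:
    min_depth: int = 10
    min_alt_depth: int = 2
    min_vaf: float = 0.03
    allowed_effects: frozenset = DEFAULT_EFFECTS
    require_exonic: bool = True
    max_pop_maf: float = 0.01
    fs_cut: float = 30.0
    qd_cut: float = 2.0
    matched_normal_exclusion: bool = True

    def __post_init__(self) -> None:
        if min(self.min_depth, self.min_alt_depth) < 0:
            raise ValidationError("depth thresholds must be non-negative")
        if not (0.0 <= self.min_vaf <= 1.0):
            raise ValidationError("min_vaf must be in [0,1]")
        if self.max_pop_maf < 0 or self.fs_cut < 0 or self.qd_cut < 0:
            raise ValidationError("thresholds must be non-negative")


FILTER_ORDER = (
    "depth", "alt_depth", "vaf", "region", "effect",
    "pop_maf", "strand_quality", "matched_normal",
)


@dataclass
class SnvFilterResult:
    survivors: list[SomaticVariant]
    attrition: "OrderedDict[str, int]"
    unevaluable: list[SomaticVariant]

    @property
    def total_removed(self) -> int:
        return sum(self.attrition.values())


def _first_failure(
    v: SomaticVariant,
    config: SnvFilterConfig,
    normal_sites: frozenset,
) -> Optional[str]:
    """Name of the first failing filter, None if the variant survives.
    Raises KeyError('<filter>') when a needed field is missing."""
    if v.total_depth is None:
        raise KeyError("depth")
    if v.total_depth < config.min_depth:
        return "depth"
    if v.alt_depth is None:
        raise KeyError("alt_depth")
    if v.alt_depth < config.min_alt_depth:
        return "alt_depth"
    vaf = v.vaf
    if vaf is None:
        raise KeyError("vaf")
    if vaf < config.min_vaf:
        return "vaf"
    if config.require_exonic:
        if v.region is None:
            raise KeyError("region")
        if v.region != "exon":
            return "region"
    if v.effect is None:
        raise KeyError("effect")
    if v.effect not in config.allowed_effects:
        return "effect"
    if v.pop_maf is not None and v.pop_maf > config.max_pop_maf:
        return "pop_maf"
    if (v.fs is not None and v.fs > config.fs_cut) or (
        v.qd is not None and v.qd < config.qd_cut
    ):
        return "strand_quality"
    if config.matched_normal_exclusion and (v.chrom, v.pos, v.alt) in normal_sites:
        return "matched_normal"
    return None


def filter_snvs(
    variants: Sequence[SomaticVariant],
    normal_variants: Sequence[SomaticVariant] = (),
    config: SnvFilterConfig = SnvFilterConfig(),
) -> SnvFilterResult:
    """Apply the hard-filter cascade; returns survivors plus a per-filter
    attrition table (ordered as the cascade runs)."""
    normal_sites = frozenset((v.chrom, v.pos, v.alt) for v in normal_variants)
    attrition: "OrderedDict[str, int]" = OrderedDict((f, 0) for f in FILTER_ORDER)
    survivors, unevaluable = [], []
    for v in variants:
        try:
            failed = _first_failure(v, config, normal_sites)
        except KeyError:
            unevaluable.append(v)
            continue
        if failed is None:
            survivors.append(v)
        else:
            attrition[failed] += 1
    return SnvFilterResult(survivors=survivors, attrition=attrition,
                           unevaluable=unevaluable)


# ------------------------------------------------------------------- matrix

@dataclass
class MutationMatrix:
    """Binary patients x genes mutation matrix with per-gene panel labels."""

    calls: pd.DataFrame  # index: patients, columns: genes, values 0/1
    panels: dict[str, str]  # gene -> oncogene | suppressor | other

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("mutation matrix entries must be 0/1")

    @property
    def patients(self) -> list[str]:
        return list(self.calls.index)

    def panel_genes(self, panel: str) -> list[str]:
        return [g for g in self.calls.columns if self.panels.get(g, "other") == panel]

    def any_mutation(self, panel: str) -> pd.Series:
        """Per-patient indicator of >= 1 mutation in the panel's genes."""
        genes = self.panel_genes(panel)
        if not genes:
            return pd.Series(False, index=self.calls.index)
        return self.calls[genes].any(axis=1)


def build_matrix(
    variants: Sequence[SomaticVariant],
    fusion_positive: Iterable[str],
    panels: Mapping[str, str],
    patients: Optional[Sequence[str]] = None,
) -> tuple[MutationMatrix, pd.Series]:
    """Collapse filtered variants to the binary matrix and the fusion
    indicator vector. ``patients`` fixes row order (and includes
    mutation-free patients); by default rows are the union of variant
    samples and fusion-positive samples, sorted."""
    fusion_positive = set(fusion_positive)
    if patients is None:
        patients = sorted({v.sample_id for v in variants} | fusion_positive)
    genes = sorted({v.gene for v in variants} | set(panels))
    calls = pd.DataFrame(0, index=list(patients), columns=genes, dtype=int)
    for v in variants:
        if v.sample_id in calls.index:
            calls.at[v.sample_id, v.gene] = 1
    fusion_vector = pd.Series(
        [p in fusion_positive for p in patients], index=list(patients), dtype=bool
    )
    matrix = MutationMatrix(calls=calls, panels=dict(panels))
    return matrix, fusion_vector


# ------------------------------------------------------------- exclusivity

@dataclass(frozen=True)
class ExclusivityResult:
    statistic: int  # fusion-positive patients with >= 1 panel mutation
    p_value: float
    n_perm: int
    n_fusion: int
    n_mutated: int


def exclusivity_test(
    matrix: MutationMatrix,
    fusion_vector: pd.Series,
    panel: str = "oncogene",
    n_perm: int = 10_000,
    seed: Union[int, np.random.Generator] = 0,
    tie_correction: str = "mid",
) -> ExclusivityResult:
    """One-sided permutation test for mutual exclusivity of fusions and
    panel mutations.

    Permuting the fusion labels across patients (matrix marginals fixed)
    makes the permuted statistic the overlap of a random size-k patient
    subset with the mutated set, so the permutation stream is realized by
    sampling label subsets uniformly. ``tie_correction='mid'`` (default)
    gives ties half weight (near-nominal calibration for this heavily tied
    integer statistic); ``'add-one'`` counts ties fully (guaranteed valid,
    conservative). Either way p lies in (0, 1].
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if tie_correction not in ("mid", "add-one"):
        raise ValidationError(f"tie_correction must be mid or add-one, got {tie_correction!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    aligned = fusion_vector.reindex(matrix.calls.index)
    if aligned.isna().any():
        raise ValidationError("fusion vector does not cover all matrix patients")
    fus = aligned.to_numpy(dtype=bool)
    mut = matrix.any_mutation(panel).to_numpy(dtype=bool)

    k = int(fus.sum())
    observed = int((fus & mut).sum())
    if k < 1:
        import warnings

        warnings.warn("no fusion-positive patients; exclusivity p set to 1", stacklevel=2)
        return ExclusivityResult(observed, 1.0, n_perm, k, int(mut.sum()))

    n = fus.size
    # vectorized label permutations: each row of `order` is a random
    # permutation; its first k slots are the permuted fusion-positive set
    perm_stats = np.empty(n_perm, dtype=np.int64)
    chunk = max(1, min(n_perm, 512))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        order = np.argsort(rng.random((m, n)), axis=1)[:, :k]
        perm_stats[done:done + m] = mut[order].sum(axis=1)
        done += m
    below = int((perm_stats < observed).sum())
    ties = int((perm_stats == observed).sum())
    tie_weight = 0.5 if tie_correction == "mid" else 1.0
    p = (1 + below + tie_weight * ties) / (1 + n_perm)
    return ExclusivityResult(observed, float(p), n_perm, k, int(mut.sum()))
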