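"""Final oncogenic-fusion verdict.

A validated in-frame fusion is called oncogenic when any of three clauses
fires:

* ``expression_outlier`` — the carrier is an expression outlier for the
  donor or acceptor gene (aberrant activation);
* ``kinase_partner`` / ``oncogene_partner`` — a partner gene is annotated
  as a kinase or an oncogene (the classic activated-kinase fusion pattern,
  e.g. an ALK or NTRK1 acceptor);
* ``suppressor_truncation`` — a partner annotated as a tumour suppressor
  loses functional sequence in the fusion: any of its annotated domains is
  lost outright, or a domain is truncated below ``truncation_threshold``
  retained fraction. Losing downstream functional regions entirely is what
  kills suppressor activity even when the region spanning the breakpoint is
  largely retained, hence the lost-domain clause.

The rule is a disjunction (expression OR function), monotone in evidence:
adding an outlier flag or a kinase/oncogene annotation can only keep or
create a true verdict. Every true verdict carries at least one reason code;
a false verdict carries none. Set ``rule='conjunctive'`` to require both an
expression outlier and a function clause.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional

from .model import FusionClassification, GeneFunctionAnnotation, ValidationError
from .proteins import FusionProtein

DEFAULT_TRUNCATION_THRESHOLD = 0.9


def _function_clauses(
    cls: FusionClassification,
    annotations: Mapping[str, GeneFunctionAnnotation],
    fp: Optional[FusionProtein],
    truncation_threshold: float,
) -> tuple[list[str], set[str]]:
    reasons: list[str] = []
    categories: set[str] = set()
    for role, gene in (("donor", cls.donor_gene), ("acceptor", cls.acceptor_gene)):
        ann = annotations.get(gene)
        if ann is None:
            continue
        categories |= ann.categories
        if "kinase" in ann.categories:
            reasons.append(f"kinase {role}")
        if "oncogene" in ann.categories:
            reasons.append(f"oncogene {role}")
        if "suppressor" in ann.categories:
            if fp is None:
                warnings.warn(
                    f"{cls.key}: suppressor partner {gene} but no fusion-protein "
                    "report; truncation clause skipped",
                    stacklevel=3,
                )
                continue
            statuses = [
                ds for ds in fp.donor_domains + fp.acceptor_domains
                if ds.domain.gene == gene
            ]
            if any(ds.status == "lost" for ds in statuses) or any(
                ds.fraction < truncation_threshold for ds in statuses
            ):
                reasons.append(f"suppressor truncation ({role})")
    return reasons, categories


def call_oncogenic(
    classification: FusionClassification,
    annotations: Mapping[str, GeneFunctionAnnotation],
    fusion_protein: Optional[FusionProtein] = None,
    truncation_threshold: float = DEFAULT_TRUNCATION_THRESHOLD,
    rule: str = "disjunctive",
) -> FusionClassification:
    """Attach the oncogenic verdict and its reason codes to a
    classification (mutates and returns it)."""
    if rule not in ("disjunctive", "conjunctive"):
        raise ValidationError(f"rule must be disjunctive or conjunctive, got {rule!r}")

    reasons: list[str] = []
    if classification.outlier_donor:
        reasons.append("expression outlier (donor)")
    if classification.outlier_acceptor:
        reasons.append("expression outlier (acceptor)")
    expression_fired = bool(reasons)

    func_reasons, categories = _function_clauses(
        classification, annotations, fusion_protein, truncation_threshold
    )
    classification.function_category = frozenset(categories)

    if rule == "disjunctive":
        verdict = expression_fired or bool(func_reasons)
    else:
        verdict = expression_fired and bool(func_reasons)

    classification.oncogenic = verdict
    classification.reasons = tuple(reasons + func_reasons) if verdict else ()
    classification.validate()
    return classification


def call_all(
    classifications: Iterable[FusionClassification],
    annotations: Mapping[str, GeneFunctionAnnotation],
    fusion_proteins: Mapping[tuple, FusionProtein] = {},
    truncation_threshold: float = DEFAULT_TRUNCATION_THRESHOLD,
    rule: str = "disjunctive",
) -> list[FusionClassification]:
    """Vector form of :func:`call_oncogenic`; ``fusion_proteins`` is keyed
    by ``classification.key``."""
    return [
        call_oncogenic(
            cls, annotations, fusion_proteins.get(cls.key),
            truncation_threshold, rule,
        )
        for cls in classifications
    ]
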