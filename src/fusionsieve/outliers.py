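"""Expression-outlier detection for fusion partner genes.

A fusion that places a proto-oncogene under a foreign promoter typically
drives that gene's expression far above the cohort distribution; the carrier
then shows up as an expression outlier for the donor and/or acceptor gene.
Two conventional criteria are offered:

* ``tukey`` (default): value above the upper Tukey fence Q3 + k*IQR of the
  reference set (k = 1.5 by default);
* ``zscore``: standardized value above ``z_cut`` (3 by default).

The reference set defaults to tumour samples only, so a gene silent in
normals but moderately expressed across tumours is not trivially flagged.
Both criteria are scale-invariant: multiplying all FPKM by a positive
constant changes no flag. An optional log2(FPKM+1) transform before fencing
is provided for heavy-tailed genes (off by default; note the log transform
is *not* scale-invariant because of the +1 offset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import ExpressionMatrix, FusionClassification, ValidationError


@dataclass(frozen=True)
class OutlierConfig:
    method: str = "tukey"  # tukey | zscore
    tukey_k: float = 1.5
    z_cut: float = 3.0
    reference_set: str = "tumours"  # tumours | all_samples
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("tukey", "zscore"):
            raise ValidationError(f"unknown outlier method {self.method!r}")
        if self.tukey_k <= 0 or self.z_cut <= 0:
            raise ValidationError("tukey_k and z_cut must be positive")
        if self.reference_set not in ("tumours", "all_samples"):
            raise ValidationError(f"unknown reference_set {self.reference_set!r}")


@dataclass(frozen=True)
class OutlierResult:
    flag: bool
    score: float  # tukey: value - fence; zscore: the z value
    threshold: float


def _reference_values(
    expr: ExpressionMatrix, gene: str, config: OutlierConfig
) -> np.ndarray:
    if gene not in expr.values.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    cls = None if config.reference_set == "all_samples" else "tumour"
    vals = expr.values.loc[gene, expr.samples(cls)].to_numpy(dtype=float)
    if config.log_scale:
        vals = np.log2(vals + 1.0)
    return vals


def outlier_flag(
    expr: ExpressionMatrix, gene: str, sample: str, config: OutlierConfig = OutlierConfig()
) -> OutlierResult:
    """Is ``sample``'s expression of ``gene`` an upper outlier of the
    reference distribution? Returns the flag with its score."""
    if sample not in expr.values.columns:
        raise KeyError(f"sample {sample!r} not in expression matrix")
    ref = _reference_values(expr, gene, config)
    value = float(expr.values.at[gene, sample])
    if config.log_scale:
        value = float(np.log2(value + 1.0))

    if config.method == "tukey":
        q1, q3 = np.percentile(ref, [25, 75])
        fence = float(q3 + config.tukey_k * (q3 - q1))
        return OutlierResult(flag=bool(value > fence), score=value - fence, threshold=fence)

    sd = float(np.std(ref, ddof=1)) if ref.size > 1 else 0.0
    if sd == 0.0:
        warnings.warn(
            f"zero-variance reference for gene {gene!r}; no sample can be an outlier",
            stacklevel=2,
        )
        return OutlierResult(flag=False, score=0.0, threshold=config.z_cut)
    z = (value - float(np.mean(ref))) / sd
    return OutlierResult(flag=bool(z > config.z_cut), score=z, threshold=config.z_cut)


def annotate_fusion_expression(
    classifications: Iterable[FusionClassification],
    expr: ExpressionMatrix,
    config: OutlierConfig = OutlierConfig(),
) -> list[FusionClassification]:
    """Set ``outlier_donor`` / ``outlier_acceptor`` on each classification.

    A partner gene missing from the matrix leaves its flag undefined (None)
    with a warning; the summary label then treats it as not flagged.
    """
    out = []
    for cls in classifications:
        for attr, gene in (("outlier_donor", cls.donor_gene),
                           ("outlier_acceptor", cls.acceptor_gene)):
            try:
                setattr(cls, attr, outlier_flag(expr, gene, cls.sample_id, config).flag)
            except KeyError as exc:
                warnings.warn(f"{cls.key}: {exc}; outlier flag undefined", stacklevel=2)
                setattr(cls, attr, None)
        out.append(cls)
    return out
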