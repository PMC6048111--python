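"""Clinicopathological association analyses and survival comparison for
fusion-positive versus fusion-negative patients.

Categorical covariates are dichotomized the way colorectal-cancer cohorts
conventionally report them (histology: well+moderately vs poorly+mucinous;
invasion depth: T1+T2 vs T3+T4; microsatellite status: MSS+MSI-L vs MSI-H)
and tested with the chi-square or Fisher's exact test ('auto' picks the
exact test whenever any expected cell count is below 5). Continuous
covariates (age, tumour size) use the two-sample t-test with group means
and standard errors reported. Overall survival is compared with
Kaplan-Meier curves and the log-rank test; mean survival is the restricted
mean (horizon = largest observed time) with its standard error, matching
the "months +/- SE" convention of clinical tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ClinicalRecord, ValidationError

# covariate -> (label, grouping function returning a binary/categorical level)
CATEGORICAL_GROUPINGS = {
    "sex": ("male vs female", lambda r: r.sex),
    "location": ("right vs left colon", lambda r: r.location),
    "histology": (
        "well+moderately vs poorly+mucinous",
        lambda r: "well+moderately" if r.histology in ("well", "moderately") else "poorly+mucinous",
    ),
    "invasion_depth": (
        "T1+T2 vs T3+T4",
        lambda r: "T1+T2" if r.invasion_depth in ("T1", "T2") else "T3+T4",
    ),
    "perineural": ("negative vs positive", lambda r: "positive" if r.perineural else "negative"),
    "lymphovascular": ("negative vs positive", lambda r: "positive" if r.lymphovascular else "negative"),
    "lymph_node": ("negative vs positive", lambda r: "positive" if r.lymph_node else "negative"),
    "msi": (
        "MSS+MSI-L vs MSI-H",
        lambda r: "MSI-H" if r.msi_status == "MSI-H" else "MSS+MSI-L",
    ),
}


@dataclass
class AssociationResult:
    covariate: str
    grouping: str
    test: str
    statistic: Optional[float]
    p_value: Optional[float]
    table: Optional[pd.DataFrame] = None  # contingency counts (levels x fusion status)
    group_means: Optional[dict] = None  # level -> (mean, se, n)

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value out of [0,1]: {self.p_value}")

    @property
    def row_percentages(self) -> Optional[pd.DataFrame]:
        if self.table is None:
            return None
        return self.table.div(self.table.sum(axis=1), axis=0) * 100.0


def _fusion_series(
    records: Sequence[ClinicalRecord], fusion_vector: Mapping[str, bool] | pd.Series
) -> pd.Series:
    if isinstance(fusion_vector, pd.Series):
        fusion_vector = fusion_vector.to_dict()
    missing = [r.sample_id for r in records if r.sample_id not in fusion_vector]
    if missing:
        raise ValidationError(f"fusion status missing for patients: {missing[:5]}")
    return pd.Series({r.sample_id: bool(fusion_vector[r.sample_id]) for r in records})


def contingency_table(
    records: Sequence[ClinicalRecord],
    covariate: str,
    fusion_vector: Mapping[str, bool] | pd.Series,
) -> pd.DataFrame:
    """Levels x (fusion absent, fusion present) count table for a grouped
    categorical covariate."""
    if covariate not in CATEGORICAL_GROUPINGS:
        raise ValidationError(
            f"unknown categorical covariate {covariate!r}; "
            f"choose from {sorted(CATEGORICAL_GROUPINGS)}"
        )
    _, grouper = CATEGORICAL_GROUPINGS[covariate]
    fus = _fusion_series(records, fusion_vector)
    rows: dict[str, list[int]] = {}
    for r in records:
        level = grouper(r)
        rows.setdefault(level, [0, 0])[1 if fus[r.sample_id] else 0] += 1
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["absent", "present"])
    return table.sort_index()


def contingency_association(
    records: Sequence[ClinicalRecord],
    covariate: str,
    fusion_vector: Mapping[str, bool] | pd.Series,
    test: str = "auto",
) -> AssociationResult:
    """Chi-square or Fisher's exact association between a grouped
    categorical covariate and fusion status."""
    if test not in ("fisher", "chisq", "auto"):
        raise ValidationError(f"test must be fisher, chisq or auto, got {test!r}")
    grouping = CATEGORICAL_GROUPINGS[covariate][0]
    table = contingency_table(records, covariate, fusion_vector)
    counts = table.to_numpy()

    if counts.shape[0] < 2 or (counts.sum(axis=1) > 0).sum() < 2:
        warnings.warn(f"{covariate}: single observed level, association undefined",
                      stacklevel=2)
        return AssociationResult(covariate, grouping, "degenerate", None, None, table)

    if test == "auto":
        expected = stats.contingency.expected_freq(counts)
        test = "fisher" if (expected < 5).any() else "chisq"

    if test == "fisher":
        if counts.shape != (2, 2):
            # r x 2 tables fall back to chi-square (scipy's exact test is 2x2)
            stat, p = stats.chi2_contingency(counts)[:2]
            return AssociationResult(covariate, grouping, "chisq (rx2)", float(stat),
                                     float(p), table)
        stat, p = stats.fisher_exact(counts, alternative="two-sided")
        return AssociationResult(covariate, grouping, "fisher", float(stat), float(p), table)

    stat, p = stats.chi2_contingency(counts)[:2]
    return AssociationResult(covariate, grouping, "chisq", float(stat), float(p), table)


def continuous_association(
    records: Sequence[ClinicalRecord],
    covariate: str,
    fusion_vector: Mapping[str, bool] | pd.Series,
    equal_var: bool = True,
) -> AssociationResult:
    """Two-sample t-test of a numeric covariate between fusion groups, with
    group means +/- standard error."""
    getters = {"age": lambda r: r.age, "size": lambda r: r.size_cm}
    if covariate not in getters:
        raise ValidationError(f"continuous covariate must be age or size, got {covariate!r}")
    fus = _fusion_series(records, fusion_vector)
    get = getters[covariate]
    absent = np.array([get(r) for r in records if not fus[r.sample_id]], dtype=float)
    present = np.array([get(r) for r in records if fus[r.sample_id]], dtype=float)

    means = {
        "absent": (float(absent.mean()), float(stats.sem(absent)), absent.size)
        if absent.size else (np.nan, np.nan, 0),
        "present": (float(present.mean()), float(stats.sem(present)), present.size)
        if present.size else (np.nan, np.nan, 0),
    }
    if absent.size < 2 or present.size < 2:
        warnings.warn(f"{covariate}: a group has n < 2, p undefined", stacklevel=2)
        return AssociationResult(covariate, "fusion absent vs present",
                                 "t-test (undefined)", None, None, group_means=means)
    if absent.std(ddof=1) == 0 and present.std(ddof=1) == 0 and absent.mean() == present.mean():
        # identical constant groups: no evidence of difference
        return AssociationResult(covariate, "fusion absent vs present",
                                 "t-test", 0.0, 1.0, group_means=means)
    stat, p = stats.ttest_ind(absent, present, equal_var=equal_var)
    name = "t-test" if equal_var else "Welch t-test"
    return AssociationResult(covariate, "fusion absent vs present", name,
                             float(stat), float(p), group_means=means)


@dataclass
class SurvivalComparison:
    """Kaplan-Meier comparison of fusion-positive vs fusion-negative."""

    logrank_statistic: Optional[float]
    p_value: Optional[float]
    mean_survival: dict  # group -> (restricted mean months, se)
    curves: dict  # group -> DataFrame(time, survival)
    horizon: float


def restricted_mean_survival(km, horizon: float) -> tuple[float, float]:
    """Restricted mean survival time up to ``horizon`` and its standard
    error, from a fitted Kaplan-Meier estimator.

    The RMST is the area under the product-limit step function; its
    variance uses the classical Greenwood-type form
    ``sum_i A_i^2 d_i / (n_i (n_i - d_i))`` where ``A_i`` is the remaining
    area beyond event time ``t_i``.
    """
    sf = km.survival_function_
    times = np.asarray(sf.index, dtype=float)
    surv = np.asarray(sf.iloc[:, 0], dtype=float)
    keep = times <= horizon
    times, surv = times[keep], surv[keep]
    edges = np.append(times, horizon)
    widths = np.diff(edges)
    areas = surv * widths  # S is right-continuous: constant on [t_j, t_{j+1})
    rmst = float(areas.sum())

    tail_area = np.append(np.cumsum(areas[::-1])[::-1], 0.0)  # A at each t_j
    ev = km.event_table
    var = 0.0
    for t_i, row in ev.iterrows():
        d, n = float(row["observed"]), float(row["at_risk"])
        if d == 0 or t_i > horizon or n <= d:
            continue
        j = int(np.searchsorted(times, t_i, side="right")) - 1
        a_i = float(tail_area[j + 1]) if j + 1 < tail_area.size else 0.0
        var += a_i**2 * d / (n * (n - d))
    return rmst, float(np.sqrt(var))


def survival_comparison(
    records: Sequence[ClinicalRecord],
    fusion_vector: Mapping[str, bool] | pd.Series,
) -> SurvivalComparison:
    """Product-limit survival estimates per fusion group, log-rank test, and
    restricted-mean survival (+/- SE) at the largest observed time."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    fus = _fusion_series(records, fusion_vector)
    groups = {
        "negative": [r for r in records if not fus[r.sample_id]],
        "positive": [r for r in records if fus[r.sample_id]],
    }
    horizon = max(r.os_months for r in records)

    curves, mean_survival, fitted = {}, {}, {}
    for name, recs in groups.items():
        if not recs:
            continue
        t = np.array([r.os_months for r in recs], dtype=float)
        e = np.array([r.os_event for r in recs], dtype=bool)
        km = KaplanMeierFitter(label=name).fit(t, event_observed=e)
        fitted[name] = (t, e, km)
        curves[name] = km.survival_function_.reset_index().rename(
            columns={"timeline": "time", name: "survival"}
        )
        mean_survival[name] = restricted_mean_survival(km, horizon)

    if len(fitted) < 2:
        warnings.warn("one fusion group is empty; log-rank undefined", stacklevel=2)
        return SurvivalComparison(None, None, mean_survival, curves, horizon)

    (t0, e0, _), (t1, e1, _) = fitted["negative"], fitted["positive"]
    if not e0.any() and not e1.any():
        warnings.warn("no events in either group; log-rank undefined", stacklevel=2)
        return SurvivalComparison(None, None, mean_survival, curves, horizon)

    res = logrank_test(t0, t1, event_observed_A=e0, event_observed_B=e1)
    return SurvivalComparison(
        float(res.test_statistic), float(res.p_value), mean_survival, curves, horizon
    )


def association_report(
    records: Sequence[ClinicalRecord],
    fusion_vector: Mapping[str, bool] | pd.Series,
    test: str = "auto",
) -> pd.DataFrame:
    """One row per covariate: the full clinical association table."""
    rows = []
    for cov in ("age", "size"):
        res = continuous_association(records, cov, fusion_vector)
        rows.append({
            "covariate": cov, "grouping": res.grouping, "test": res.test,
            "statistic": res.statistic, "p_value": res.p_value,
        })
    for cov in CATEGORICAL_GROUPINGS:
        res = contingency_association(records, cov, fusion_vector, test=test)
        rows.append({
            "covariate": cov, "grouping": res.grouping, "test": res.test,
            "statistic": res.statistic, "p_value": res.p_value,
        })
    return pd.DataFrame(rows)
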