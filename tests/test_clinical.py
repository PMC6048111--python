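"""Clinical association tables, t-tests and survival comparison."""

import numpy as np
import pytest
from scipy import stats

from fusionsieve.clinical import (
    contingency_association,
    contingency_table,
    continuous_association,
    survival_comparison,
)
from fusionsieve.model import ClinicalRecord
from fusionsieve.simulate import SimConfig, simulate

from .helpers import fisher_two_sided_oracle


def record(sample, msi="MSS", size=5.0, age=60.0, sex="male",
           os_months=50.0, os_event=True, **kw):
    base = dict(
        sample_id=sample, age=age, size_cm=size, sex=sex, location="left",
        histology="moderately", invasion_depth="T3", perineural=False,
        lymphovascular=False, lymph_node=False, msi_status=msi,
        os_months=os_months, os_event=os_event,
    )
    base.update(kw)
    return ClinicalRecord(**base)


def cohort_with_msi_counts(a, b, c, d):
    """MSS+MSI-L: a absent / b present; MSI-H: c absent / d present."""
    records, fusion = [], {}
    i = 0
    for count, msi, fus in ((a, "MSS", False), (b, "MSS", True),
                            (c, "MSI-H", False), (d, "MSI-H", True)):
        for _ in range(count):
            sid = f"S{i:03d}"
            records.append(record(sid, msi=msi))
            fusion[sid] = fus
            i += 1
    return records, fusion


class TestContingency:
    def test_msi_association_on_printed_cohort_counts(self):
        """The published 147-patient MSI split ([[113,13],[15,6]]) is
        significant under the exact test, with the printed row
        percentages, and scipy's p matches the hypergeometric enumeration
        oracle."""
        records, fusion = cohort_with_msi_counts(113, 13, 15, 6)
        res = contingency_association(records, "msi", fusion, test="auto")
        assert res.test == "fisher"
        assert res.p_value < 0.05
        oracle = fisher_two_sided_oracle([[113, 13], [15, 6]])
        assert res.p_value == pytest.approx(oracle, rel=1e-9)
        pct = res.row_percentages
        assert pct.loc["MSS+MSI-L", "present"] == pytest.approx(10.3, abs=0.05)
        assert pct.loc["MSI-H", "present"] == pytest.approx(28.6, abs=0.05)

    def test_balanced_table_gives_p_one(self):
        records, fusion = cohort_with_msi_counts(50, 50, 50, 50)
        res = contingency_association(records, "msi", fusion, test="fisher")
        assert res.p_value == pytest.approx(1.0)

    def test_sex_counts_show_no_association(self):
        """A near-even male/female split of carriers (68/9 vs 60/10) is
        not significant."""
        records, fusion = [], {}
        i = 0
        for count, sex, fus in ((68, "male", False), (9, "male", True),
                                (60, "female", False), (10, "female", True)):
            for _ in range(count):
                sid = f"S{i:03d}"
                records.append(record(sid, sex=sex))
                fusion[sid] = fus
                i += 1
        res = contingency_association(records, "sex", fusion, test="auto")
        assert res.test == "chisq"
        assert res.p_value > 0.05

    def test_auto_switches_to_exact_for_sparse_cells(self):
        records, fusion = cohort_with_msi_counts(100, 10, 4, 2)
        res = contingency_association(records, "msi", fusion, test="auto")
        assert res.test == "fisher"

    def test_single_level_covariate_is_degenerate(self):
        records = [record(f"S{i}") for i in range(10)]  # all MSS
        fusion = {r.sample_id: i < 2 for i, r in enumerate(records)}
        with pytest.warns(UserWarning, match="single observed level"):
            res = contingency_association(records, "msi", fusion)
        assert res.p_value is None

    def test_grouped_levels_histology_and_depth(self):
        records = [
            record("S0", histology="well"), record("S1", histology="moderately"),
            record("S2", histology="poorly"), record("S3", histology="mucinous"),
        ]
        fusion = {r.sample_id: False for r in records}
        table = contingency_table(records, "histology", fusion)
        assert table.loc["well+moderately", "absent"] == 2
        assert table.loc["poorly+mucinous", "absent"] == 2


class TestContinuous:
    def test_identical_groups_give_p_one(self):
        records = [record(f"S{i}", size=4.0) for i in range(20)]
        fusion = {r.sample_id: i < 10 for i, r in enumerate(records)}
        res = continuous_association(records, "size", fusion)
        assert res.p_value == pytest.approx(1.0)

    def test_planted_size_difference_recovered_within_two_se(self):
        """Generator cohorts plant a 1.0 cm smaller tumour size in
        carriers; the pooled recovered difference must agree within 2 SE."""
        diffs, ses = [], []
        for seed in range(10):
            cohort = simulate(SimConfig(seed=seed))
            fusion = {r.sample_id: r.sample_id in set(cohort.carriers)
                      for r in cohort.clinical}
            res = continuous_association(cohort.clinical, "size", fusion)
            (m0, se0, _), (m1, se1, _) = res.group_means["absent"], res.group_means["present"]
            diffs.append(m0 - m1)
            ses.append(np.hypot(se0, se1))
        pooled = float(np.mean(diffs))
        pooled_se = float(np.mean(ses)) / np.sqrt(len(diffs))
        assert abs(pooled - 1.0) <= 2 * pooled_se

    def test_equal_and_unequal_variance_options_differ(self):
        rng = np.random.default_rng(0)
        records, fusion = [], {}
        for i, v in enumerate(rng.normal(5, 0.3, 40)):
            records.append(record(f"A{i:03d}", size=float(v)))
            fusion[f"A{i:03d}"] = False
        for i, v in enumerate(rng.normal(6, 3.0, 6)):
            records.append(record(f"B{i:03d}", size=float(abs(v)) + 0.5))
            fusion[f"B{i:03d}"] = True
        pooled = continuous_association(records, "size", fusion, equal_var=True)
        welch = continuous_association(records, "size", fusion, equal_var=False)
        assert pooled.p_value != welch.p_value
        assert welch.test == "Welch t-test"

    def test_tiny_group_leaves_p_undefined(self):
        records = [record("S0", size=3.0), record("S1", size=4.0), record("S2", size=5.0)]
        fusion = {"S0": True, "S1": False, "S2": False}
        with pytest.warns(UserWarning, match="n < 2"):
            res = continuous_association(records, "size", fusion)
        assert res.p_value is None


class TestSurvival:
    def test_identical_groups_give_logrank_p_one(self):
        times = [10.0, 20.0, 30.0, 40.0, 50.0]
        records, fusion = [], {}
        for grp, fus in (("A", False), ("B", True)):
            for i, t in enumerate(times):
                sid = f"{grp}{i}"
                records.append(record(sid, os_months=t, os_event=True))
                fusion[sid] = fus
        res = survival_comparison(records, fusion)
        assert res.p_value == pytest.approx(1.0)
        assert res.logrank_statistic == pytest.approx(0.0, abs=1e-9)

    def test_product_limit_matches_hand_computation(self):
        """Five patients (6+,14+,21+ deaths, 44 censored, 62 death):
        S = 0.8, 0.6, 0.4, 0.4, 0.0 at the event times."""
        data = [(6.0, True), (14.0, True), (21.0, True), (44.0, False), (62.0, True)]
        records = [record(f"S{i}", os_months=t, os_event=e)
                   for i, (t, e) in enumerate(data)]
        fusion = {r.sample_id: False for r in records}
        with pytest.warns(UserWarning, match="log-rank undefined"):
            res = survival_comparison(records, fusion)
        curve = res.curves["negative"].set_index("time")["survival"]
        assert curve.loc[6.0] == pytest.approx(0.8)
        assert curve.loc[14.0] == pytest.approx(0.6)
        assert curve.loc[21.0] == pytest.approx(0.4)
        assert curve.loc[62.0] == pytest.approx(0.0)
        mean, se = res.mean_survival["negative"]
        assert mean > 0 and se > 0

    def test_no_events_leaves_p_undefined(self):
        records = [record(f"S{i}", os_months=20.0, os_event=False)
                   for i in range(6)]
        fusion = {r.sample_id: i < 3 for i, r in enumerate(records)}
        with pytest.warns(UserWarning, match="no events"):
            res = survival_comparison(records, fusion)
        assert res.p_value is None

    def test_null_hazard_gives_uniformish_logrank_p(self):
        """Equal hazards in both groups: log-rank p-values across
        replicates behave like a uniform sample (Kolmogorov-Smirnov)."""
        master = np.random.default_rng(7)
        ps = []
        for _ in range(200):
            rng = np.random.default_rng(master.integers(2**31))
            records, fusion = [], {}
            for i in range(60):
                t_event = rng.exponential(100.0)
                t_cens = rng.uniform(50.0, 150.0)
                sid = f"S{i:03d}"
                records.append(record(sid, os_months=float(min(t_event, t_cens)),
                                      os_event=bool(t_event <= t_cens)))
                fusion[sid] = i < 30
            ps.append(survival_comparison(records, fusion).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.001


class TestRestrictedMean:
    def test_point_estimate_matches_lifelines(self, rng):
        """Our step-function RMST area equals the independent library
        computation on random censored samples."""
        import warnings

        from lifelines import KaplanMeierFitter
        from lifelines.utils import restricted_mean_survival_time

        from fusionsieve.clinical import restricted_mean_survival

        for _ in range(3):
            t_event = rng.exponential(100, 50)
            t_cens = rng.uniform(40, 150, 50)
            t = np.minimum(t_event, t_cens)
            e = t_event <= t_cens
            km = KaplanMeierFitter().fit(t, e)
            horizon = float(t.max())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = restricted_mean_survival_time(km, t=horizon)
            mine, se = restricted_mean_survival(km, horizon)
            assert mine == pytest.approx(float(ref), rel=1e-9)
            assert 0 < se < mine
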