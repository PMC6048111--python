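"""Somatic-variant hard filtering and the mutual-exclusivity permutation
test."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from fusionsieve.exclusivity import (
    MutationMatrix,
    SnvFilterConfig,
    build_matrix,
    exclusivity_test,
    filter_snvs,
)
from fusionsieve.model import SomaticVariant

from .helpers import exact_overlap_mid_p


def variant(**kwargs) -> SomaticVariant:
    base = dict(
        sample_id="S001", gene="KRAS", chrom="chr12", pos=25_398_284,
        ref="C", alt="T", total_depth=100, alt_depth=30,
        effect="non-synonymous", region="exon", fs=5.0, qd=15.0, pop_maf=0.0,
    )
    base.update(kwargs)
    return SomaticVariant(**base)


class TestSnvFilters:
    @pytest.mark.parametrize(
        "kwargs, removed_by",
        [
            (dict(total_depth=9, alt_depth=3), "depth"),
            (dict(alt_depth=1), "alt_depth"),
            (dict(total_depth=200, alt_depth=2), "vaf"),  # 1% < 3%
            (dict(region="intron"), "region"),
            (dict(effect="other"), "effect"),
            (dict(pop_maf=0.02), "pop_maf"),
            (dict(fs=35.0), "strand_quality"),
            (dict(qd=1.5), "strand_quality"),
        ],
    )
    def test_each_rule_removes_its_violator(self, kwargs, removed_by):
        result = filter_snvs([variant(**kwargs)])
        assert result.survivors == []
        assert result.attrition[removed_by] == 1

    def test_boundaries_are_inclusive(self):
        at_depth = variant(total_depth=10, alt_depth=2)
        at_vaf = variant(total_depth=100, alt_depth=3)  # exactly 3%
        at_maf = variant(pop_maf=0.01)
        at_fs = variant(fs=30.0)
        at_qd = variant(qd=2.0)
        result = filter_snvs([at_depth, at_vaf, at_maf, at_fs, at_qd])
        assert len(result.survivors) == 5

    def test_matched_normal_site_excluded(self):
        tumour = variant()
        germline_echo = variant(sample_id="S001_N")
        result = filter_snvs([tumour], normal_variants=[germline_echo])
        assert result.survivors == []
        assert result.attrition["matched_normal"] == 1

    def test_missing_field_is_unevaluable_not_dropped(self):
        incomplete = variant(total_depth=None, alt_depth=None)
        result = filter_snvs([incomplete])
        assert result.unevaluable == [incomplete]
        assert result.total_removed == 0

    def test_ten_variant_cascade_three_survive(self):
        """One violation of each rule, one unevaluable, three clean: the
        cascade keeps exactly the clean three and the attrition table
        accounts for every input variant."""
        violators = [
            variant(total_depth=5, alt_depth=2),
            variant(alt_depth=1),
            variant(total_depth=200, alt_depth=3),
            variant(region="UTR"),
            variant(effect="other"),
            variant(pop_maf=0.05),
        ]
        unevaluable = [variant(effect=None)]
        clean = [variant(gene=g) for g in ("KRAS", "NRAS", "PIK3CA")]
        result = filter_snvs(violators + unevaluable + clean)
        assert len(result.survivors) == 3
        assert result.total_removed == 6
        assert (
            len(result.survivors) + result.total_removed + len(result.unevaluable)
            == 10
        )


class TestMutationMatrix:
    def test_multiple_variants_collapse_to_single_entry(self):
        variants = [variant(pos=p) for p in (100, 200, 300)]
        matrix, fus = build_matrix(variants, ["S001"], {"KRAS": "oncogene"})
        assert matrix.calls.at["S001", "KRAS"] == 1
        assert matrix.calls.to_numpy().sum() == 1
        assert fus["S001"]

    def test_empty_variant_list_gives_zero_matrix(self):
        matrix, fus = build_matrix([], ["S001"], {"KRAS": "oncogene"},
                                   patients=["S001", "S002"])
        assert matrix.calls.to_numpy().sum() == 0
        assert list(fus.index) == ["S001", "S002"]

    def test_single_overlapping_carrier_pattern(self):
        """19 patients; oncogene-panel mutations placed only in the one
        fusion carrier that breaks exclusivity."""
        patients = [f"P{i:02d}" for i in range(19)]
        carriers = patients[:10]
        exceptional = carriers[0]
        variants = [variant(sample_id=exceptional, gene="KRAS")]
        variants += [
            variant(sample_id=p, gene="TP53") for p in patients[5:]
        ]
        matrix, fus = build_matrix(
            variants, carriers,
            {"KRAS": "oncogene", "TP53": "suppressor"}, patients=patients,
        )
        onc = matrix.any_mutation("oncogene")
        overlap = (onc & fus).sum()
        assert overlap == 1 and onc[exceptional]


class TestExclusivityTest:
    def make(self, mut, carriers, patients=None):
        patients = patients or [f"P{i:02d}" for i in range(len(mut))]
        calls = pd.DataFrame({"ONC1": np.asarray(mut, dtype=int)}, index=patients)
        matrix = MutationMatrix(calls=calls, panels={"ONC1": "oncogene"})
        fus = pd.Series([p in set(carriers) for p in patients], index=patients)
        return matrix, fus

    def test_no_carriers_degenerates_to_p_one(self):
        matrix, fus = self.make([1, 0, 1, 0], [])
        with pytest.warns(UserWarning, match="no fusion-positive"):
            res = exclusivity_test(matrix, fus, n_perm=100)
        assert res.p_value == 1.0 and res.statistic == 0

    def test_reproducible_under_fixed_seed_and_patient_reordering(self, rng):
        mut = list(rng.random(30) < 0.4)
        patients = [f"P{i:02d}" for i in range(30)]
        carriers = [patients[i] for i in rng.choice(30, 6, replace=False)]
        matrix, fus = self.make(mut, carriers, patients)
        r1 = exclusivity_test(matrix, fus, n_perm=2000, seed=5)
        r2 = exclusivity_test(matrix, fus, n_perm=2000, seed=5)
        assert r1 == r2

        order = list(rng.permutation(30))
        calls2 = matrix.calls.iloc[order]
        matrix2 = MutationMatrix(calls=calls2, panels=matrix.panels)
        r3 = exclusivity_test(matrix2, fus.iloc[order], n_perm=2000, seed=5)
        assert r3.statistic == r1.statistic
        assert abs(r3.p_value - r1.p_value) < 0.05

    def test_sampled_p_matches_exhaustive_enumeration(self, rng):
        """On 6-patient toys the sampled mid-p must sit within 3 Monte-Carlo
        standard errors of the exhaustive label-permutation value."""
        n_perm = 20_000
        for trial in range(5):
            mut = list(rng.random(6) < 0.5)
            if not any(mut):
                mut[0] = True
            patients = [f"P{i}" for i in range(6)]
            k = int(rng.integers(1, 4))
            carriers = [patients[i] for i in rng.choice(6, k, replace=False)]
            matrix, fus = self.make(mut, carriers, patients)
            res = exclusivity_test(matrix, fus, n_perm=n_perm, seed=trial)
            exact = exact_overlap_mid_p(mut, k, res.statistic)
            se = np.sqrt(max(exact * (1 - exact), 1e-6) / n_perm)
            assert abs(res.p_value - exact) <= 3 * se + 2 / n_perm

    def test_strong_exclusivity_detected_in_synthetic_cohorts(self):
        """100 patients, 15 carriers, 50% oncogene mutation rate outside
        carriers and none inside: p < 0.01 in at least 95% of replicates."""
        hits = 0
        n_rep = 40
        master = np.random.default_rng(2024)
        for _ in range(n_rep):
            rng = np.random.default_rng(master.integers(2**31))
            patients = [f"P{i:03d}" for i in range(100)]
            carriers = set(np.array(patients)[rng.choice(100, 15, replace=False)])
            mut = [
                (p not in carriers) and (rng.random() < 0.5) for p in patients
            ]
            matrix, fus = self.make(mut, carriers, patients)
            res = exclusivity_test(matrix, fus, n_perm=2000,
                                   seed=np.random.default_rng(rng.integers(2**31)))
            hits += res.p_value < 0.01
        assert hits / n_rep >= 0.95

    def test_null_p_values_are_valid(self):
        """With fusion labels independent of mutations, P(p <= a) must not
        exceed a by more than Monte-Carlo slack, at several levels."""
        master = np.random.default_rng(99)
        ps = []
        for _ in range(300):
            rng = np.random.default_rng(master.integers(2**31))
            mut = rng.random(60) < 0.4
            patients = [f"P{i:03d}" for i in range(60)]
            carriers = set(np.array(patients)[rng.choice(60, 9, replace=False)])
            matrix, fus = self.make(list(mut), carriers, patients)
            ps.append(
                exclusivity_test(matrix, fus, n_perm=500,
                                 seed=np.random.default_rng(rng.integers(2**31))).p_value
            )
        ps = np.asarray(ps)
        for alpha in (0.05, 0.1, 0.25, 0.5):
            assert (ps <= alpha).mean() <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / len(ps))
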