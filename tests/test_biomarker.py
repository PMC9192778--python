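"""Receptor calls, marker calls, the hazard decision tree and enrichment stats."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from dcistraj.biomarker import (
    HazardGroup,
    MarkerPanel,
    ReceptorThresholds,
    assign_hazard,
    ecdf_fisher_compare,
    enrichment_fold,
    fold_from_proportions,
    hazard_assignments,
    patient_marker_status,
    progressor_tally,
    receptor_status_call,
)


class TestReceptorCalls:
    def test_er_positive_above_threshold(self):
        expr = pd.DataFrame({"s1": [7.2, 3.0, 5.0]}, index=["ESR1", "PGR", "ERBB2"])
        calls = receptor_status_call(expr)
        assert calls.loc["s1", "ER"] and not calls.loc["s1", "PR"]

    def test_boundary_value_counts_positive(self):
        expr = pd.DataFrame({"s1": [6.0, 6.0, 10.5]}, index=["ESR1", "PGR", "ERBB2"])
        calls = receptor_status_call(expr)
        assert calls.loc["s1", ["ER", "PR", "Her2"]].all()

    def test_triple_negative(self):
        expr = pd.DataFrame({"s1": [5.0, 5.0, 9.0]}, index=["ESR1", "PGR", "ERBB2"])
        calls = receptor_status_call(expr)
        assert bool(calls.loc["s1", "triple_negative"])

    def test_missing_gene_raises(self):
        expr = pd.DataFrame({"s1": [5.0]}, index=["ESR1"])
        with pytest.raises(KeyError, match="PGR"):
            receptor_status_call(expr)


def marker_setup(values_by_sample, patients, tissue="DCIS"):
    samples = list(values_by_sample)
    expr = pd.DataFrame({s: [v] for s, v in values_by_sample.items()}, index=["MNX1"])
    meta = pd.DataFrame({"patient": patients, "tissue": tissue}, index=samples)
    return expr, meta


class TestMarkerCalls:
    def test_two_of_three_below_cut_is_idc_associated(self):
        expr, meta = marker_setup({"a": 1.0, "b": 1.5, "c": 9.0}, ["p1"] * 3)
        calls = patient_marker_status(expr, meta, "MNX1", cut=5.0, idc_associated_direction="low")
        assert calls["p1"] is True

    def test_single_sample_patient_unassigned(self):
        expr, meta = marker_setup({"a": 1.0}, ["p1"])
        calls = patient_marker_status(expr, meta, "MNX1", cut=5.0)
        assert calls["p1"] is None

    def test_one_of_five_below_cut_not_associated(self):
        expr, meta = marker_setup({c: 9.0 for c in "abcde"} | {"a": 1.0}, ["p1"] * 5)
        calls = patient_marker_status(expr, meta, "MNX1", cut=5.0)
        assert calls["p1"] is False

    def test_high_direction_counts_at_or_above_cut(self):
        expr, meta = marker_setup({"a": 5.0, "b": 7.0, "c": 1.0}, ["p1"] * 3)
        calls = patient_marker_status(expr, meta, "MNX1", cut=5.0, idc_associated_direction="high")
        assert calls["p1"] is True


class TestTally:
    def test_counts(self):
        calls = pd.DataFrame(
            {
                "MNX1": [True, False, True],
                "HOXC11": [True, False, True],
                "ANKRD22": [True, False, None],
                "ADCY5": [True, False, False],
            },
            index=["all_down", "none_down", "partial"],
        )
        tally = progressor_tally(calls)
        assert tally["all_down"] == 4 and tally["none_down"] == 0
        assert tally["partial"] is None  # missing call propagates

    def test_two_down(self):
        calls = pd.DataFrame(
            {"MNX1": [True], "HOXC11": [True], "ANKRD22": [False], "ADCY5": [False]}, index=["p"]
        )
        assert progressor_tally(calls)["p"] == 2


class TestDecisionTree:
    @pytest.mark.parametrize(
        "anchor,tally,refiner,expected",
        [
            (False, 1, False, HazardGroup.LOWER),  # anchor high, 0-1 down, refiner low
            (False, 0, False, HazardGroup.LOWER),
            (True, 0, False, HazardGroup.HIGHER),  # anchor low overrides everything
            (False, 3, False, HazardGroup.HIGHER),
            (False, 4, True, HazardGroup.HIGHER),
            (False, 1, True, HazardGroup.HIGHER),  # refiner high pushes out of Lower
            (False, 2, False, HazardGroup.INDETERMINATE),  # tally gap
        ],
    )
    def test_printed_rules(self, anchor, tally, refiner, expected):
        group, _ = assign_hazard(anchor, tally, refiner, False)
        assert group is expected

    def test_rescuer_mitigation_recorded_only_in_high_tally_branch(self):
        group, mitigated = assign_hazard(False, 4, False, False)  # THRSP high
        assert group is HazardGroup.HIGHER and mitigated
        group, mitigated = assign_hazard(False, 4, False, True)  # THRSP low
        assert group is HazardGroup.HIGHER and not mitigated

    def test_tree_total_and_deterministic(self):
        for anchor, tally, refiner, rescuer in itertools.product(
            [True, False], range(5), [True, False], [True, False]
        ):
            g1, _ = assign_hazard(anchor, tally, refiner, rescuer)
            g2, _ = assign_hazard(anchor, tally, refiner, rescuer)
            assert g1 is g2
            assert g1 in (HazardGroup.LOWER, HazardGroup.HIGHER, HazardGroup.INDETERMINATE)

    def test_unresolved_calls_unassigned(self):
        group, _ = assign_hazard(None, 1, False, False)
        assert group is HazardGroup.UNASSIGNED


class TestEnrichment:
    def test_printed_folds(self):
        assert fold_from_proportions(0.36, 0.10) == 3.6
        assert fold_from_proportions(0.71, 0.42) == 1.7
        assert fold_from_proportions(0.5, 0.5) == 1.0

    def test_fold_from_group_assignments(self):
        # 36 of 100 Pure patients and 10 of 100 IDC-diagnosed in the group
        groups = pd.Series(
            ["Lower"] * 36 + ["Other"] * 64 + ["Lower"] * 10 + ["Other"] * 90,
            index=[f"p{i}" for i in range(200)],
        )
        outcomes = pd.Series(["Pure"] * 100 + ["IDC"] * 100, index=groups.index)
        res = enrichment_fold(groups, outcomes, "Lower", "Pure", "IDC")
        assert res["fold"] == 3.6 and res["prop_a"] == 0.36 and res["prop_b"] == 0.10

    def test_reciprocal_folds_multiply_to_one(self):
        rng = np.random.default_rng(0)
        groups = pd.Series(rng.choice(["L", "H"], 300), index=range(300))
        outcomes = pd.Series(rng.choice(["Pure", "IDC"], 300), index=range(300))
        a = enrichment_fold(groups, outcomes, "L", "Pure", "IDC")
        b = enrichment_fold(groups, outcomes, "L", "IDC", "Pure")
        assert a["prop_a"] / a["prop_b"] * (b["prop_a"] / b["prop_b"]) == pytest.approx(1.0)

    def test_planted_markers_enrich_lower_hazard_for_pure(self, small_cohort, small_expr):
        counts, meta, truth = small_cohort
        hazard = hazard_assignments(small_expr, meta)
        status = meta.groupby("patient")["patient_status"].first().reindex(hazard.index)
        res = enrichment_fold(hazard["group"], status, HazardGroup.LOWER.value, "Pure", "NotPure")
        assert res["fold"] > 1.0


def fisher_exact_enumeration(table):
    """Two-sided Fisher p by full enumeration of tables with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestEcdfFisher:
    def test_identical_groups_p_one(self):
        res = ecdf_fisher_compare([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert res.p == pytest.approx(1.0)

    def test_matches_enumeration(self):
        # dichotomization chosen to yield the table [[8,2],[2,8]]
        a = np.concatenate([np.zeros(8), np.ones(2)])
        b = np.concatenate([np.zeros(2), np.ones(8)])
        res = ecdf_fisher_compare(a, b, dichotomize_at=0.5)
        assert res.table.tolist() == [[8, 2], [2, 8]]
        assert res.p == pytest.approx(fisher_exact_enumeration(res.table), rel=1e-9)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            a = rng.normal(0, 1, rng.integers(4, 13))
            b = rng.normal(0.5, 1, rng.integers(4, 13))
            res = ecdf_fisher_compare(a, b)
            assert res.p == pytest.approx(fisher_exact_enumeration(res.table), rel=1e-9)

    def test_cut_below_all_values_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = ecdf_fisher_compare([1.0, 2.0], [3.0, 4.0], dichotomize_at=-10.0)
        assert res.p == 1.0

    def test_ecdf_is_cumulative_fraction(self):
        res = ecdf_fisher_compare([3.0, 1.0, 2.0], [1.0, 5.0])
        vals, fracs = res.ecdf_a
        assert list(vals) == [1.0, 2.0, 3.0]
        assert list(fracs) == pytest.approx([1 / 3, 2 / 3, 1.0])


class TestHazardAssignments:
    def test_every_multi_sample_dcis_patient_gets_one_group(self, small_cohort, small_expr):
        counts, meta, truth = small_cohort
        hazard = hazard_assignments(small_expr, meta)
        dcis_counts = meta[meta["tissue"] == "DCIS"].groupby("patient").size()
        assert set(hazard.index) == set(dcis_counts.index)
        multi = dcis_counts.index[dcis_counts >= 2]
        valid = {g.value for g in HazardGroup}
        assert hazard["group"].isin(valid).all()
        single = dcis_counts.index[dcis_counts == 1]
        assert (hazard.loc[single, "group"] == HazardGroup.UNASSIGNED.value).all()
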