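"""Four-stage sample quality filtering."""

import numpy as np
import pandas as pd
import pytest

from dcistraj import preprocess, qc


def make_meta(sample_ids, tissue="DCIS", patient=None, subtype="LumA"):
    n = len(sample_ids)
    return pd.DataFrame(
        {
            "patient": patient if patient is not None else [f"p{i}" for i in range(n)],
            "tissue": [tissue] * n if isinstance(tissue, str) else tissue,
            "subtype": [subtype] * n if isinstance(subtype, str) else subtype,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


def correlated_block(rng, n_samples, n_genes=300, noise=0.3):
    base = rng.normal(5, 2, n_genes)
    return pd.DataFrame(
        base[:, None] + rng.normal(0, noise, (n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i:02d}" for i in range(n_samples)],
    )


class TestMetricsFilter:
    @pytest.mark.parametrize(
        "reads,unique,genes,passes",
        [
            (2e6, 50.0, 20.0, True),
            (0.9e6, 50.0, 20.0, False),  # below the 1M read floor
            (1e6, 50.0, 20.0, True),  # boundary passes (strict <)
            (2e6, 15.0, 20.0, True),
            (2e6, 14.9, 20.0, False),
            (2e6, 50.0, 5.0, True),
            (2e6, 50.0, 4.9, False),
        ],
    )
    def test_any_criterion_fails_sample(self, reads, unique, genes, passes):
        stats = pd.DataFrame(
            {"raw_reads": [reads], "pct_unique_map": [unique], "pct_reads_in_genes": [genes]},
            index=["s1"],
        )
        ok, bad = qc.initial_metrics_filter(stats)
        assert (ok == ["s1"]) == passes and (bad == ["s1"]) != passes

    def test_missing_metric_names_sample(self):
        stats = pd.DataFrame(
            {"raw_reads": [2e6, np.nan], "pct_unique_map": [50, 50], "pct_reads_in_genes": [20, 20]},
            index=["good", "incomplete"],
        )
        with pytest.raises(ValueError, match="incomplete"):
            qc.initial_metrics_filter(stats)


class TestCohortFilter:
    def test_shuffled_sample_removed(self):
        rng = np.random.default_rng(0)
        expr = correlated_block(rng, 5)
        expr["s02"] = rng.permutation(expr["s02"].to_numpy())  # r ~ 0 to the mean
        removed = qc.iterative_cohort_filter(expr, make_meta(expr.columns))
        assert removed == ["s02"]

    def test_identical_samples_no_removals(self):
        expr = pd.DataFrame(
            np.tile(np.arange(20, dtype=float)[:, None], (1, 4)), columns=list("abcd")
        )
        assert qc.iterative_cohort_filter(expr, make_meta(expr.columns)) == []

    def test_idc_class_uses_relaxed_threshold(self):
        rng = np.random.default_rng(1)
        expr = correlated_block(rng, 8, noise=0.2)
        meta_dcis = make_meta(expr.columns, tissue="DCIS")
        meta_idc = make_meta(expr.columns, tissue="IDC")
        # craft one sample whose correlation to the mean sits in [0.65, 0.70)
        others_mean = expr.drop(columns="s07").mean(axis=1)
        noise = rng.normal(0, 1, len(expr))
        lo, hi = 0.1, 20.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            cand = others_mean + mid * noise
            r = np.corrcoef(cand, others_mean)[0, 1]
            if r < 0.66:
                hi = mid
            elif r >= 0.69:
                lo = mid
            else:
                break
        expr["s07"] = cand
        assert 0.65 <= r < 0.70  # between the IDC and default thresholds
        assert "s07" in qc.iterative_cohort_filter(expr, meta_dcis)
        assert "s07" not in qc.iterative_cohort_filter(expr, meta_idc)

    def test_small_class_skipped_with_warning(self):
        rng = np.random.default_rng(2)
        expr = correlated_block(rng, 2)
        with pytest.warns(UserWarning, match="skipped"):
            removed = qc.iterative_cohort_filter(expr, make_meta(expr.columns))
        assert removed == []

    def test_gram_path_matches_naive_recomputation(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            x = rng.normal(0, 1, (60, 30)) + rng.normal(0, 1.2, (60, 1))
            expr = pd.DataFrame(x, columns=[f"s{i:02d}" for i in range(30)])
            thr = rng.uniform(0.3, 0.9)
            assert qc._iterative_filter(expr, thr) == qc._iterative_filter_naive(expr, thr)


class TestPatientMeanFilter:
    def test_sample_identical_to_its_patient_retained(self):
        # within-patient replicates identical -> patient correlation is maximal
        rng = np.random.default_rng(4)
        base = rng.normal(5, 2, 300)
        p1 = base + rng.normal(0, 1, 300)
        p2 = base + rng.normal(0, 1, 300)
        expr = pd.DataFrame({"a1": p1, "a2": p1, "a3": p1, "b1": p2, "b2": p2, "b3": p2})
        meta = make_meta(expr.columns, patient=["p1", "p1", "p1", "p2", "p2", "p2"])
        assert qc.patient_mean_filter(expr, meta) == []

    def test_cohort_profile_sample_in_divergent_patient_removed(self):
        rng = np.random.default_rng(5)
        base = rng.normal(5, 2, 300)
        shift = rng.normal(0, 3, 300)  # strong private patient profile
        cols = {}
        for i in range(4):
            cols[f"c{i}"] = base + rng.normal(0, 0.3, 300)  # cohort-like patient p0
        for i in range(3):
            cols[f"d{i}"] = base + shift + rng.normal(0, 0.3, 300)  # divergent patient p1
        cols["intruder"] = base + rng.normal(0, 0.3, 300)  # cohort profile, inside p1
        expr = pd.DataFrame(cols)
        meta = make_meta(expr.columns, patient=["p0"] * 4 + ["p1"] * 3 + ["p1"])
        removed = qc.patient_mean_filter(expr, meta)
        assert removed == ["intruder"]

    def test_single_sample_patient_exempt(self):
        rng = np.random.default_rng(6)
        expr = correlated_block(rng, 5, noise=2.0)
        meta = make_meta(expr.columns, patient=["p1", "p1", "p1", "p1", "solo"])
        assert "s04" not in qc.patient_mean_filter(expr, meta)


class TestPatientFilter:
    def test_identical_pair_retained(self):
        rng = np.random.default_rng(7)
        expr = correlated_block(rng, 4, noise=0.0)
        meta = make_meta(expr.columns, patient=["p1"] * 4)
        assert qc.iterative_patient_filter(expr, meta) == []

    def test_corrupted_section_removed(self):
        rng = np.random.default_rng(8)
        expr = correlated_block(rng, 5, noise=0.2)
        expr["s04"] = rng.permutation(expr["s04"].to_numpy())
        meta = make_meta(expr.columns, patient=["p1"] * 5)
        assert qc.iterative_patient_filter(expr, meta) == ["s04"]

    def test_basal_idc_threshold_is_070(self):
        thr = qc.QCThresholds()
        assert thr.patient_threshold("IDC", "Basal") == 0.70
        assert thr.cohort_threshold("IDC", "Basal") == 0.60
        assert thr.cohort_threshold("DCIS", "Basal") == 0.65
        assert thr.patient_threshold("DCIS", "LumA") == 0.80


class TestRunQC:
    def test_conservation_and_recovery_on_injected_cohort(self, small_cohort_bad):
        counts, meta, truth = small_cohort_bad
        expr = preprocess.log_cpm(preprocess.filter_genes(counts), None)
        report = qc.run_qc(expr, meta)
        assert report.check_conservation()
        bad = set(truth.injected_bad[truth.injected_bad].index)
        removed = set(report.removed_cohort) | set(report.removed_patient_vs_cohort) | set(
            report.removed_patient
        )
        assert bad <= removed, "all injected samples must be caught"
        clean = set(counts.columns) - bad
        assert len(set(report.retained) & clean) / len(clean) >= 0.95

    def test_idempotent_on_retained_set(self, small_cohort_bad):
        counts, meta, truth = small_cohort_bad
        expr = preprocess.log_cpm(preprocess.filter_genes(counts), None)
        report = qc.run_qc(expr, meta)
        second = qc.run_qc(expr[report.retained], meta.loc[report.retained])
        assert second.retained == report.retained

    def test_generous_thresholds_retain_all(self, small_cohort):
        counts, meta, _ = small_cohort
        expr = preprocess.log_cpm(preprocess.filter_genes(counts), None)
        loose = qc.QCThresholds(
            cohort_r={k: 0.01 for k in qc.QCThresholds().cohort_r},
            patient_r={k: 0.01 for k in qc.QCThresholds().patient_r},
        )
        sub = expr.iloc[:, :120]
        report = qc.run_qc(sub, meta, thresholds=loose)
        # stages 1 and 3 cannot remove anything at threshold 0.01
        assert report.removed_cohort == [] and report.removed_patient == []
        assert report.check_conservation()

    def test_raising_threshold_never_shrinks_removed_set(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, (80, 20)) + rng.normal(0, 1, (80, 1))
        expr = pd.DataFrame(x, columns=[f"s{i:02d}" for i in range(20)])
        meta = make_meta(expr.columns)
        removed_low = set(
            qc.iterative_cohort_filter(expr, meta, qc.QCThresholds(cohort_r={"default": 0.4, "IDC": 0.4, "basal_DCIS": 0.4, "basal_IDC": 0.4}))
        )
        removed_high = set(
            qc.iterative_cohort_filter(expr, meta, qc.QCThresholds(cohort_r={"default": 0.6, "IDC": 0.6, "basal_DCIS": 0.6, "basal_IDC": 0.6}))
        )
        assert removed_low <= removed_high

    def test_retained_after_printed_bookkeeping(self):
        assert qc.retained_after(2724, [414, 43, 45]) == 2222
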