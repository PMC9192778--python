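"""Four-stage sample quality filtering for micro-dissected lesion RNA-seq.

Stages, applied in order within each tissue class:

0. library metrics — fail on <1e6 raw reads, <15% uniquely mapping, or <5% of
   raw reads assigned to genes (strict inequalities; boundary values pass);
1. iterative cohort filter — repeatedly drop the sample least correlated to
   the class mean log-CPM until every remaining sample meets the class
   threshold;
2. patient-vs-cohort filter — drop samples more correlated to the cohort mean
   than to their own patient's mean;
3. iterative patient filter — as stage 1, but against the per-patient mean at
   the stricter patient threshold.

Correlations are Pearson on log-CPM, with the scored sample excluded from the
mean profile it is compared against. Invasive (IDC) and basal-subtype classes
use relaxed thresholds reflecting their higher biological heterogeneity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUES = ("normal", "benign", "atypia", "DCIS", "IDC")


@dataclass(frozen=True)
class QCThresholds:
    """Correlation thresholds per (tissue, subtype) class.

    ``cohort_r`` applies to stage 1, ``patient_r`` to stage 3. Keys are
    ``"default"``, ``"IDC"``, ``"basal_DCIS"`` and ``"basal_IDC"``; basal DCIS
    borrows the IDC thresholds and basal IDC gets a further relaxation.
    """

    cohort_r: dict = field(
        default_factory=lambda: {
            "default": 0.70,
            "IDC": 0.65,
            "basal_DCIS": 0.65,
            "basal_IDC": 0.60,
        }
    )
    patient_r: dict = field(
        default_factory=lambda: {
            "default": 0.80,
            "IDC": 0.75,
            "basal_DCIS": 0.75,
            "basal_IDC": 0.70,
        }
    )

    def cohort_threshold(self, tissue: str, subtype: str | None = None) -> float:
        return self.cohort_r[_threshold_class(tissue, subtype)]

    def patient_threshold(self, tissue: str, subtype: str | None = None) -> float:
        return self.patient_r[_threshold_class(tissue, subtype)]


def _threshold_class(tissue: str, subtype: str | None) -> str:
    basal = subtype is not None and str(subtype).lower() == "basal"
    if basal and tissue in ("DCIS", "IDC"):
        return f"basal_{tissue}"
    if tissue == "IDC":
        return "IDC"
    return "default"


@dataclass
class QCReport:
    """Bookkeeping of every QC decision; removed sets are disjoint by stage."""

    input_samples: list
    removed_metrics: list
    removed_cohort: list
    removed_patient_vs_cohort: list
    removed_patient: list
    retained: list

    @property
    def counts(self) -> dict:
        return {
            "input": len(self.input_samples),
            "removed_metrics": len(self.removed_metrics),
            "removed_cohort": len(self.removed_cohort),
            "removed_patient_vs_cohort": len(self.removed_patient_vs_cohort),
            "removed_patient": len(self.removed_patient),
            "retained": len(self.retained),
        }

    def check_conservation(self) -> bool:
        c = self.counts
        removed = (
            c["removed_metrics"]
            + c["removed_cohort"]
            + c["removed_patient_vs_cohort"]
            + c["removed_patient"]
        )
        return c["input"] == c["retained"] + removed

    def to_frame(self) -> pd.DataFrame:
        rows = []
        stages = [
            ("metrics", self.removed_metrics),
            ("cohort", self.removed_cohort),
            ("patient_vs_cohort", self.removed_patient_vs_cohort),
            ("patient", self.removed_patient),
        ]
        for stage, samples in stages:
            rows += [(s, f"removed_{stage}") for s in samples]
        rows += [(s, "retained") for s in self.retained]
        return pd.DataFrame(rows, columns=["sample_id", "status"]).set_index("sample_id")


def retained_after(input_count: int, removals: list[int] | tuple[int, ...]) -> int:
    """Retained sample count implied by an input size and per-stage removals."""
    if input_count < 0 or any(r < 0 for r in removals):
        raise ValueError("counts must be nonnegative")
    retained = input_count - sum(removals)
    if retained < 0:
        raise ValueError("removals exceed input count")
    return retained


def initial_metrics_filter(stats: pd.DataFrame) -> tuple[list, list]:
    """Split samples on raw library metrics; a sample fails if ANY criterion holds.

    ``stats`` columns: raw_reads, pct_unique_map, pct_reads_in_genes.
    """
    required = {"raw_reads", "pct_unique_map", "pct_reads_in_genes"}
    missing_cols = required - set(stats.columns)
    if missing_cols:
        raise ValueError(f"missing metrics columns: {sorted(missing_cols)}")
    if stats[sorted(required)].isna().any(axis=None):
        bad = stats.index[stats[sorted(required)].isna().any(axis=1)][0]
        raise ValueError(f"missing metrics for sample {bad!r}")
    fail = (
        (stats["raw_reads"] < 1e6)
        | (stats["pct_unique_map"] < 15.0)
        | (stats["pct_reads_in_genes"] < 5.0)
    )
    return list(stats.index[~fail]), list(stats.index[fail])


def _corr_to_loo_mean(x: np.ndarray) -> np.ndarray:
    """Pearson r of each column to the mean of the remaining columns (vectorized)."""
    g, n = x.shape
    total = x.sum(axis=1, keepdims=True)
    m = (total - x) / (n - 1)  # leave-one-out mean profiles, g x n
    return _colwise_pearson(x, m)


def _colwise_pearson(x: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Pearson r between matching columns of two g x n matrices; NaN if degenerate."""
    g = x.shape[0]
    xm = x.mean(axis=0)
    mm = m.mean(axis=0)
    xc = x - xm[None, :]
    mc = m - mm[None, :]
    cov = (xc * mc).sum(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    sm = np.sqrt((mc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / (sx * sm)
    r[(sx == 0) | (sm == 0)] = np.nan
    return r


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _iterative_filter_naive(expr: pd.DataFrame, threshold: float) -> list:
    """Reference implementation: full recomputation at every step."""
    cols = list(expr.columns)
    x = expr.to_numpy().astype(float)
    if x.shape[1] >= 2 and (x == x[:, [0]]).all():
        return []
    removed: list = []
    while len(cols) >= 3:
        r = _corr_to_loo_mean(x)
        r_eff = np.where(np.isnan(r), -np.inf, r)
        if (r_eff >= threshold).all():
            break
        worst = r_eff.min()
        drop = sorted(c for c, v in zip(cols, r_eff) if v == worst)[0]
        j = cols.index(drop)
        removed.append(drop)
        cols.pop(j)
        x = np.delete(x, j, axis=1)
    return removed


def _iterative_filter(expr: pd.DataFrame, threshold: float) -> list:
    """Drop the least-correlated sample until all meet ``threshold``.

    The mean profile excludes the scored sample and is recomputed after every
    removal. Undefined (zero-variance) correlations are treated as failing.
    Ties on the worst correlation break to the lexicographically smallest ID.

    All correlations against leave-one-out means are expressed through the
    sample Gram matrix, so each removal is O(n) after one O(g n^2) setup;
    equivalence with the direct computation is enforced in the test suite.
    """
    cols = np.asarray(expr.columns, dtype=object)
    x = np.ascontiguousarray(expr.to_numpy().astype(float))
    g, n_total = x.shape
    if n_total >= 2 and (x == x[:, [0]]).all():
        return []  # all-identical class: nothing to remove
    gram = x.T @ x
    s = x.sum(axis=0)  # per-sample gene sums
    q = np.diag(gram).copy()  # per-sample sums of squares
    alive = np.ones(n_total, dtype=bool)
    c = gram.sum(axis=1)  # sum_g x_gj * T_g over alive samples
    removed: list = []
    while alive.sum() >= 3:
        ia = np.flatnonzero(alive)
        n = ia.size
        st = s[ia].sum()  # sum of the pooled profile T over genes
        st2 = c[ia].sum()  # sum of T^2 over genes
        sj, qj, cj = s[ia], q[ia], c[ia]
        cov = (cj - qj) - sj * (st - sj) / g
        varx = qj - sj**2 / g
        vary = (st2 - 2 * cj + qj) - (st - sj) ** 2 / g
        with np.errstate(divide="ignore", invalid="ignore"):
            r = cov / np.sqrt(varx * vary)
        r[(varx <= 0) | (vary <= 0)] = np.nan
        r_eff = np.where(np.isnan(r), -np.inf, r)
        if (r_eff >= threshold).all():
            break
        worst = r_eff.min()
        tied = ia[r_eff == worst]
        j = tied[np.argsort(cols[tied].astype(str))[0]]
        removed.append(cols[j])
        alive[j] = False
        c -= gram[:, j]
    return removed


def iterative_cohort_filter(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> list:
    """Stage 1: per tissue class, iteratively remove cohort outliers."""
    thresholds = thresholds or QCThresholds()
    removed: list = []
    for cls, ids in _class_groups(meta.loc[expr.columns]):
        if len(ids) < 3:
            warnings.warn(f"class {cls} has <3 samples; skipped", stacklevel=2)
            continue
        removed += _iterative_filter(expr[ids], thresholds.cohort_r[cls])
    return removed


def patient_mean_filter(expr: pd.DataFrame, meta: pd.DataFrame) -> list:
    """Stage 2: remove samples closer to the cohort mean than to their patient mean.

    Single-sample patients are exempt; comparisons stay within tissue class.
    """
    removed: list = []
    meta = meta.loc[expr.columns]
    for _cls, ids in _class_groups(meta):
        if len(ids) < 3:
            continue
        x = expr[ids].to_numpy().astype(float)
        n = x.shape[1]
        pats, inv = np.unique(meta.loc[ids, "patient"].to_numpy(), return_inverse=True)
        pat_n = np.bincount(inv)
        multi = pat_n[inv] > 1  # single-sample patients are exempt
        if not multi.any():
            continue
        total = x.sum(axis=1, keepdims=True)
        r_cohort = _colwise_pearson(x, (total - x) / (n - 1))
        pat_sum = np.zeros((x.shape[0], pats.size))
        np.add.at(pat_sum.T, inv, x.T)
        pat_mean = (pat_sum[:, inv] - x) / np.maximum(pat_n[inv] - 1, 1)[None, :]
        r_pat = _colwise_pearson(x, pat_mean)
        worse = multi & (
            (np.isnan(r_pat) & ~np.isnan(r_cohort))
            | (~np.isnan(r_pat) & ~np.isnan(r_cohort) & (r_cohort > r_pat))
        )
        removed += [sid for sid, w in zip(ids, worse) if w]
    return removed


def iterative_patient_filter(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> list:
    """Stage 3: per patient (within tissue class), iteratively remove outliers."""
    thresholds = thresholds or QCThresholds()
    removed: list = []
    meta = meta.loc[expr.columns]
    for cls, ids in _class_groups(meta):
        threshold = thresholds.patient_r[cls]
        sub_meta = meta.loc[ids]
        for _pat, pat_ids in sorted(sub_meta.groupby("patient").groups.items()):
            pat_ids = list(pat_ids)
            if len(pat_ids) < 3:
                continue
            removed += _iterative_filter(expr[pat_ids], threshold)
    return removed


def _class_groups(meta: pd.DataFrame):
    """Deterministically ordered (threshold-class, sample IDs) groups."""
    subtype = meta["subtype"] if "subtype" in meta.columns else pd.Series(index=meta.index, dtype=object)
    cls = pd.Series(
        [_threshold_class(t, s) for t, s in zip(meta["tissue"], subtype)],
        index=meta.index,
    )
    # iterate per tissue (and basal split) in fixed order
    order = {}
    for sid in meta.index:
        key = (meta.at[sid, "tissue"], cls[sid])
        order.setdefault(key, []).append(sid)
    for (tissue, c), ids in sorted(order.items()):
        yield c, ids


def run_qc(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    stats: pd.DataFrame | None = None,
    thresholds: QCThresholds | None = None,
) -> QCReport:
    """Run the full four-stage filter; each stage sees the previous survivors."""
    thresholds = thresholds or QCThresholds()
    all_samples = list(expr.columns)
    if stats is not None:
        passed, failed0 = initial_metrics_filter(stats.loc[all_samples])
    else:
        passed, failed0 = all_samples, []
    expr1 = expr[passed]
    removed1 = iterative_cohort_filter(expr1, meta, thresholds)
    expr2 = expr1.drop(columns=removed1)
    removed2 = patient_mean_filter(expr2, meta)
    expr3 = expr2.drop(columns=removed2)
    removed3 = iterative_patient_filter(expr3, meta, thresholds)
    retained = [s for s in expr3.columns if s not in set(removed3)]
    report = QCReport(
        input_samples=all_samples,
        removed_metrics=list(failed0),
        removed_cohort=removed1,
        removed_patient_vs_cohort=removed2,
        removed_patient=removed3,
        retained=retained,
    )
    assert report.check_conservation()
    return report
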