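"""Receptor calls, per-patient marker calls and the progression-hazard tree.

The decision tree stratifies DCIS-bearing patients by a small marker panel:
CAMK2N1 anchors the tree (low expression is IDC-associated in every part of
the continuum); the four "progressor" genes MNX1, HOXC11, ANKRD22 and ADCY5
are tallied (low = IDC-associated); SCGB2A1 refines the low-tally branch
(HIGH = IDC-associated); THRSP marks a mitigating state inside the high-tally
branch. A patient's call for a gene requires at least two DCIS samples on the
IDC-associated side of the gene's expression cut; patients with a single
usable sample stay Unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ReceptorThresholds:
    """log2-CPM positivity cuts for the three receptor transcripts."""

    esr1: float = 6.0
    pgr: float = 6.0
    erbb2: float = 10.5


def receptor_status_call(
    expr: pd.DataFrame, thresholds: ReceptorThresholds | None = None
) -> pd.DataFrame:
    """Per-sample ER/PR/Her2 status from ESR1/PGR/ERBB2 log2-CPM.

    Positive iff expression >= threshold (boundary counts as positive);
    ``triple_negative`` flags samples negative for all three.
    """
    thresholds = thresholds or ReceptorThresholds()
    for gene in ("ESR1", "PGR", "ERBB2"):
        if gene not in expr.index:
            raise KeyError(f"receptor gene {gene!r} absent from expression matrix")
    out = pd.DataFrame(
        {
            "ER": expr.loc["ESR1"] >= thresholds.esr1,
            "PR": expr.loc["PGR"] >= thresholds.pgr,
            "Her2": expr.loc["ERBB2"] >= thresholds.erbb2,
        }
    )
    out["triple_negative"] = ~out[["ER", "PR", "Her2"]].any(axis=1)
    return out


PROGRESSOR_GENES = ("MNX1", "HOXC11", "ANKRD22", "ADCY5")


@dataclass(frozen=True)
class MarkerPanel:
    """Marker genes, their expression cuts and IDC-associated directions.

    ``cuts`` maps gene -> log2-CPM threshold; by default (empty) cuts are
    derived from pooled per-gene medians of the data at call time.
    """

    anchor: str = "CAMK2N1"
    progressors: tuple = PROGRESSOR_GENES
    refiner: str = "SCGB2A1"
    rescuer: str = "THRSP"
    directions: dict = field(
        default_factory=lambda: {
            "CAMK2N1": "low",
            "MNX1": "low",
            "HOXC11": "low",
            "ANKRD22": "low",
            "ADCY5": "low",
            "SCGB2A1": "high",
            "THRSP": "low",
        }
    )
    cuts: dict = field(default_factory=dict)

    @property
    def genes(self) -> tuple:
        return (self.anchor, *self.progressors, self.refiner, self.rescuer)

    def with_median_cuts(self, expr: pd.DataFrame) -> "MarkerPanel":
        """Fill missing cuts with pooled per-gene medians."""
        cuts = dict(self.cuts)
        for g in self.genes:
            if g not in cuts:
                cuts[g] = float(expr.loc[g].median())
        return replace(self, cuts=cuts)


class HazardGroup(str, Enum):
    LOWER = "LowerHazard"
    HIGHER = "HigherHazard"
    INDETERMINATE = "Indeterminate"
    UNASSIGNED = "Unassigned"


def patient_marker_status(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    gene: str,
    cut: float,
    idc_associated_direction: str = "low",
    min_samples: int = 2,
) -> pd.Series:
    """Per-patient IDC-association call for one marker gene.

    Uses DCIS samples only. A patient is called IDC-associated (True) iff at
    least ``min_samples`` of their samples fall on the IDC-associated side of
    ``cut`` (strictly below for ``"low"``, at-or-above for ``"high"``).
    Patients with exactly one usable sample get ``None`` (Unassigned).
    """
    if gene not in expr.index:
        raise KeyError(f"marker gene {gene!r} absent from expression matrix")
    dcis = meta.index[meta["tissue"] == "DCIS"].intersection(expr.columns)
    vals = expr.loc[gene, dcis]
    if idc_associated_direction == "low":
        on_side = vals < cut
    elif idc_associated_direction == "high":
        on_side = vals >= cut
    else:
        raise ValueError("direction must be 'low' or 'high'")
    out = {}
    for pat, ids in meta.loc[dcis].groupby("patient").groups.items():
        if len(ids) < 2:
            out[pat] = None
        else:
            out[pat] = bool(on_side[list(ids)].sum() >= min_samples)
    return pd.Series(out, name=gene, dtype=object)


def progressor_tally(calls: pd.DataFrame) -> pd.Series:
    """Number of progressor genes called IDC-associated (down) per patient.

    ``calls`` columns are the four progressor genes; a missing (None) call
    propagates to a missing tally.
    """
    missing = [g for g in PROGRESSOR_GENES if g not in calls.columns]
    if missing:
        raise ValueError(f"missing progressor calls: {missing}")
    sub = calls[list(PROGRESSOR_GENES)]
    tally = sub.sum(axis=1).astype("object")
    tally[sub.isna().any(axis=1)] = None
    return tally.rename("progressor_tally")


def assign_hazard(
    anchor_call, tally, refiner_call, rescuer_call=None
) -> tuple[HazardGroup, bool]:
    """Decision tree for one patient; returns (group, mitigated-by-rescuer).

    Rules: anchor low (IDC-associated) -> HigherHazard; tally 3-4 ->
    HigherHazard, with the rescuer state (THRSP high) recorded as mitigating
    inside that branch; tally 0-1 -> LowerHazard unless the refiner is
    IDC-associated (SCGB2A1 high), which pushes to HigherHazard; tally 2 is
    not covered by the printed rules and stays Indeterminate. Unresolvable
    calls give Unassigned.
    """
    if anchor_call is None or (tally is None and anchor_call is not True):
        return HazardGroup.UNASSIGNED, False
    if anchor_call:
        return HazardGroup.HIGHER, False
    if tally in (3, 4):
        mitigated = rescuer_call is False and refiner_call is False
        return HazardGroup.HIGHER, mitigated
    if tally in (0, 1):
        if refiner_call is None:
            return HazardGroup.UNASSIGNED, False
        if refiner_call:  # SCGB2A1 high, IDC-associated
            return HazardGroup.HIGHER, False
        return HazardGroup.LOWER, False
    return HazardGroup.INDETERMINATE, False


def hazard_assignments(
    expr: pd.DataFrame, meta: pd.DataFrame, panel: MarkerPanel | None = None
) -> pd.DataFrame:
    """Per-patient marker calls, tally and hazard group for all DCIS patients."""
    panel = (panel or MarkerPanel()).with_median_cuts(expr)
    calls = {}
    for g in panel.genes:
        calls[g] = patient_marker_status(
            expr, meta, g, panel.cuts[g], panel.directions[g]
        )
    calls_df = pd.DataFrame(calls)
    rows = []
    for pat, row in calls_df.iterrows():
        tally_row = row[list(panel.progressors)]
        tally = None if tally_row.isna().any() else int(tally_row.sum())
        group, mitigated = assign_hazard(
            row[panel.anchor], tally, row[panel.refiner], row[panel.rescuer]
        )
        rows.append(
            {
                "patient": pat,
                "anchor_call": row[panel.anchor],
                "progressor_tally": tally,
                "refiner_call": row[panel.refiner],
                "rescuer_call": row[panel.rescuer],
                "group": group.value,
                "rescuer_mitigated": mitigated,
            }
        )
    return pd.DataFrame(rows).set_index("patient")


def fold_from_proportions(prop_a: float, prop_b: float) -> float:
    """Enrichment fold between two group-membership proportions, one decimal."""
    if prop_b == 0:
        return float("inf")
    return round(prop_a / prop_b, 1)


def enrichment_fold(
    groups: pd.Series, outcomes: pd.Series, group: str, outcome_a: str, outcome_b: str
) -> dict:
    """Fold enrichment of ``outcome_a`` over ``outcome_b`` patients in ``group``.

    Each proportion is the fraction of that outcome's patients falling in the
    group; fold = proportion_a / proportion_b, reported to one decimal.
    """
    outcomes = outcomes.reindex(groups.index)
    n_a = int((outcomes == outcome_a).sum())
    n_b = int((outcomes == outcome_b).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both outcome classes must be present")
    in_group = groups == group
    prop_a = float((in_group & (outcomes == outcome_a)).sum()) / n_a
    prop_b = float((in_group & (outcomes == outcome_b)).sum()) / n_b
    return {
        "fold": fold_from_proportions(prop_a, prop_b),
        "prop_a": prop_a,
        "prop_b": prop_b,
        "n_a": n_a,
        "n_b": n_b,
    }


@dataclass
class EcdfComparison:
    ecdf_a: tuple  # (sorted values, cumulative fractions)
    ecdf_b: tuple
    table: np.ndarray  # 2x2 counts (group x below/at-or-above cut)
    odds_ratio: float
    p: float
    cut: float


def ecdf_fisher_compare(
    values_a: pd.Series | np.ndarray,
    values_b: pd.Series | np.ndarray,
    dichotomize_at: float | None = None,
) -> EcdfComparison:
    """Two-sided Fisher's exact test on dichotomized expression plus ECDFs.

    The dichotomization point defaults to the pooled median. A degenerate
    table (an empty margin) returns p = 1 with a warning.
    """
    a = np.sort(np.asarray(values_a, dtype=float))
    b = np.sort(np.asarray(values_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    cut = float(np.median(np.concatenate([a, b]))) if dichotomize_at is None else float(dichotomize_at)
    table = np.array(
        [[(a < cut).sum(), (a >= cut).sum()], [(b < cut).sum(), (b >= cut).sum()]]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        import warnings

        warnings.warn("degenerate 2x2 margin; p set to 1", stacklevel=2)
        odds, p = float("nan"), 1.0
    else:
        odds, p = stats.fisher_exact(table, alternative="two-sided")
    return EcdfComparison(
        ecdf_a=(a, np.arange(1, a.size + 1) / a.size),
        ecdf_b=(b, np.arange(1, b.size + 1) / b.size),
        table=table,
        odds_ratio=float(odds),
        p=float(p),
        cut=cut,
    )
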