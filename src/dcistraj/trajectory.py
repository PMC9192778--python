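"""Panel-based PCA, principal-curve fitting, and pseudotime ordering.

The progression coordinate is the arc-length position of each sample after
projection onto a principal curve fitted in the first two principal components
of a small discriminative gene panel (the principal curve projection, PCP).
The curve is fitted with the classic Hastie-Stuetzle alternation: smooth each
coordinate against the current arc-length parameter, project samples onto the
resulting polyline, and re-parameterize by cumulative arc length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess


@dataclass
class PCAModel:
    """Column-centered SVD PCA fitted on a designated sample set."""

    mean_: np.ndarray  # per-gene centering vector (fitting set)
    components_: np.ndarray  # k x n_genes, orthonormal rows
    explained_variance_ratio_: np.ndarray
    genes: pd.Index

    def transform(self, expr: pd.DataFrame) -> pd.DataFrame:
        """Project samples (columns of ``expr``) with the fitting-set centering."""
        x = expr.loc[self.genes].to_numpy().T - self.mean_[None, :]
        scores = x @ self.components_.T
        cols = [f"pc{i + 1}" for i in range(scores.shape[1])]
        return pd.DataFrame(scores, index=expr.columns, columns=cols)


@dataclass
class CurveModel:
    """Fitted principal curve with per-sample arc-length projections."""

    vertices: np.ndarray  # ordered polyline vertices in PC space
    arc_length: np.ndarray  # cumulative arc length per vertex
    positions: pd.Series  # arc-length position per sample (PCP position)
    distances: pd.Series  # perpendicular distance per sample
    converged: bool
    n_iter: int
    mse_history: list = field(default_factory=list)


@dataclass(frozen=True)
class SegmentBoundaries:
    """E1/E2/L1/L2 placed as rank quantiles along the ordered samples."""

    e1: float = 0.15
    e2: float = 0.45
    l1: float = 0.55
    l2: float = 0.85

    def __post_init__(self) -> None:
        if not (0 <= self.e1 < self.e2 <= self.l1 < self.l2 <= 1):
            raise ValueError("boundaries must satisfy E1 < E2 <= L1 < L2 in [0, 1]")


SEGMENT_LABELS = ("pre-E1", "E1-E2", "mid", "L1-L2", "post-L2")


def pca_embed_panel(
    expr: pd.DataFrame,
    panel,
    fit_samples,
    all_samples=None,
    n_components: int = 2,
) -> tuple[PCAModel, pd.DataFrame]:
    """Fit PCA on ``fit_samples`` over ``panel`` genes; embed ``all_samples``."""
    panel = pd.Index(panel)
    missing = panel.difference(expr.index)
    if len(missing):
        raise KeyError(f"panel genes absent from expression matrix: {list(missing)[:5]}")
    if all_samples is None:
        all_samples = list(expr.columns)
    if not set(fit_samples) <= set(all_samples):
        raise ValueError("fit_samples must be a subset of all_samples")
    xfit = expr.loc[panel, fit_samples].to_numpy().T
    mean = xfit.mean(axis=0)
    xc = xfit - mean[None, :]
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(n_components, vt.shape[0])
    var = s**2 / max(xfit.shape[0] - 1, 1)
    ratio = var / var.sum() if var.sum() > 0 else var
    model = PCAModel(
        mean_=mean,
        components_=vt[:k],
        explained_variance_ratio_=ratio[:k],
        genes=panel,
    )
    coords = model.transform(expr[list(all_samples)])
    return model, coords


def _project_to_polyline(points: np.ndarray, vertices: np.ndarray, chunk: int = 512):
    """Orthogonal projection of points onto a polyline.

    Returns (arc positions, squared distances). Vectorized over segments with
    chunking over points to bound memory.
    """
    seg_a = vertices[:-1]  # (m, d)
    seg_v = vertices[1:] - vertices[:-1]
    seg_len2 = np.maximum((seg_v**2).sum(axis=1), 1e-300)
    seg_len = np.sqrt((seg_v**2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    pos = np.empty(points.shape[0])
    d2 = np.empty(points.shape[0])
    for start in range(0, points.shape[0], chunk):
        p = points[start : start + chunk]  # (c, d)
        diff = p[:, None, :] - seg_a[None, :, :]  # (c, m, d)
        t = np.clip((diff * seg_v[None, :, :]).sum(-1) / seg_len2[None, :], 0.0, 1.0)
        proj = seg_a[None, :, :] + t[:, :, None] * seg_v[None, :, :]
        dist2 = ((p[:, None, :] - proj) ** 2).sum(-1)
        best = dist2.argmin(axis=1)
        rows = np.arange(p.shape[0])
        pos[start : start + chunk] = cum[best] + t[rows, best] * seg_len[best]
        d2[start : start + chunk] = dist2[rows, best]
    return pos, d2


def fit_principal_curve(
    points: pd.DataFrame | np.ndarray,
    span: float = 0.6,
    max_iter: int = 30,
    tol: float = 2e-3,
) -> CurveModel:
    """Hastie-Stuetzle principal curve through 2-D (or d-D) points.

    Positions are initialized by the first coordinate (PC1); each iteration
    smooths every coordinate against arc-length position with a lowess
    smoother (``span`` fraction), projects points back to the smoothed
    polyline, and re-parameterizes by cumulative arc length, until the mean
    squared projection distance changes by less than ``tol`` (relative).
    """
    if isinstance(points, pd.DataFrame):
        index = points.index
        x = points.to_numpy().astype(float)
    else:
        x = np.asarray(points, dtype=float)
        index = pd.RangeIndex(x.shape[0])
    if x.shape[0] < 10:
        raise ValueError("need at least 10 points")
    if not np.isfinite(x).all():
        raise ValueError("points must be finite")

    # initialize along the leading principal axis of the point cloud itself
    # (coincides with PC1 when the points are PCA scores of the fitting set,
    # but stays well-defined when the embedded cloud is oriented differently)
    xc = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    lam = xc @ vt[0]
    if np.corrcoef(lam, x[:, 0])[0, 1] < 0:
        lam = -lam  # keep orientation aligned with the first coordinate
    mse_prev = np.inf
    mse_hist: list = []
    converged = False
    vertices = None
    pos = lam
    d2 = np.zeros(x.shape[0])
    it = 0
    for it in range(1, max_iter + 1):
        order = np.lexsort((np.arange(x.shape[0]), lam))
        lam_s = lam[order]
        smoothed = np.column_stack(
            [lowess(x[order, j], lam_s, frac=span, it=0, return_sorted=False) for j in range(x.shape[1])]
        )
        # collapse duplicate consecutive vertices
        keep = np.ones(smoothed.shape[0], dtype=bool)
        keep[1:] = (np.abs(np.diff(smoothed, axis=0)).sum(axis=1)) > 1e-12
        vertices = smoothed[keep]
        if vertices.shape[0] < 2:
            vertices = np.vstack([smoothed[0], smoothed[-1] + 1e-9])
        pos, d2 = _project_to_polyline(x, vertices)
        mse = d2.mean()
        mse_hist.append(mse)
        lam = pos
        denom = max(mse_prev, 1e-12)
        if np.isfinite(mse_prev) and abs(mse_prev - mse) / denom < tol:
            converged = True
            break
        mse_prev = mse
    if not converged:
        warnings.warn("principal curve did not converge; returning best iterate", stacklevel=2)

    seg_len = np.sqrt((np.diff(vertices, axis=0) ** 2).sum(axis=1))
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    return CurveModel(
        vertices=vertices,
        arc_length=arc,
        positions=pd.Series(pos, index=index, name="pcp_position"),
        distances=pd.Series(np.sqrt(d2), index=index, name="pcp_distance"),
        converged=converged,
        n_iter=it,
        mse_history=mse_hist,
    )


def order_samples(
    curve: CurveModel,
    tissue: pd.Series | None = None,
    start_tissues: tuple = ("normal", "benign"),
    end_tissue: str = "IDC",
) -> pd.DataFrame:
    """Sort samples by arc-length position, oriented so normal/benign come first.

    When the mean position of ``start_tissues`` exceeds that of ``end_tissue``
    the axis is flipped (positions become ``total_length - position``). Ties
    break by sample ID.
    """
    pos = curve.positions.copy()
    total = float(curve.arc_length[-1])
    if tissue is not None:
        tissue = tissue.reindex(pos.index)
        start_mean = pos[tissue.isin(start_tissues)].mean()
        end_mean = pos[tissue == end_tissue].mean()
        if np.isfinite(start_mean) and np.isfinite(end_mean) and start_mean > end_mean:
            pos = total - pos
    out = pd.DataFrame({"pcp_position": pos})
    out["_sid"] = out.index.astype(str)
    out = out.sort_values(["pcp_position", "_sid"], kind="stable").drop(columns="_sid")
    out["pcp_rank"] = np.arange(len(out))
    return out


def segment_positions(order: pd.DataFrame, boundaries: SegmentBoundaries | None = None) -> pd.Series:
    """Label each ordered sample by PCP segment using rank-quantile boundaries.

    Intervals are left-closed: a sample exactly at E1 belongs to ``E1-E2``.
    """
    boundaries = boundaries or SegmentBoundaries()
    n = len(order)
    ranks = order["pcp_rank"].to_numpy()
    cuts = np.array([boundaries.e1, boundaries.e2, boundaries.l1, boundaries.l2]) * n
    labels = np.array(SEGMENT_LABELS, dtype=object)
    idx = np.searchsorted(cuts, ranks, side="right")
    return pd.Series(labels[idx], index=order.index, name="segment")


def compare_group_positions(
    positions: pd.Series, status: pd.Series, group_a: str, group_b: str
) -> tuple[float, float]:
    """Welch two-sample t-test on PCP positions between two patient-status groups.

    Returns ``(mean_a - mean_b, two-sided p)``.
    """
    status = status.reindex(positions.index)
    a = positions[status == group_a].to_numpy()
    b = positions[status == group_b].to_numpy()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 samples")
    diff = float(a.mean() - b.mean())
    se2 = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size
    if se2 == 0:
        return diff, 1.0 if diff == 0 else 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return diff, float(res.pvalue)


def spearman_tissue_trend(
    expr_gene: pd.Series, tissue: pd.Series, order: tuple = ("normal", "benign", "atypia", "DCIS", "IDC")
) -> tuple[float, float]:
    """Spearman correlation of one gene's expression with ordinal tissue grade.

    Two-sided p, uncorrected. Constant expression returns ``(nan, nan)``.
    """
    tissue = tissue.reindex(expr_gene.index)
    codes = tissue.map({t: i for i, t in enumerate(order)})
    if codes.isna().any():
        raise ValueError("unknown tissue label")
    if codes.nunique() < 2:
        raise ValueError("need at least two distinct tissue levels")
    x = expr_gene.to_numpy().astype(float)
    if np.all(x == x[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, codes.to_numpy())
    return float(rho), float(p)
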