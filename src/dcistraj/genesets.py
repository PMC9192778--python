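"""Per-sample gene-set scoring and enrichment along the pseudotime order.

Three tools:

* :func:`ssgsea_scores` — single-sample GSEA: per sample, a rank-weighted
  running-sum statistic contrasting the empirical CDF of in-set genes
  (weighted by rank^alpha) against the unweighted CDF of out-of-set genes.
* :func:`window_enrichment_scan` — slide a fixed-size window along the
  ordered samples, call genes up-regulated in the window versus all remaining
  samples, and test each gene set for over-representation among those genes
  with a one-sided hypergeometric test (BH-corrected across sets per window).
* :func:`bootstrap_trend` — OLS of any per-sample score on pseudotime
  position with residual-resampling bootstrap confidence bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


def read_gmt(path: str | Path) -> dict[str, set]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = {g for g in fields[2:] if g}
    if not sets:
        raise ValueError("empty GMT file")
    return sets


def write_gmt(sets: dict, path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(genes)]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class ScanConfig:
    """Sliding-window scan parameters."""

    window: int = 100
    step: int = 50
    fdr_alpha: float = 1e-5  # significance cut on window-level adjusted p
    de_alpha: float = 0.05  # within-window DE cut (adjusted p) for the hit list
    ssgsea_alpha: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.window:
            raise ValueError("need 0 < step <= window")
        if not (0 < self.fdr_alpha <= 1 and 0 < self.de_alpha <= 1):
            raise ValueError("alphas must be in (0, 1]")
        if self.ssgsea_alpha <= 0:
            raise ValueError("ssgsea_alpha must be positive")


def _ssgsea_sample(order_desc: np.ndarray, ranks: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Un-normalized ssGSEA enrichment score for one sample.

    ``order_desc`` indexes genes from highest to lowest expression; ``ranks``
    are 1..N with N the highest-expressed gene.
    """
    sel = in_set[order_desc]
    w = ranks[order_desc].astype(float) ** alpha
    w_in = np.where(sel, w, 0.0)
    denom_in = w_in.sum()
    n_out = (~sel).sum()
    if denom_in == 0 or n_out == 0:
        return 0.0
    cdf_in = np.cumsum(w_in) / denom_in
    cdf_out = np.cumsum((~sel).astype(float)) / n_out
    return float(np.sum(cdf_in - cdf_out))


def ssgsea_scores(
    expr: pd.DataFrame,
    sets: dict,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """ssGSEA score matrix (sets x samples).

    Scores are rank-based, hence invariant to any strictly monotone transform
    of the expression values within a sample. With ``normalize=True`` the
    whole matrix is divided by its score range (max - min), the standard
    ssGSEA normalization; otherwise raw running-sum scores are returned.
    Sets with fewer than 2 expressed genes are skipped with a warning.
    """
    genes = expr.index
    usable = {}
    for name, members in sets.items():
        present = genes.isin(set(members))
        if present.sum() < 2:
            warnings.warn(f"gene set {name!r} has <2 expressed genes; skipped", stacklevel=2)
            continue
        usable[name] = present
    if not usable:
        raise ValueError("no usable gene sets")
    x = expr.to_numpy()
    n_genes, n_samples = x.shape
    out = np.zeros((len(usable), n_samples))
    set_masks = list(usable.values())
    for j in range(n_samples):
        ranks = stats.rankdata(x[:, j], method="average")
        order_desc = np.argsort(-ranks, kind="stable")
        for i, mask in enumerate(set_masks):
            out[i, j] = _ssgsea_sample(order_desc, ranks, mask, alpha)
    scores = pd.DataFrame(out, index=pd.Index(usable.keys(), name="set"), columns=expr.columns)
    if normalize:
        rng_ = scores.to_numpy().max() - scores.to_numpy().min()
        if rng_ > 0:
            scores = scores / rng_
    return scores


def hypergeom_enrichment(n_background: int, n_set: int, n_hits: int, n_overlap: int) -> tuple[float, float]:
    """One-sided over-representation (fold, p) for a window hit-list vs a set."""
    if n_hits == 0 or n_set == 0:
        return 0.0, 1.0
    fold = (n_overlap / n_hits) / (n_set / n_background)
    p = float(stats.hypergeom.sf(n_overlap - 1, n_background, n_set, n_hits))
    return float(fold), p


def window_starts(n_samples: int, window: int, step: int) -> list[int]:
    """0-based start ranks of full windows tiling the order."""
    if n_samples < window:
        raise ValueError("fewer samples than window size")
    return list(range(0, n_samples - window + 1, step))


def window_enrichment_scan(
    order: pd.DataFrame,
    sets: dict,
    de_engine,
    config: ScanConfig | None = None,
    background: pd.Index | None = None,
) -> pd.DataFrame:
    """Scan gene-set over-representation along the PCP order.

    ``order`` is the ordered-sample frame from :func:`~dcistraj.trajectory.order_samples`;
    ``de_engine(window_ids, rest_ids)`` must return a per-gene DataFrame with
    ``log2_fc`` (positive = up in window) and ``adj_p`` columns. The final
    partial window is dropped. Per window, up-regulated genes at
    ``adj_p < config.de_alpha`` are tested per set with a one-sided
    hypergeometric against the full gene background, BH-corrected across sets.
    """
    from .diffexp import bh_adjust

    config = config or ScanConfig()
    ordered_ids = list(order.sort_values("pcp_rank").index)
    starts = window_starts(len(ordered_ids), config.window, config.step)
    rows = []
    for start in starts:
        win = ordered_ids[start : start + config.window]
        rest = ordered_ids[:start] + ordered_ids[start + config.window :]
        de = de_engine(win, rest)
        bg = background if background is not None else de.index
        de = de.loc[de.index.intersection(bg)]
        hits = set(de.index[(de["log2_fc"] > 0) & (de["adj_p"] < config.de_alpha)])
        n_bg = len(de.index)
        folds, ps, names, sizes, overlaps = [], [], [], [], []
        for name, members in sets.items():
            members = set(members) & set(de.index)
            overlap = len(members & hits)
            fold, p = hypergeom_enrichment(n_bg, len(members), len(hits), overlap)
            names.append(name)
            folds.append(fold)
            ps.append(p)
            sizes.append(len(members))
            overlaps.append(overlap)
        adj = bh_adjust(np.array(ps)) if ps else np.array([])
        for k, name in enumerate(names):
            rows.append(
                {
                    "window_start_rank": start,
                    "window_end_rank": start + config.window - 1,
                    "set": name,
                    "set_size": sizes[k],
                    "n_hits": len(hits),
                    "n_overlap": overlaps[k],
                    "fold": folds[k],
                    "p": ps[k],
                    "adj_p": adj[k],
                    "significant": adj[k] < config.fdr_alpha,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class TrendFit:
    """OLS trend of a per-sample score on pseudotime, with bootstrap bands."""

    slope: float
    intercept: float
    r_squared: float
    slope_ci: tuple[float, float]
    r_squared_ci: tuple[float, float]
    grid: np.ndarray  # positions at which the fitted band is evaluated
    fitted: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    n_boot: int


def bootstrap_trend(
    score: pd.Series | np.ndarray,
    positions: pd.Series | np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
    ci: float = 0.95,
    n_grid: int = 100,
) -> TrendFit:
    """Linear trend of ``score`` on ``positions`` with residual-resampling bootstrap.

    Residuals from the OLS fit are resampled with replacement and added back
    to the fitted values ``n_boot`` times; percentile intervals are reported
    for the slope, r^2 and the fitted line on an even position grid.
    """
    y = np.asarray(score, dtype=float)
    x = np.asarray(positions, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 samples")
    if np.ptp(x) == 0:
        raise ValueError("constant positions")
    slope, intercept, r, _, _ = stats.linregress(x, y)
    fitted = intercept + slope * x
    resid = y - fitted
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    sxx = (xc**2).sum()
    grid = np.linspace(x.min(), x.max(), n_grid)
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    slopes = np.empty(n_boot)
    r2s = np.empty(n_boot)
    band = np.empty((n_boot, n_grid))
    chunk = max(1, int(5e6 // max(y.size, 1)))
    for start in range(0, n_boot, chunk):
        m = min(chunk, n_boot - start)
        res_b = resid[rng.integers(0, y.size, size=(m, y.size))]
        yb = fitted[None, :] + res_b
        ybc = yb - yb.mean(axis=1, keepdims=True)
        b = (ybc * xc[None, :]).sum(axis=1) / sxx
        a = yb.mean(axis=1) - b * x.mean()
        pred = a[:, None] + b[:, None] * x[None, :]
        ssr = ((yb - pred) ** 2).sum(axis=1)
        sst = (ybc**2).sum(axis=1)
        r2 = np.where(sst > 0, 1 - ssr / sst, 0.0)
        slopes[start : start + m] = b
        r2s[start : start + m] = r2
        band[start : start + m] = a[:, None] + b[:, None] * grid[None, :]
    return TrendFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r**2),
        slope_ci=(float(np.quantile(slopes, lo_q)), float(np.quantile(slopes, hi_q))),
        r_squared_ci=(float(np.quantile(r2s, lo_q)), float(np.quantile(r2s, hi_q))),
        grid=grid,
        fitted=intercept + slope * grid,
        band_lo=np.quantile(band, lo_q, axis=0),
        band_hi=np.quantile(band, hi_q, axis=0),
        n_boot=n_boot,
    )
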