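"""Moderated two-group differential expression on RNA-seq counts.

The model follows the limma-voom lineage: per-gene linear models on log2-CPM
with (a) observation-level precision weights from a fitted mean-variance
trend, (b) a single consensus intra-patient correlation used in generalized
least squares to absorb replicate sections from the same patient, and (c)
empirical-Bayes shrinkage of residual variances toward a pooled prior before
moderated t-statistics. Two weight-estimation passes bracket the correlation
estimate (weights, then correlation, then weights again under GLS).

Sign convention: ``log2_fc > 0`` means higher expression in the *second*
factor level (levels sorted, or as given in ``group_order``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.nonparametric.smoothers_lowess import lowess

from .preprocess import NormFactors, log_cpm, tmm_factors


@dataclass
class DEResult:
    """Per-gene DE table plus the fitted global hyperparameters."""

    table: pd.DataFrame  # columns: log2_fc, t, p, adj_p, mean_logcpm
    consensus_correlation: float
    prior_df: float
    prior_var: float
    group_order: tuple

    def __getitem__(self, col):
        return self.table[col]


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration, limma-style)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif / x) < 1e-8:
            break
    return float(x)


def squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit a scaled inverse-chi-square prior to sample variances.

    Returns ``(prior_df, prior_var)``; ``prior_df`` is ``inf`` when the
    observed variances are less dispersed than chi-square sampling alone
    implies.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-12)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0 = np.exp(emean)
    return float(d0), float(s0)


def _block_whiten(a: np.ndarray, blocks: np.ndarray, rho: float) -> np.ndarray:
    """Apply R^{-1/2} within equicorrelated sample blocks, rows = genes.

    R = (1-rho) I + rho J per block; R^{-1/2} acts as
    ``alpha (v - vbar 1) + beta vbar 1`` with ``alpha = (1-rho)^{-1/2}`` and
    ``beta = (1 + (n_b - 1) rho)^{-1/2}``.
    """
    if rho == 0.0:
        return a
    out = a.astype(float).copy()
    alpha = 1.0 / np.sqrt(1.0 - rho)
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        nb = idx.size
        if nb == 1:
            continue
        beta = 1.0 / np.sqrt(1.0 + (nb - 1) * rho)
        sub = out[:, idx]
        m = sub.mean(axis=1, keepdims=True)
        out[:, idx] = alpha * (sub - m) + beta * m
    return out


def consensus_correlation(
    resid: np.ndarray, patients: np.ndarray, expression_rank: np.ndarray, top_frac: float = 0.10
) -> float:
    """Consensus intra-patient correlation from per-gene intraclass correlations.

    One-way ANOVA ICC per gene on residuals grouped by patient, averaged on
    the Fisher z-scale over the ``top_frac`` most-expressed genes.
    """
    n_top = max(10, int(np.ceil(top_frac * resid.shape[0])))
    top = np.argsort(expression_rank)[::-1][: min(n_top, resid.shape[0])]
    r = resid[top]
    pats, inv = np.unique(patients, return_inverse=True)
    a = pats.size
    n = patients.size
    if a >= n or a < 2:
        return 0.0
    counts = np.bincount(inv).astype(float)
    sums = np.zeros((r.shape[0], a))
    np.add.at(sums.T, inv, r.T)
    group_means = sums / counts[None, :]
    grand = r.mean(axis=1, keepdims=True)
    ssb = (counts[None, :] * (group_means - grand) ** 2).sum(axis=1)
    sst = ((r - grand) ** 2).sum(axis=1)
    ssw = sst - ssb
    msb = ssb / (a - 1)
    msw = np.maximum(ssw / (n - a), 1e-12)
    k0 = (n - (counts**2).sum() / n) / (a - 1)
    icc = (msb - msw) / (msb + (k0 - 1) * msw)
    icc = np.clip(icc, -0.99, 0.99)
    rho = float(np.tanh(np.mean(np.arctanh(icc))))
    max_block = counts.max()
    lo = -0.9 / max(max_block - 1, 1)
    return float(np.clip(rho, lo, 0.99))


def _lowess_trend(sx: np.ndarray, sy: np.ndarray, frac: float = 0.5):
    """Fitted lowess curve returned as an interpolator over sx."""
    fit = lowess(sy, sx, frac=frac, it=3, return_sorted=True)
    xs, ys = fit[:, 0], fit[:, 1]
    ys = np.maximum(ys, 1e-6)

    def predict(x: np.ndarray) -> np.ndarray:
        return np.interp(x, xs, ys)

    return predict


def _ls_fit_2col(xw1: np.ndarray, xw2: np.ndarray, yw: np.ndarray):
    """Per-gene least squares for a two-column design, all arrays genes x n."""
    a = (xw1 * xw1).sum(axis=1)
    b = (xw1 * xw2).sum(axis=1)
    c = (xw2 * xw2).sum(axis=1)
    d = (xw1 * yw).sum(axis=1)
    e = (xw2 * yw).sum(axis=1)
    det = a * c - b * b
    beta1 = (c * d - b * e) / det
    beta2 = (a * e - b * d) / det
    rss = (yw * yw).sum(axis=1) - beta1 * d - beta2 * e
    se2_unscaled = a / det
    return beta1, beta2, np.maximum(rss, 0.0), se2_unscaled


def fit_de(
    counts: pd.DataFrame,
    groups: pd.Series,
    patient: pd.Series | None = None,
    factors: NormFactors | None = None,
    group_order: tuple | None = None,
    moderate: bool = True,
    use_weights: bool = True,
    correlation: float | None = None,
) -> DEResult:
    """Two-group moderated DE with precision weights and patient blocking.

    Parameters
    ----------
    counts : genes x samples raw counts (already gene-filtered).
    groups : two-level factor per sample.
    patient : blocking factor; ``None`` disables the correlation step.
    factors : TMM factors; computed from ``counts`` when omitted.
    group_order : explicit (reference, test) levels; ``log2_fc > 0`` means
        higher in the second level.
    moderate : apply empirical-Bayes variance shrinkage.
    use_weights : apply voom-style precision weights.
    correlation : fix the consensus correlation instead of estimating it.
    """
    groups = groups.reindex(counts.columns)
    if groups.isna().any():
        raise ValueError("groups must cover all samples")
    levels = tuple(group_order) if group_order else tuple(sorted(groups.unique()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    g = (groups == levels[1]).to_numpy().astype(float)
    if g.sum() == 0 or g.sum() == len(g):
        raise ValueError("both groups must be nonempty")

    pats = None
    if patient is not None:
        pats = patient.reindex(counts.columns).to_numpy()
        if pd.isna(pats).any():
            raise ValueError("patient labels must cover all samples")
        for lev, sel in ((levels[0], g == 0), (levels[1], g == 1)):
            if np.unique(pats[sel]).size == 1 and np.unique(pats).size > 1:
                raise ValueError(
                    f"group {lev!r} lies entirely within one patient; effect confounded"
                )

    if factors is None:
        factors = tmm_factors(counts)
    eff_lib = factors.effective_lib_size.reindex(counts.columns).to_numpy()
    y = log_cpm(counts, factors).to_numpy()
    n = y.shape[1]
    x1 = np.ones(n)
    x2 = g
    log_adj = np.log2(eff_lib + 1.0) - np.log2(1e6)
    mean_logcpm = y.mean(axis=1)
    df_resid = n - 2

    def weighted_fit(w: np.ndarray, rho: float):
        sw = np.sqrt(w)
        yw = _block_whiten(y * sw, pats, rho) if pats is not None else y * sw
        xw1 = sw * x1[None, :]
        xw2 = sw * x2[None, :]
        if pats is not None and rho != 0.0:
            xw1 = _block_whiten(xw1, pats, rho)
            xw2 = _block_whiten(xw2, pats, rho)
        return _ls_fit_2col(xw1, xw2, yw)

    ones = np.ones_like(y)

    def voom_pass(rho: float, w: np.ndarray) -> np.ndarray:
        b1, b2, rss, _ = weighted_fit(w, rho)
        s2 = rss / df_resid
        sy = np.sqrt(np.sqrt(np.maximum(s2, 1e-12)))
        sx = mean_logcpm + np.mean(log_adj)
        trend = _lowess_trend(sx, sy)
        fitted_logcpm = b1[:, None] + b2[:, None] * x2[None, :]
        fitted_logcount = fitted_logcpm + log_adj[None, :]
        return 1.0 / trend(fitted_logcount) ** 4

    w = ones
    if use_weights:
        w = voom_pass(0.0, ones)

    rho = 0.0
    if pats is not None:
        if correlation is not None:
            rho = float(correlation)
        else:
            b1, b2, _, _ = weighted_fit(w, 0.0)
            fitted = b1[:, None] + b2[:, None] * x2[None, :]
            rho = consensus_correlation(y - fitted, pats, mean_logcpm)
    if use_weights and rho != 0.0:
        w = voom_pass(rho, w)

    b1, b2, rss, se2_unscaled = weighted_fit(w, rho)
    s2 = rss / df_resid

    if moderate:
        d0, s02 = squeeze_var(s2, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s02)
            df_total = np.inf
        else:
            s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
            df_total = d0 + df_resid
    else:
        d0, s02 = 0.0, float("nan")
        s2_post = s2
        df_total = df_resid

    se = np.sqrt(se2_unscaled * s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, b2 / se, 0.0)
    if np.isinf(df_total):
        from scipy.stats import norm

        p = 2.0 * norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * t_dist.sf(np.abs(t_stat), df_total)
    table = pd.DataFrame(
        {
            "log2_fc": b2,
            "t": t_stat,
            "p": p,
            "adj_p": bh_adjust(p),
            "mean_logcpm": mean_logcpm,
        },
        index=counts.index,
    )
    return DEResult(
        table=table,
        consensus_correlation=rho,
        prior_df=float(d0),
        prior_var=float(s02),
        group_order=levels,
    )


def select_panel(de: DEResult, alpha: float = 1e-5, use_adjusted: bool = True) -> pd.Index:
    """Genes below ``alpha`` on adjusted (default) or raw p, ordered by significance."""
    col = "adj_p" if use_adjusted else "p"
    hits = de.table[de.table[col] < alpha].sort_values([col, "p"])
    if hits.empty:
        raise ValueError(
            f"no genes with {col} < {alpha}; relax alpha or check the contrast"
        )
    return hits.index
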