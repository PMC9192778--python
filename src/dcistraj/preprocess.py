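"""Count-matrix I/O, gene filtering, TMM normalization and log2-CPM.

The count matrix convention throughout the package is a :class:`pandas.DataFrame`
with genes as rows (index name ``gene_id``) and samples as columns. All
normalization follows the edgeR/limma lineage: trimmed-mean-of-M-values (TMM)
factors against a reference sample, and log2 counts-per-million with a 0.5
count / 1.0 library-size prior.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import scipy.stats


class CountMatrixError(ValueError):
    """Raised for malformed count matrices (duplicates, negatives, non-integers)."""


@dataclass(frozen=True)
class NormFactors:
    """Per-sample TMM factors and library sizes.

    ``tmm`` is rescaled so its geometric mean is 1; the effective library size
    of a sample is ``lib_size * tmm``.
    """

    tmm: pd.Series
    lib_size: pd.Series

    def __post_init__(self) -> None:
        if not self.tmm.index.equals(self.lib_size.index):
            raise ValueError("tmm and lib_size must be indexed by the same samples")
        if (self.tmm <= 0).any() or (self.lib_size <= 0).any():
            raise ValueError("normalization factors and library sizes must be positive")

    @property
    def effective_lib_size(self) -> pd.Series:
        return self.lib_size * self.tmm


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a genes x samples count matrix and return it unchanged."""
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise CountMatrixError(f"duplicate gene ID: {dup!r}")
    if counts.columns.has_duplicates:
        dup = counts.columns[counts.columns.duplicated()][0]
        raise CountMatrixError(f"duplicate sample ID: {dup!r}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise CountMatrixError("counts must be numeric")
    if (values < 0).any():
        raise CountMatrixError("counts must be nonnegative")
    if not np.allclose(values, np.round(values)):
        raise CountMatrixError("counts must be integers")
    return counts


def read_counts(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read a genes x samples count matrix.

    ``tsv``: tab-separated, first column ``gene_id``, header row of sample IDs.
    ``mtx``: MatrixMarket coordinate file ``<path>`` with sidecar ID files
    ``<stem>.genes.txt`` and ``<stem>.samples.txt`` (one ID per line).
    """
    path = Path(path)
    if format == "tsv":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        counts.index.name = "gene_id"
    elif format == "mtx":
        mat = scipy.sparse.csr_matrix(scipy.io.mmread(path))
        stem = path.with_suffix("")
        genes = stem.with_suffix(".genes.txt").read_text().split()
        samples = stem.with_suffix(".samples.txt").read_text().split()
        counts = pd.DataFrame(mat.toarray(), index=genes, columns=samples)
        counts.index.name = "gene_id"
    else:
        raise ValueError(f"unknown format {format!r}")
    return validate_counts(counts.astype(np.int64))


def write_counts(counts: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write a count matrix in the dialect read back by :func:`read_counts`."""
    path = Path(path)
    if format == "tsv":
        out = counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")
    elif format == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(counts.to_numpy()), field="integer")
        stem = path.with_suffix("")
        stem.with_suffix(".genes.txt").write_text("\n".join(counts.index) + "\n")
        stem.with_suffix(".samples.txt").write_text("\n".join(counts.columns) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def filter_genes(counts: pd.DataFrame, min_frac: float = 0.05) -> pd.DataFrame:
    """Keep genes detected (count > 0) in at least ``ceil(min_frac * n_samples)`` samples."""
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    min_samples = math.ceil(min_frac * counts.shape[1])
    keep = (counts.to_numpy() > 0).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("gene filter removed every gene", stacklevel=2)
    return counts.loc[keep]


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    obs_lib: float,
    ref_lib: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference (log2 scale returned as linear)."""
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok].astype(float), ref[ok].astype(float)
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / obs_lib, ref / ref_lib
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # inverse asymptotic binomial variance of M
    w = (obs_lib - obs) / (obs_lib * obs) + (ref_lib - ref) / (ref_lib * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = scipy.stats.rankdata(m, method="ordinal")
    rank_a = scipy.stats.rankdata(a, method="ordinal")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(counts: pd.DataFrame) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors.

    The reference is the sample whose 75th expression percentile (of
    counts/library-size) is closest to the mean 75th percentile. M-values are
    trimmed 30% on each side, A-values 5%, and the surviving M-values are
    averaged with inverse asymptotic-variance weights. Factors are rescaled to
    geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = lib.index[lib == 0][0]
        raise ValueError(f"sample with zero total count: {bad!r}")
    x = counts.to_numpy().astype(float)
    q75 = np.quantile(x / lib.to_numpy()[None, :], 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = x[:, ref_idx]
    ref_lib = float(lib.iloc[ref_idx])
    factors = np.array(
        [_tmm_pair(x[:, j], ref, float(lib.iloc[j]), ref_lib) for j in range(x.shape[1])]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(
        tmm=pd.Series(factors, index=counts.columns, name="tmm"),
        lib_size=lib.rename("lib_size"),
    )


def log_cpm(counts: pd.DataFrame, factors: NormFactors | None = None) -> pd.DataFrame:
    """log2 counts-per-million with the voom prior: log2((k + 0.5) / (L + 1) * 1e6).

    ``L`` is the TMM-effective library size when ``factors`` is given, else the
    raw column sum.
    """
    if factors is None:
        eff = counts.sum(axis=0).astype(float)
    else:
        if set(factors.tmm.index) != set(counts.columns):
            raise ValueError("normalization factors do not match sample set")
        eff = factors.effective_lib_size.reindex(counts.columns)
    vals = np.log2(
        (counts.to_numpy() + 0.5) / (eff.to_numpy()[None, :] + 1.0) * 1e6
    )
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)
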