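"""Sampling-depth-adjusted pairwise Spearman correlation.

In sparse single-nucleus data, two genes can look correlated simply because
both are detected mostly in deeply sequenced nuclei.  The adjusted statistic
removes this artifact by subtracting, from the observed Spearman matrix, the
correlation expected when each feature's total count is redistributed across
nuclei by multinomial sampling proportional to per-nucleus depth — a null
that preserves both marginals (each feature's expression level and each
nucleus's sampling depth) while destroying all biological co-variation.

    adjusted(i, j) = observed_rho(i, j) - E_null[rho(i, j)]

The expectation is estimated by Monte-Carlo over ``n_null`` independent
redistributions; the replicate standard error is reported alongside.
Spearman uses average ranks (midranks) — the sparse data are tie-dominated,
so the tie convention is part of the statistic's definition here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
from scipy.stats import rankdata

from ._rng import stream_rng


@dataclass
class CorrelationMatrix:
    """Symmetric feature x feature correlation statistic.

    ``flavor`` is one of observed / expected / adjusted; the diagonal is NaN
    (not applicable) and excluded from all summaries, as are entries
    involving constant (zero-variance) features.
    """

    values: np.ndarray
    feature_ids: list[str]
    flavor: str
    n_null: int = 0
    se: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.feature_ids):
            raise ValueError("values must be square and match feature_ids")
        if not np.allclose(v, v.T, equal_nan=True, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")

    def mean_offdiagonal(self) -> float:
        mask = ~np.eye(len(self.feature_ids), dtype=bool) & ~np.isnan(self.values)
        return float(self.values[mask].mean())

    def lookup(self, a: str, b: str) -> float:
        i, j = self.feature_ids.index(a), self.feature_ids.index(b)
        return float(self.values[i, j])


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def _subset_matrix(adata: ad.AnnData, feature_subset) -> tuple[np.ndarray, list[str]]:
    if feature_subset is None:
        return _dense(adata.X).astype(float), list(adata.var_names)
    ids = list(feature_subset)
    missing = sorted(set(ids) - set(adata.var_names))
    if missing:
        raise KeyError(f"feature ids not in matrix: {missing[:5]}")
    return _dense(adata[:, ids].X).astype(float), ids


def _spearman_columns(X: np.ndarray) -> np.ndarray:
    """Pairwise Spearman over columns with midranks; NaN for constant
    columns and on the diagonal."""
    R = rankdata(X, axis=0)
    Rc = R - R.mean(axis=0, keepdims=True)
    norms = np.sqrt((Rc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (Rc.T @ Rc) / np.outer(norms, norms)
    C[:, norms == 0] = np.nan
    C[norms == 0, :] = np.nan
    np.fill_diagonal(C, np.nan)
    return np.clip(C, -1.0, 1.0)


def spearman_matrix(adata: ad.AnnData, feature_subset=None) -> CorrelationMatrix:
    """Observed pairwise Spearman correlation over nuclei."""
    if adata.n_obs < 3:
        raise ValueError("need at least 3 nuclei for a correlation matrix")
    X, ids = _subset_matrix(adata, feature_subset)
    return CorrelationMatrix(_spearman_columns(X), ids, "observed")


def expected_correlation(adata: ad.AnnData, n_null: int = 100, seed: int = 0,
                         feature_subset=None) -> CorrelationMatrix:
    """Expected Spearman under depth-preserving multinomial redistribution.

    Each null replicate redistributes every feature's observed total count
    independently across nuclei with probabilities proportional to the
    nucleus's total sequencing depth (taken over ALL features, not the
    subset).  The returned matrix is the mean over replicates; ``se`` holds
    the per-entry Monte-Carlo standard error.
    """
    if n_null < 10:
        raise ValueError("n_null < 10 gives an unstable expectation; use >= 10")
    if adata.n_obs < 3:
        raise ValueError("need at least 3 nuclei")
    X, ids = _subset_matrix(adata, feature_subset)
    depth = _dense(adata.X).sum(axis=1).astype(float)
    if depth.sum() <= 0:
        raise ValueError("matrix has no reads")
    p = depth / depth.sum()
    totals = X.sum(axis=0).astype(np.int64)

    rng = stream_rng(seed, "expected_correlation")
    # nan-aware accumulation: a feature can come out constant in a single
    # replicate (small totals), which yields NaN entries for that replicate
    total = np.zeros((len(ids), len(ids)))
    total_sq = np.zeros_like(total)
    count = np.zeros_like(total)
    for _ in range(n_null):
        Xr = rng.multinomial(totals, p).T.astype(float)  # nuclei x features
        C = _spearman_columns(Xr)
        valid = ~np.isnan(C)
        total[valid] += C[valid]
        total_sq[valid] += C[valid] ** 2
        count += valid
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / count
        var = np.maximum(total_sq / count - mean ** 2, 0.0)
        se = np.sqrt(var / np.maximum(count, 1))
    mean[count == 0] = np.nan
    np.fill_diagonal(mean, np.nan)
    np.fill_diagonal(se, np.nan)
    return CorrelationMatrix(mean, ids, "expected", n_null=n_null, se=se)


def adjusted_correlation(observed: CorrelationMatrix,
                         expected: CorrelationMatrix) -> CorrelationMatrix:
    """Elementwise observed minus expected; NaN entries propagate."""
    if observed.flavor != "observed" or expected.flavor != "expected":
        raise ValueError("arguments must be (observed, expected) flavors")
    if observed.feature_ids != expected.feature_ids:
        raise ValueError("feature orderings differ between observed and expected")
    return CorrelationMatrix(
        observed.values - expected.values, list(observed.feature_ids),
        "adjusted", n_null=expected.n_null, se=expected.se)


def adjusted_from_counts(adata: ad.AnnData, n_null: int = 100, seed: int = 0,
                         feature_subset=None) -> CorrelationMatrix:
    """Convenience one-call path: observed, expected, then adjusted."""
    obs = spearman_matrix(adata, feature_subset)
    exp = expected_correlation(adata, n_null=n_null, seed=seed,
                               feature_subset=feature_subset)
    return adjusted_correlation(obs, exp)


def write_correlation_tsv(corr: CorrelationMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(corr.values, index=corr.feature_ids,
                 columns=corr.feature_ids).to_csv(path, sep="\t")
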