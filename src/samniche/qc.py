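"""Quality-control filters on the nucleus x feature count matrix.

Filter order is fixed: nuclei first, then features, because feature
detection counts must be recomputed after nuclei are removed.  Both filters
are idempotent and log before/after sizes.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np

log = logging.getLogger(__name__)


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def filter_nuclei(adata: ad.AnnData, min_features: int = 100,
                  min_reads: int = 1000) -> ad.AnnData:
    """Drop nuclei with fewer than `min_features` detected features or
    fewer than `min_reads` total reads.

    The thresholds are configuration values, not constants: low-quality
    wells vary by experiment, so callers state what "low feature and read
    count" means for their data.
    """
    if min_features < 0 or min_reads < 0:
        raise ValueError("thresholds must be >= 0")
    X = _dense(adata.X)
    n_feat = (X > 0).sum(axis=1)
    n_reads = X.sum(axis=1)
    keep = (n_feat >= min_features) & (n_reads >= min_reads)
    if not keep.any():
        raise ValueError(
            f"nucleus filter removed everything (min_features={min_features}, "
            f"min_reads={min_reads})")
    log.info("filter_nuclei: %d -> %d nuclei (min_features=%d, min_reads=%d)",
             adata.n_obs, int(keep.sum()), min_features, min_reads)
    out = adata[keep].copy()
    out.obs["total_reads"] = _dense(out.X).sum(axis=1)
    out.obs["n_features_detected"] = (_dense(out.X) > 0).sum(axis=1)
    return out


def filter_features(adata: ad.AnnData, min_nuclei: int = 4,
                    exclude_ids: set[str] | list[str] | None = None) -> ad.AnnData:
    """Keep features detected (count >= 1) in at least `min_nuclei` nuclei;
    drop features named in `exclude_ids` regardless.

    The default of 4 is the detection cutoff used throughout: a feature
    counts as expressed when it is nonzero in at least 4 nuclei.  The
    curated high-count/high-variance exclusion is supplied by the caller
    (or produced by :func:`flag_high_variance`).
    """
    if min_nuclei < 1:
        raise ValueError("min_nuclei must be >= 1")
    exclude = set(exclude_ids or ())
    X = _dense(adata.X)
    detected_in = (X > 0).sum(axis=0)
    keep = (detected_in >= min_nuclei) & ~adata.var_names.isin(exclude)
    if not keep.any():
        log.warning("filter_features removed every feature")
    log.info("filter_features: %d -> %d features (min_nuclei=%d, excluded=%d)",
             adata.n_vars, int(keep.sum()), min_nuclei, len(exclude))
    out = adata[:, keep].copy()
    out.obs["n_features_detected"] = (_dense(out.X) > 0).sum(axis=1)
    return out


def flag_high_variance(adata: ad.AnnData, top_fraction_by_total: float = 0.01,
                       variance_quantile: float = 0.99) -> set[str]:
    """Reproducible stand-in for a curated exclusion of dominating genes.

    Flags features that are simultaneously in the top `top_fraction_by_total`
    of total counts and above the `variance_quantile` of per-feature count
    variance — the "very high read counts and variance" profile typical of
    translational/photosynthetic housekeeping genes that would otherwise
    dominate the correlation structure.  Deterministic given the matrix.
    """
    if not 0 < top_fraction_by_total < 1 or not 0 < variance_quantile < 1:
        raise ValueError("fractions must lie in (0, 1)")
    X = _dense(adata.X)
    totals = X.sum(axis=0)
    variances = X.var(axis=0)
    n_top = max(1, int(np.ceil(top_fraction_by_total * adata.n_vars)))
    # strict threshold: in an all-equal matrix nothing exceeds itself
    order = np.argsort(totals, kind="stable")[::-1]
    total_cut = totals[order[n_top - 1]]
    var_cut = np.quantile(variances, variance_quantile)
    flagged = (totals >= total_cut) & (variances > var_cut) & (variances > 0)
    ids = set(adata.var_names[flagged])
    log.info("flag_high_variance: flagged %d features", len(ids))
    return ids
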