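"""Nucleus classification and group/overlap statistics.

Nuclei are classified by AGO5/AGO9 marker reads (L2 expresses both, L1 only
AGO9) and by cell-cycle marker expression; TE-cluster expression is compared
between marker groups with Mann-Whitney U tests; set overlaps (TE clusters
vs AGO cargo, cargo vs derepressed TEs) use the hypergeometric upper tail.

The Mann-Whitney exact path (both groups <= 8) enumerates all C(n+m, n)
assignments of the pooled observations — a full permutation test that is
correct under ties.  Larger groups use the normal approximation with tie
correction (no continuity correction; see methods note).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu, rankdata, tiecorrect
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

MARKER_GROUPS = ("AGO5_AGO9", "AGO9_only", "AGO5_only", "none")
DEFAULT_CYCLE_MARKERS = {"HTR13": "S-G2", "CDT1A": "G1", "CYCB1.1": "G2-M"}


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    U: float
    p: float
    direction: int  # sign of median(a) - median(b)
    median_a: float
    median_b: float
    method: str
    label: str = ""


@dataclass
class OverlapTest:
    size_a: int
    size_b: int
    overlap: int
    universe: int
    p: float
    fold: float


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def _marker_counts(adata: ad.AnnData, marker: str) -> np.ndarray:
    if marker not in adata.var_names:
        raise KeyError(f"marker gene {marker!r} not in the count matrix")
    return _dense(adata[:, [marker]].X).ravel()


def classify_nuclei_by_markers(adata: ad.AnnData, ago5: str = "AGO5",
                               ago9: str = "AGO9", min_reads: int = 2) -> pd.Series:
    """Partition nuclei by AGO5/AGO9 expression (count >= min_reads).

    AGO5_AGO9 marks putative L2 nuclei, AGO9_only putative L1; AGO5_only is
    biologically unexpected but reported as its own group rather than merged.
    Every nucleus receives exactly one label.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    a5 = _marker_counts(adata, ago5) >= min_reads
    a9 = _marker_counts(adata, ago9) >= min_reads
    lab = np.where(a5 & a9, "AGO5_AGO9",
                   np.where(a9, "AGO9_only", np.where(a5, "AGO5_only", "none")))
    return pd.Series(pd.Categorical(lab, categories=MARKER_GROUPS),
                     index=adata.obs_names, name="marker_group")


def assign_cell_cycle(adata: ad.AnnData,
                      markers: dict[str, str] | None = None,
                      min_reads: int = 1) -> pd.Series:
    """Phase of the strictly maximal cycle marker with count >= min_reads;
    ties or all-below-threshold give 'unassigned'."""
    markers = dict(DEFAULT_CYCLE_MARKERS if markers is None else markers)
    counts = np.column_stack([_marker_counts(adata, m) for m in markers])
    phases = np.array(list(markers.values()))
    top = counts.max(axis=1)
    is_top = counts == top[:, None]
    unique_top = is_top.sum(axis=1) == 1
    ok = (top >= min_reads) & unique_top
    lab = np.where(ok, phases[np.argmax(counts, axis=1)], "unassigned")
    cats = list(dict.fromkeys(list(markers.values()) + ["unassigned"]))
    return pd.Series(pd.Categorical(lab, categories=cats),
                     index=adata.obs_names, name="cell_cycle")


def mann_whitney(a, b, exact_max: int = 8, label: str = "",
                 group_a: str = "a", group_b: str = "b") -> GroupComparison:
    """Two-sided Mann-Whitney U; exact enumeration when both groups are
    small, normal approximation with tie correction otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u = float(ranks[:n].sum() - n * (n + 1) / 2)
    mu = n * m / 2.0
    if n <= exact_max and m <= exact_max:
        # full permutation enumeration over which pooled ranks belong to a
        dev = abs(u - mu)
        hits = 0
        for idx in combinations(range(n + m), n):
            u_perm = ranks[list(idx)].sum() - n * (n + 1) / 2
            if abs(u_perm - mu) >= dev - 1e-9:
                hits += 1
        p = hits / comb(n + m, n)
        method = "exact"
    else:
        tc = tiecorrect(ranks)
        if tc == 0:  # all values identical
            p = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(mannwhitneyu(a, b, alternative="two-sided",
                                       method="asymptotic",
                                       use_continuity=False).pvalue)
        method = "normal"
    med_a, med_b = float(np.median(a)), float(np.median(b))
    return GroupComparison(group_a, group_b, n, m, u, min(p, 1.0),
                           int(np.sign(med_a - med_b)), med_a, med_b,
                           method, label)


def normalized_cluster_expression(adata: ad.AnnData, member_ids) -> np.ndarray:
    """Per-nucleus mean depth-normalized count (counts per 10,000) over the
    cluster's member TEs — the per-nucleus summary used in group tests."""
    member_ids = [m for m in member_ids if m in adata.var_names]
    if not member_ids:
        raise KeyError("no cluster members present in the matrix")
    X = _dense(adata[:, member_ids].X).astype(float)
    depth = _dense(adata.X).sum(axis=1).astype(float)
    depth[depth == 0] = np.nan
    cp10k = X / depth[:, None] * 1e4
    return np.nanmean(cp10k, axis=1)


def compare_te_expression(adata: ad.AnnData, assign,
                          groups=("AGO5_AGO9", "AGO9_only", "none"),
                          marker_group: pd.Series | None = None) -> pd.DataFrame:
    """Mann-Whitney comparisons of per-nucleus TE-cluster expression between
    marker groups, one row per (cluster, group pair), with BH-adjusted q.

    Group pairs with fewer than 2 nuclei on either side are skipped with a
    warning.  `assign` is a ClusterAssignment over TE features.
    """
    mg = adata.obs["marker_group"] if marker_group is None else marker_group
    rows = []
    for c in range(1, assign.k + 1):
        members = assign.members(c)
        if not members:
            continue
        expr = normalized_cluster_expression(adata, members)
        for ga, gb in combinations(groups, 2):
            va = expr[(mg == ga).to_numpy()]
            vb = expr[(mg == gb).to_numpy()]
            if len(va) < 2 or len(vb) < 2:
                log.warning("skipping cluster %d %s vs %s: group too small", c, ga, gb)
                continue
            r = mann_whitney(va, vb, label=f"te_cluster_{c}", group_a=ga, group_b=gb)
            rows.append({
                "cluster": c, "group_a": ga, "group_b": gb, "n_a": r.n_a,
                "n_b": r.n_b, "U": r.U, "p": r.p, "direction": r.direction,
                "median_a": r.median_a, "median_b": r.median_b, "method": r.method,
            })
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def hypergeometric_overlap(set_a, set_b, universe) -> OverlapTest:
    """Upper-tail hypergeometric probability of the observed overlap.

    p = P(X >= |A ∩ B|) for X ~ Hypergeom(|U|, |A|, |B|); fold is the
    observed overlap over its expectation |A||B|/|U|.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("both sets must be contained in the universe")
    if not universe:
        raise ValueError("universe must be non-empty")
    k = len(set_a & set_b)
    M, K, N = len(universe), len(set_a), len(set_b)
    p = float(hypergeom.sf(k - 1, M, K, N))
    expected = K * N / M
    fold = k / expected if expected > 0 else np.nan
    return OverlapTest(K, N, k, M, min(p, 1.0), fold)


def te_length_comparison(cargo_ids, features: pd.DataFrame) -> GroupComparison:
    """Mann-Whitney on length_bp: cargo TEs vs all other TEs."""
    cargo_ids = set(cargo_ids)
    if not cargo_ids:
        raise ValueError("cargo set is empty")
    tes = features[features["kind"] == "transposon"]
    cargo = tes.loc[tes.index.isin(cargo_ids), "length_bp"].to_numpy(dtype=float)
    rest = tes.loc[~tes.index.isin(cargo_ids), "length_bp"].to_numpy(dtype=float)
    if len(rest) == 0:
        raise ValueError("no non-cargo TEs to compare against")
    if len(cargo) == 0:
        raise ValueError("no cargo ids correspond to annotated TEs")
    return mann_whitney(cargo, rest, label="te_length",
                        group_a="cargo", group_b="non_cargo")
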