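"""Small-RNA cargo characterization.

ARGONAUTE immunoprecipitation yields read populations whose identity shows
in three summaries: the read-length x 5'-nucleotide table (AGO5 prefers
21/22/24 nt with a 5' C; AGO9 24 nt with a 5' A), scaled TE-body metaplots
(easiRNA-like 21 nt reads pile up at TE ends), and the superfamily makeup
of the targeted transposons.  Cargo-vs-input enrichment is a per-feature
binomial proportion test with BH correction.

Reads carry fractional weights (1/n_mappings for multimappers); every
summary here is weight-aware and conserves total weight exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

LENGTH_RANGE = range(18, 27)
NUCLEOTIDES = ("A", "C", "G", "U")


@dataclass
class SizeBiasProfile:
    """Weighted read-length x 5'-nucleotide tabulation."""

    counts: pd.DataFrame              # index 18..26, columns A/C/G/U
    proportions_per_length: pd.DataFrame  # rows sum to 1 where counts > 0
    proportions_overall: pd.DataFrame     # sums to 1 overall
    total_weight: float


@dataclass
class Metaplot:
    """Scaled TE-body coverage: length classes x position bins."""

    matrix: pd.DataFrame  # index = length-class label, columns = bin index
    body_bins: int
    upstream_bins: int = 0
    downstream_bins: int = 0
    normalization: str = "raw"


def size_5p_profile(reads: pd.DataFrame) -> SizeBiasProfile:
    """Tabulate weighted counts by read length and 5' nucleotide."""
    if len(reads) == 0:
        raise ValueError("empty read list")
    counts = (reads.pivot_table(index="length", columns="first_nt",
                                values="weight", aggfunc="sum", fill_value=0.0)
              .reindex(index=list(LENGTH_RANGE), columns=list(NUCLEOTIDES),
                       fill_value=0.0))
    counts.index.name = "length"
    counts.columns.name = "first_nt"
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_length = counts.div(row_sums, axis=0).fillna(0.0)
    total = float(counts.to_numpy().sum())
    return SizeBiasProfile(counts, per_length, counts / total, total)


def metaplot(reads: pd.DataFrame, features: pd.DataFrame, body_bins: int = 100,
             flank_bp: int = 0, length_classes: dict[str, list[int]] | None = None,
             normalization: str = "raw") -> Metaplot:
    """Bin read weight along scaled TE bodies, per read-length class.

    Each read's weight lands in body bin ``floor(rel_pos * body_bins)``;
    features annotated on the minus strand are orientation-flipped so bin 0
    is always the feature's 5' end.  With ``flank_bp > 0``, reads whose
    rel_pos falls outside [0, 1) are mapped onto ``body_bins // 10`` flank
    bins covering ``flank_bp`` on either side (positions beyond the flank
    are out of scope and dropped); with the default ``flank_bp = 0`` such
    reads are an error.  In raw mode the matrix mass equals the total
    in-scope read weight exactly.
    """
    if body_bins < 10:
        raise ValueError("body_bins must be >= 10")
    if normalization not in ("raw", "per_million"):
        raise ValueError("normalization must be 'raw' or 'per_million'")
    unknown = set(reads["feature_id"]) - set(features.index)
    if unknown:
        raise KeyError(f"reads map to unknown features: {sorted(unknown)[:5]}")
    if length_classes is None:
        length_classes = {"21": [21], "22": [22], "24": [24],
                          "other": [18, 19, 20, 23, 25, 26]}
    covered = sorted(ln for lens in length_classes.values() for ln in lens)
    if len(covered) != len(set(covered)):
        raise ValueError("length_classes must not overlap")

    flank_bins = body_bins // 10 if flank_bp > 0 else 0
    n_cols = flank_bins + body_bins + flank_bins

    pos = reads["rel_pos"].to_numpy(dtype=float)
    weight = reads["weight"].to_numpy(dtype=float)
    lengths = reads["length"].to_numpy()
    feat_len = features["length_bp"].reindex(reads["feature_id"]).to_numpy(dtype=float)
    if "strand" in features.columns:
        minus = (features["strand"].reindex(reads["feature_id"]) == "-").to_numpy()
    else:
        minus = np.zeros(len(reads), dtype=bool)

    in_body = (pos >= 0) & (pos < 1)
    if flank_bp == 0 and not in_body.all():
        raise ValueError("reads outside [0,1) require flank_bp > 0")

    col = np.full(len(reads), -1)
    body_bin = np.floor(pos * body_bins).astype(int)
    body_bin = np.where(minus, body_bins - 1 - body_bin, body_bin)
    col[in_body] = flank_bins + body_bin[in_body]
    if flank_bins:
        off_bp = pos * feat_len  # signed bp offset from feature start
        up = (pos < 0) & (off_bp >= -flank_bp)
        down = (pos >= 1) & ((off_bp - feat_len) < flank_bp)
        up_bin = np.floor((off_bp + flank_bp) / flank_bp * flank_bins).astype(int)
        down_bin = np.floor((off_bp - feat_len) / flank_bp * flank_bins).astype(int)
        col[up & ~minus] = np.clip(up_bin, 0, flank_bins - 1)[up & ~minus]
        col[down & ~minus] = (flank_bins + body_bins
                              + np.clip(down_bin, 0, flank_bins - 1))[down & ~minus]
        # minus strand: upstream in genome space is downstream in feature space
        col[up & minus] = (flank_bins + body_bins + flank_bins - 1
                           - np.clip(up_bin, 0, flank_bins - 1))[up & minus]
        col[down & minus] = (flank_bins - 1
                             - np.clip(down_bin, 0, flank_bins - 1))[down & minus]

    mat = np.zeros((len(length_classes), n_cols))
    for i, (label, lens) in enumerate(length_classes.items()):
        sel = np.isin(lengths, lens) & (col >= 0)
        np.add.at(mat[i], col[sel], weight[sel])
    if normalization == "per_million":
        total = weight.sum()
        mat = mat / total * 1e6 if total > 0 else mat
    return Metaplot(
        pd.DataFrame(mat, index=pd.Index(list(length_classes), name="length_class")),
        body_bins, flank_bins, flank_bins, normalization)


def reads_per_feature(reads: pd.DataFrame) -> pd.Series:
    """Total read weight per mapped feature."""
    return reads.groupby("feature_id")["weight"].sum()


def cargo_enrichment(cargo_counts: pd.Series, input_counts: pd.Series,
                     min_normalized: float = 5.0, alpha: float = 0.05,
                     min_log2fc: float = 1.0) -> pd.DataFrame:
    """Per-feature enrichment of cargo over input sRNA abundance.

    Features below ``min_normalized`` reads per million in BOTH libraries
    are filtered out.  Each remaining feature gets a two-sided binomial test
    of its cargo count against the input proportion (library-size
    normalized), BH correction across features, and an ``enriched`` call at
    q < alpha and log2 fold-change > min_log2fc.
    """
    universe = sorted(set(cargo_counts.index) | set(input_counts.index))
    cargo = cargo_counts.reindex(universe).fillna(0.0)
    inp = input_counts.reindex(universe).fillna(0.0)
    n_cargo, n_input = float(cargo.sum()), float(inp.sum())
    if n_cargo <= 0 or n_input <= 0:
        raise ValueError("both libraries need positive total counts")
    cpm_cargo = cargo / n_cargo * 1e6
    cpm_input = inp / n_input * 1e6
    keep = (cpm_cargo >= min_normalized) | (cpm_input >= min_normalized)
    if not keep.any():
        log.warning("cargo_enrichment: no features pass the %g-CPM filter",
                    min_normalized)
        return pd.DataFrame(columns=["cargo_count", "input_count", "cargo_cpm",
                                     "input_cpm", "log2fc", "p", "q", "enriched"])
    cargo, inp = cargo[keep], inp[keep]
    cpm_cargo, cpm_input = cpm_cargo[keep], cpm_input[keep]

    n_trials = int(round(n_cargo))
    pvals = np.empty(len(cargo))
    for i, (x, c_in) in enumerate(zip(cargo.to_numpy(), inp.to_numpy())):
        p0 = c_in / n_input if c_in > 0 else 0.5 / n_input
        pvals[i] = binomtest(int(round(x)), n_trials, min(p0, 1.0)).pvalue
    with np.errstate(divide="ignore"):
        denom = np.where(cpm_input > 0, cpm_input, 0.5 / n_input * 1e6)
        numer = np.where(cpm_cargo > 0, cpm_cargo, 0.5 / n_cargo * 1e6)
        log2fc = np.log2(numer / denom)
    q = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "cargo_count": cargo.to_numpy(),
            "input_count": inp.to_numpy(),
            "cargo_cpm": cpm_cargo.to_numpy(),
            "input_cpm": cpm_input.to_numpy(),
            "log2fc": log2fc,
            "p": pvals,
            "q": q,
        },
        index=pd.Index(cargo.index, name="feature_id"),
    )
    out["enriched"] = (out["q"] < alpha) & (out["log2fc"] > min_log2fc)
    return out


def classify_cargo_by_superfamily(enriched_ids, features: pd.DataFrame) -> pd.DataFrame:
    """Superfamily counts and proportions of a cargo TE set."""
    ids = [i for i in enriched_ids if i in features.index]
    if not ids:
        return pd.DataFrame(columns=["superfamily", "count", "proportion"])
    sf = features.loc[ids, "superfamily"]
    counts = sf.value_counts().rename_axis("superfamily").rename("count").reset_index()
    counts["proportion"] = counts["count"] / counts["count"].sum()
    return counts
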