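"""Reading and writing the pipeline's standard formats.

The central container is an AnnData count matrix (obs = nuclei, var =
features).  On disk it is an MTX (or dense TSV) matrix plus two TSV metadata
tables; TE annotations come in as GFF3 (1-based closed, converted on ingest)
or BED (0-based half-open).  Internal coordinates are 0-based half-open
everywhere.
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import pyranges
import scipy.io
import scipy.sparse

log = logging.getLogger(__name__)

NUCLEUS_COLUMNS = ("total_reads", "n_features_detected", "cell_cycle", "marker_group")
FEATURE_COLUMNS = ("kind", "superfamily", "chromosome", "start", "end",
                   "length_bp", "pericentromeric")
_KNOWN_SUPERFAMILIES = {"LTR/Gypsy", "LTR/Copia", "RC/Helitron", "DNA/MuDR",
                        "LINE", "SINE", "other", "none"}


def _validate_counts(X: np.ndarray, matrix_path) -> np.ndarray:
    if np.any(X < 0):
        i, j = np.argwhere(X < 0)[0]
        raise ValueError(f"{matrix_path}: negative count at row {i + 1}, column {j + 1}")
    if not np.allclose(X, np.round(X)):
        i, j = np.argwhere(~np.isclose(X, np.round(X)))[0]
        raise ValueError(f"{matrix_path}: non-integer count at row {i + 1}, column {j + 1}")
    return X.astype(np.int64)


def read_counts(matrix_path, nucleus_meta_path, feature_meta_path) -> ad.AnnData:
    """Load a nuclei x features CountMatrix from MTX or TSV plus metadata.

    Raises ValueError on dimension mismatches, negative / non-integer
    entries, or duplicate ids; messages carry 1-based row/column numbers.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        X = np.asarray(scipy.io.mmread(matrix_path).todense())
    else:
        X = pd.read_csv(matrix_path, sep="\t", header=None).to_numpy(dtype=float)
    X = _validate_counts(X, matrix_path)

    obs = pd.read_csv(nucleus_meta_path, sep="\t", index_col=0)
    var = pd.read_csv(feature_meta_path, sep="\t", index_col=0)
    for name, df, path in (("nucleus", obs, nucleus_meta_path),
                           ("feature", var, feature_meta_path)):
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            line = int(np.flatnonzero(df.index == dup)[-1]) + 2  # header + 1-based
            raise ValueError(f"{path}: duplicate {name} id {dup!r} (line {line})")
    if X.shape != (len(obs), len(var)):
        raise ValueError(
            f"dimension mismatch: matrix is {X.shape[0]}x{X.shape[1]} but metadata "
            f"describe {len(obs)} nuclei and {len(var)} features")
    missing = [c for c in FEATURE_COLUMNS if c not in var.columns]
    if missing:
        raise ValueError(f"{feature_meta_path}: missing feature columns {missing}")
    bad = var.index[var["end"] <= var["start"]]
    if len(bad):
        raise ValueError(f"{feature_meta_path}: end <= start for feature {bad[0]!r}")
    for col, default in (("cell_cycle", "unassigned"), ("marker_group", "none")):
        if col not in obs.columns:
            obs[col] = default
    if "total_reads" not in obs.columns:
        obs["total_reads"] = X.sum(axis=1)
    if "n_features_detected" not in obs.columns:
        obs["n_features_detected"] = (X > 0).sum(axis=1)
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    return ad.AnnData(X=X, obs=obs, var=var)


def write_counts(adata: ad.AnnData, outdir, stem: str = "counts") -> dict[str, Path]:
    """Write matrix.mtx + nuclei.tsv + features.tsv; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{stem}.mtx",
        "nuclei": outdir / f"{stem}.nuclei.tsv",
        "features": outdir / f"{stem}.features.tsv",
    }
    X = adata.X
    if scipy.sparse.issparse(X):
        X = np.asarray(X.todense())
    scipy.io.mmwrite(paths["matrix"], scipy.sparse.csr_matrix(X.astype(np.int64)))
    adata.obs.to_csv(paths["nuclei"], sep="\t")
    adata.var.to_csv(paths["features"], sep="\t")
    return paths


def _records_from_frame(df: pd.DataFrame, path, id_col: str,
                        superfamily_col: str | None) -> pd.DataFrame:
    bad = df.index[df["End"] <= df["Start"]]
    if len(bad):
        raise ValueError(f"{path}: end <= start in record {bad[0]}")
    ids = df[id_col].astype(str)
    if superfamily_col is not None and superfamily_col in df.columns:
        sf = df[superfamily_col].fillna("other").astype(str)
        sf = sf.where(sf.isin(_KNOWN_SUPERFAMILIES), "other")
    else:
        sf = pd.Series("other", index=df.index)
    out = pd.DataFrame(
        {
            "kind": "transposon",
            "superfamily": sf.to_numpy(),
            "chromosome": df["Chromosome"].astype(str).to_numpy(),
            "start": df["Start"].astype(int).to_numpy(),
            "end": df["End"].astype(int).to_numpy(),
            "length_bp": (df["End"] - df["Start"]).astype(int).to_numpy(),
            "pericentromeric": False,
        },
        index=pd.Index(ids, name="feature_id"),
    )
    if "Strand" in df.columns:
        out["strand"] = df["Strand"].astype(str).to_numpy()
    return out


def read_te_annotation(path, format: str = "GFF3") -> pd.DataFrame:
    """Read TE records from GFF3 or BED into feature-metadata form.

    Coordinates are normalized to 0-based half-open (GFF3 is converted on
    ingest); the superfamily is taken from the GFF3 ``superfamily`` attribute
    or the 7th BED column and defaults to ``other`` when absent.
    """
    path = Path(path)
    if format.upper() == "GFF3":
        gr = pyranges.read_gff3(str(path))
        df = gr.df
        id_col = "ID" if "ID" in df.columns else "Name"
        if id_col not in df.columns:
            raise ValueError(f"{path}: GFF3 records lack ID/Name attributes")
        return _records_from_frame(df, path, id_col, "superfamily")
    if format.upper() == "BED":
        df = pyranges.read_bed(str(path)).df
        if "Name" not in df.columns:
            raise ValueError(f"{path}: BED needs at least 4 columns (name required)")
        # optional 7th column carries the superfamily
        extra = "ThickStart" if "ThickStart" in df.columns else None
        return _records_from_frame(df, path, "Name", extra)
    raise ValueError(f"unknown annotation format {format!r} (use GFF3 or BED)")


SRNA_COLUMNS = ("read_id", "feature_id", "length", "first_nt", "rel_pos", "weight")


def read_srna_reads(path) -> pd.DataFrame:
    """Read the 6-column sRNA read table; maps DNA T to RNA U on ingest."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SRNA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing sRNA read columns {missing}")
    df["first_nt"] = df["first_nt"].str.upper().str.replace("T", "U")
    bad = df.index[(df["length"] < 18) | (df["length"] > 26)]
    if len(bad):
        raise ValueError(f"{path}: read length outside 18..26 at line {bad[0] + 2}")
    bad = df.index[(df["rel_pos"] < 0) | (df["rel_pos"] >= 1)]
    if len(bad):
        raise ValueError(f"{path}: rel_pos outside [0,1) at line {bad[0] + 2}")
    bad = df.index[(df["weight"] <= 0) | (df["weight"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: weight outside (0,1] at line {bad[0] + 2}")
    return df[list(SRNA_COLUMNS)]


def write_srna_reads(reads: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    reads[list(SRNA_COLUMNS)].to_csv(path, sep="\t", index=False)
    return path


def read_id_list(path) -> list[str]:
    """Plain-text id list, one id per line; '#' comments and blanks skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
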