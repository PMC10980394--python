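"""Synthetic single-nucleus count matrices with planted niche structure.

The generator emulates a sparse SMART-seq experiment on sorted stem-cell
nuclei of the Arabidopsis shoot apical meristem: ~200 nuclei with strongly
heterogeneous sequencing depth (lognormal, tracked by a DAPI-like covariate),
latent niche labels (L1 / L2 / other), cell-cycle states, marker genes
(CLV3 everywhere; AGO5 in L2; AGO9 in L1+L2; HTR13 / CDT1A / CYCB1.1 by
cycle phase), two planted seed-gene programs and three planted transposable-
element (TE) expression programs.

The count model is a per-nucleus multinomial over a fixed rate vector, NOT
independent per-gene Poisson draws.  This matters: multinomial sampling at
heterogeneous depth produces the spurious positive gene-gene correlation
that the sampling-adjusted correlation statistic exists to remove, so the
null-calibration tests downstream are meaningful.

Program parametrization: a member of a program has rate ``base`` inside the
program's compartment and ``base / effect`` outside, so ``effect`` is the
in/out fold change, ``effect = inf`` forces exactly zero expression outside
the compartment, and ``effect = 1`` disables the program (including its
shared activity factor) — the negative-control null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd

from ._rng import stream_rng

NICHES = ("L1", "L2", "other")
PHASES = ("G1", "S-G2", "G2-M")
MARKER_GENES = ("CLV3", "AGO5", "AGO9", "HTR13", "CDT1A", "CYCB1.1")
CYCLE_MARKERS = {"HTR13": "S-G2", "CDT1A": "G1", "CYCB1.1": "G2-M"}

SUPERFAMILIES = (
    "LTR/Gypsy", "LTR/Copia", "RC/Helitron", "DNA/MuDR", "LINE", "SINE", "other",
)

#: superfamily mix of the background TE program: genome-like, mostly
#: RC/Helitron and DNA/MuDR elements on chromosome arms
_BACKGROUND_MIX = {
    "RC/Helitron": 0.40, "DNA/MuDR": 0.30, "LTR/Gypsy": 0.08, "LTR/Copia": 0.07,
    "LINE": 0.05, "SINE": 0.05, "other": 0.05,
}
#: mix of the niche-elevated programs: pericentromeric, LTR/Gypsy dominated
_GYPSY_MIX = {
    "LTR/Gypsy": 0.70, "LTR/Copia": 0.12, "RC/Helitron": 0.05, "DNA/MuDR": 0.05,
    "LINE": 0.04, "SINE": 0.02, "other": 0.02,
}

TE_PROGRAMS = ("te_cluster1", "te_cluster2", "te_cluster3")


def _check_proportions(name: str, props: Mapping[str, float], keys: tuple[str, ...]) -> None:
    if set(props) != set(keys):
        raise ValueError(f"{name} must have keys {keys}, got {sorted(props)}")
    total = float(sum(props.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {total})")
    if any(v < 0 for v in props.values()):
        raise ValueError(f"{name} entries must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults are the study conditions assumed throughout: 200 nuclei,
    2000 genes + 500 TEs, niche mix L1 0.2 / L2 0.3 / other 0.5, lognormal
    per-nucleus depth (median ~8000 reads), 30 seed genes split between an
    L2-specific and a general stem-cell program, and TE programs split
    50 / 25 / 25 between a cycle-coupled background program and two
    L2-elevated, Gypsy-enriched programs.
    """

    n_nuclei: int = 200
    n_genes: int = 2000
    n_tes: int = 500
    niche_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"L1": 0.2, "L2": 0.3, "other": 0.5})
    depth_lognormal_mu: float = math.log(8000.0)
    depth_lognormal_sigma: float = 0.6
    marker_effect: float = 50.0
    te_program_effect: float = 8.0
    n_seed_genes: int = 30
    cell_cycle_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"G1": 0.5, "S-G2": 0.3, "G2-M": 0.2})
    te_cluster_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"te_cluster1": 0.5, "te_cluster2": 0.25, "te_cluster3": 0.25})
    #: lognormal sigma of the shared per-program activity factor; applied
    #: only while the program's effect is > 1
    program_factor_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_nuclei", "n_genes", "n_tes", "n_seed_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        _check_proportions("niche_proportions", self.niche_proportions, NICHES)
        _check_proportions("cell_cycle_proportions", self.cell_cycle_proportions, PHASES)
        _check_proportions("te_cluster_proportions", self.te_cluster_proportions, TE_PROGRAMS)
        if self.marker_effect < 1 or self.te_program_effect < 1:
            raise ValueError("effects must be >= 1")
        if self.n_seed_genes + len(MARKER_GENES) > self.n_genes:
            raise ValueError("n_genes too small for markers plus seed genes")
        if self.program_factor_sigma < 0:
            raise ValueError("program_factor_sigma must be >= 0")
        if self.depth_lognormal_sigma <= 0:
            raise ValueError("depth_lognormal_sigma must be > 0")
        # degenerate-sparsity guard: expected reads per nucleus below one
        # cannot produce a usable matrix
        mean_depth = math.exp(self.depth_lognormal_mu + self.depth_lognormal_sigma ** 2 / 2)
        if mean_depth < 1.0:
            raise ValueError(
                "degenerate configuration: expected per-nucleus depth "
                f"{mean_depth:.3g} < 1 read")


@dataclass
class TruthLabels:
    """Planted ground truth, kept apart from the observable CountMatrix."""

    niche_per_nucleus: pd.Series
    cycle_per_nucleus: pd.Series
    dapi_covariate: pd.Series
    program_per_feature: pd.Series

    @property
    def seed_gene_ids(self) -> list[str]:
        mask = self.program_per_feature.isin(["seed_group1", "seed_group2"])
        return list(self.program_per_feature.index[mask])

    @property
    def te_program_ids(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for prog in TE_PROGRAMS:
            mask = self.program_per_feature == prog
            out[prog] = list(self.program_per_feature.index[mask])
        return out


def _feature_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Feature metadata plus the planted program label per feature."""
    n_seed2 = config.n_seed_genes // 2          # L2-specific program
    n_seed1 = config.n_seed_genes - n_seed2     # general stem program (L1+L2)
    gene_ids = list(MARKER_GENES)
    programs = ["marker"] * len(MARKER_GENES)
    gene_ids += [f"GESS_STEM_{i:03d}" for i in range(1, n_seed1 + 1)]
    programs += ["seed_group1"] * n_seed1
    gene_ids += [f"GESS_L2_{i:03d}" for i in range(1, n_seed2 + 1)]
    programs += ["seed_group2"] * n_seed2
    n_rest = config.n_genes - len(gene_ids)
    gene_ids += [f"GENE_{i:04d}" for i in range(1, n_rest + 1)]
    programs += ["none"] * n_rest

    te_ids = [f"TE_{i:04d}" for i in range(1, config.n_tes + 1)]
    te_programs = rng.choice(
        TE_PROGRAMS, size=config.n_tes,
        p=[config.te_cluster_proportions[p] for p in TE_PROGRAMS])
    programs += list(te_programs)

    ids = gene_ids + te_ids
    kind = ["gene"] * config.n_genes + ["transposon"] * config.n_tes

    superfamily = ["none"] * config.n_genes
    for prog in te_programs:
        mix = _BACKGROUND_MIX if prog == "te_cluster1" else _GYPSY_MIX
        superfamily.append(rng.choice(list(mix), p=list(mix.values())))

    # coordinates: genes 1-4 kb, background TEs short (median ~0.8 kb),
    # Gypsy-program TEs long (median ~4 kb) and mostly pericentromeric
    lengths = np.empty(len(ids), dtype=int)
    lengths[:config.n_genes] = rng.integers(1000, 4000, size=config.n_genes)
    peri = np.zeros(len(ids), dtype=bool)
    for j, prog in enumerate(te_programs):
        i = config.n_genes + j
        if prog == "te_cluster1":
            lengths[i] = max(80, int(rng.lognormal(math.log(800.0), 0.7)))
            peri[i] = rng.random() < 0.2
        else:
            lengths[i] = max(80, int(rng.lognormal(math.log(4000.0), 0.5)))
            peri[i] = rng.random() < 0.8

    chrom = rng.choice([f"Chr{c}" for c in range(1, 6)], size=len(ids))
    start = rng.integers(0, 25_000_000, size=len(ids))

    return pd.DataFrame(
        {
            "kind": pd.Categorical(kind, categories=["gene", "transposon"]),
            "superfamily": superfamily,
            "chromosome": chrom,
            "start": start,
            "end": start + lengths,
            "length_bp": lengths,
            "pericentromeric": peri,
            "program": programs,
        },
        index=pd.Index(ids, name="feature_id"),
    )


def _base_rates(config: SimConfig, features: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Skewed baseline expression rates (arbitrary units, later normalized)."""
    rates = np.empty(len(features))
    is_gene = (features["kind"] == "gene").to_numpy()
    rates[is_gene] = rng.lognormal(0.0, 1.5, size=int(is_gene.sum()))
    rates[~is_gene] = rng.lognormal(math.log(0.6), 0.9, size=int((~is_gene).sum()))
    prog = features["program"].to_numpy()
    # markers and seed genes get solid, fixed baselines so a positive nucleus
    # reliably yields a handful of reads (CLV3 drives the sorting reporter)
    rates[features.index == "CLV3"] = 20.0
    for m in MARKER_GENES[1:]:
        rates[features.index == m] = 8.0
    rates[np.isin(prog, ["seed_group1", "seed_group2"])] = 4.0
    return rates


def _program_spec(config: SimConfig):
    """(members-predicate, compartment, effect, factor-name) per program.

    Compartments are expressed against the truth labels: niche for the
    spatial programs, cycle phase for the replication-coupled ones.  The two
    L2 TE programs share their activity factor with one seed-gene program
    each, which is what couples TE clusters to seed-gene groups.
    """
    me, te = config.marker_effect, config.te_program_effect
    return [
        # program, compartment-kind, compartment-labels, effect, factor
        ("seed_group1", "niche", ("L1", "L2"), me, "f_stem"),
        ("seed_group2", "niche", ("L2",), me, "f_l2"),
        ("te_cluster1", "cycle", ("S-G2", "G2-M"), te, "f_cycle"),
        ("te_cluster2", "niche", ("L2",), te, "f_l2"),
        ("te_cluster3", "niche", ("L1", "L2"), te, "f_stem"),
    ]


def generate_dataset(config: SimConfig) -> tuple[ad.AnnData, TruthLabels]:
    """Draw one synthetic dataset; bit-reproducible for a given config.

    Returns the observable nuclei x features count matrix (AnnData; obs =
    nucleus metadata, var = feature metadata) and the planted TruthLabels.
    Row sums equal the drawn per-nucleus depths exactly (multinomial
    conservation).
    """
    seed = config.seed
    niche = stream_rng(seed, "niche").choice(
        NICHES, size=config.n_nuclei, p=[config.niche_proportions[k] for k in NICHES])
    cycle = stream_rng(seed, "cycle").choice(
        PHASES, size=config.n_nuclei, p=[config.cell_cycle_proportions[k] for k in PHASES])
    depth = np.maximum(
        1,
        np.round(stream_rng(seed, "depth").lognormal(
            config.depth_lognormal_mu, config.depth_lognormal_sigma, config.n_nuclei)),
    ).astype(np.int64)

    features = _feature_table(config, stream_rng(seed, "features"))
    base = _base_rates(config, features, stream_rng(seed, "rates"))

    rates = np.tile(base, (config.n_nuclei, 1))
    program_col = features["program"].to_numpy()
    rng_fact = stream_rng(seed, "factors")
    factors: dict[str, np.ndarray] = {}
    for prog, comp_kind, comp_labels, effect, factor in _program_spec(config):
        members = program_col == prog
        if not members.any():
            continue
        labels = niche if comp_kind == "niche" else cycle
        inside = np.isin(labels, comp_labels)
        if effect > 1:
            with np.errstate(divide="ignore"):
                out_scale = 1.0 / effect
            rates[np.ix_(~inside, members)] *= out_scale
            if factor not in factors:
                factors[factor] = rng_fact.normal(size=config.n_nuclei)
            mult = np.exp(config.program_factor_sigma * factors[factor])
            rates[:, members] *= mult[:, None]

    # marker genes: compartments per marker, no shared factor
    marker_comp = {
        "CLV3": ("niche", NICHES),   # all nuclei: the sorted population is CLV3+
        "AGO5": ("niche", ("L2",)),
        "AGO9": ("niche", ("L1", "L2")),
        "HTR13": ("cycle", ("S-G2",)),
        "CDT1A": ("cycle", ("G1",)),
        "CYCB1.1": ("cycle", ("G2-M",)),
    }
    for m, (comp_kind, comp_labels) in marker_comp.items():
        col = features.index.get_loc(m)
        labels = niche if comp_kind == "niche" else cycle
        inside = np.isin(labels, comp_labels)
        if config.marker_effect > 1 and not inside.all():
            with np.errstate(divide="ignore"):
                rates[~inside, col] *= 1.0 / config.marker_effect

    probs = rates / rates.sum(axis=1, keepdims=True)
    rng_counts = stream_rng(seed, "counts")
    X = np.empty((config.n_nuclei, len(features)), dtype=np.int64)
    for i in range(config.n_nuclei):
        X[i] = rng_counts.multinomial(depth[i], probs[i])

    nucleus_ids = pd.Index([f"N{i:04d}" for i in range(1, config.n_nuclei + 1)],
                           name="nucleus_id")
    rng_cov = stream_rng(seed, "covariates")
    dapi = depth * np.exp(rng_cov.normal(0.0, 0.2, config.n_nuclei))
    mcherry = rng_cov.lognormal(math.log(100.0), 0.4, config.n_nuclei)

    obs = pd.DataFrame(
        {
            "total_reads": depth,
            "n_features_detected": (X > 0).sum(axis=1),
            "dapi_intensity": dapi,
            "mcherry_intensity": mcherry,
            "cell_cycle": "unassigned",
            "marker_group": "none",
        },
        index=nucleus_ids,
    )
    var = features.drop(columns="program")
    adata = ad.AnnData(X=X, obs=obs, var=var)

    truth = TruthLabels(
        niche_per_nucleus=pd.Series(niche, index=nucleus_ids, name="niche"),
        cycle_per_nucleus=pd.Series(cycle, index=nucleus_ids, name="cycle"),
        dapi_covariate=pd.Series(dapi, index=nucleus_ids, name="dapi_covariate"),
        program_per_feature=features["program"].rename("program"),
    )
    return adata, truth


def generate_cargo_sets(
    truth: TruthLabels,
    jaccard_with_programs: float,
    sizes: Mapping[str, int],
    seed: int,
) -> dict[str, set[str]]:
    """Draw AGO cargo TE sets at a requested Jaccard overlap with the
    planted L2 TE programs (te_cluster2 plus te_cluster3).

    ``jaccard_with_programs = 1`` with size equal to the program-union size
    returns exactly the planted union; 0 returns sets disjoint from it.
    """
    if not 0.0 <= jaccard_with_programs <= 1.0:
        raise ValueError("jaccard_with_programs must be in [0, 1]")
    program_ids = truth.te_program_ids
    union = sorted(set(program_ids["te_cluster2"]) | set(program_ids["te_cluster3"]))
    all_tes = sorted(
        truth.program_per_feature.index[truth.program_per_feature.isin(TE_PROGRAMS)])
    outside = sorted(set(all_tes) - set(union))
    p = len(union)
    out: dict[str, set[str]] = {}
    rng = stream_rng(seed, "cargo")
    for name, s in sizes.items():
        if s <= 0 or s > len(all_tes):
            raise ValueError(f"set size {s} for {name!r} outside 1..{len(all_tes)}")
        j = jaccard_with_programs
        o = int(round(j * (s + p) / (1.0 + j)))
        o = min(o, s, p)
        if s - o > len(outside):
            raise ValueError(
                f"cannot draw {name!r}: size {s} at Jaccard {j} needs {s - o} "
                f"TEs outside the planted programs but only {len(outside)} exist")
        chosen = list(rng.choice(union, size=o, replace=False)) if o else []
        chosen += list(rng.choice(outside, size=s - o, replace=False)) if s - o else []
        out[name] = set(chosen)
    return out


DEFAULT_LENGTH_DIST = {18: 0.01, 19: 0.01, 20: 0.02, 21: 0.15, 22: 0.10,
                       23: 0.05, 24: 0.60, 25: 0.04, 26: 0.02}
DEFAULT_P5_BIAS = {"A": 0.55, "C": 0.20, "G": 0.10, "U": 0.15}


def generate_srna_reads(
    cargo: set[str] | list[str],
    n_reads: int,
    length_dist: Mapping[int, float] | None = None,
    p5_bias: Mapping[str, float] | None = None,
    positional_profile: str = "uniform",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate small-RNA reads mapped to cargo TEs.

    Each read carries a length in 18..26 nt, a 5' nucleotide, a feature id
    drawn uniformly from the cargo, and a relative 5'-end position in [0, 1).
    ``positional_profile="end_biased"`` concentrates mass near both feature
    ends (a Beta(1,6)/uniform/Beta(6,1) mixture), mimicking read pileups at
    TE extremities; ``"uniform"`` spreads reads evenly over the body.
    """
    if not cargo:
        raise ValueError("cargo must be non-empty")
    length_dist = dict(DEFAULT_LENGTH_DIST if length_dist is None else length_dist)
    p5_bias = dict(DEFAULT_P5_BIAS if p5_bias is None else p5_bias)
    if any(not 18 <= k <= 26 for k in length_dist):
        raise ValueError("length_dist keys must lie in 18..26")
    if set(p5_bias) - {"A", "C", "G", "U"}:
        raise ValueError("p5_bias keys must be RNA nucleotides A/C/G/U")
    for name, dist in (("length_dist", length_dist), ("p5_bias", p5_bias)):
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1")
    if positional_profile not in ("uniform", "end_biased"):
        raise ValueError("positional_profile must be 'uniform' or 'end_biased'")

    rng = stream_rng(seed, "srna_reads")
    cargo_list = sorted(cargo)
    lengths = rng.choice(list(length_dist), size=n_reads, p=list(length_dist.values()))
    nts = rng.choice(list(p5_bias), size=n_reads, p=list(p5_bias.values()))
    feats = rng.choice(cargo_list, size=n_reads)
    if positional_profile == "uniform":
        pos = rng.random(n_reads)
    else:
        comp = rng.choice(3, size=n_reads, p=[0.4, 0.2, 0.4])
        pos = np.where(
            comp == 0, rng.beta(1.0, 6.0, n_reads),
            np.where(comp == 1, rng.random(n_reads), rng.beta(6.0, 1.0, n_reads)))
    pos = np.clip(pos, 0.0, np.nextafter(1.0, 0.0))
    return pd.DataFrame(
        {
            "read_id": [f"r{i:07d}" for i in range(n_reads)],
            "feature_id": feats,
            "length": lengths.astype(int),
            "first_nt": nts,
            "rel_pos": pos,
            "weight": 1.0,
        }
    )
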