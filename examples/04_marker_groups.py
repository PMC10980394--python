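"""Confirm TE-cluster expression by marker-defined nucleus groups.

Nuclei expressing both AGO5 and AGO9 (>= 2 reads each) stand in for the L2
layer, AGO9-only for L1.  The niche-elevated TE clusters should be higher
in double-positive nuclei, and the AGO cargo sets should overlap them.
"""

import samniche as sn

adata, truth = sn.generate_dataset(sn.SimConfig(seed=7))
adata = sn.filter_nuclei(adata, 100, 1000)
adata = sn.filter_features(adata, 4)

adata.obs["marker_group"] = sn.classify_nuclei_by_markers(adata, min_reads=2)
adata.obs["cell_cycle"] = sn.assign_cell_cycle(adata)
print("marker groups:", adata.obs["marker_group"].value_counts().to_dict())
print("cell cycle:   ", adata.obs["cell_cycle"].value_counts().to_dict())

seeds = [s for s in truth.seed_gene_ids if s in adata.var_names]
cyc = ["HTR13", "CDT1A", "CYCB1.1"]
te_ids = list(adata.var_names[adata.var["kind"] == "transposon"])
adj = sn.adjusted_from_counts(adata, n_null=100, seed=7,
                              feature_subset=seeds + cyc + te_ids)
profiles = sn.extract_seed_profiles(adj, sn.SeedGeneSet(seeds + cyc), te_ids)
assign = sn.cluster_features(profiles, k=3)

res = sn.compare_te_expression(adata, assign)
res = res[(res.group_a == "AGO5_AGO9") & (res.group_b == "none")]
for _, row in res.iterrows():
    arrow = "higher" if row.direction > 0 else "lower/equal"
    print(f"cluster {row.cluster}: AGO5&AGO9 vs none, U-test p = {row.p:.2e} "
          f"({arrow} in AGO5&AGO9)")

# overlap of simulated AGO cargo with the recovered TE clusters (phyper)
cargo = sn.generate_cargo_sets(truth, jaccard_with_programs=0.7,
                               sizes={"AGO5_cargo": 100, "AGO9_cargo": 120}, seed=7)
universe = set(te_ids)
for name, ids in cargo.items():
    for c in range(1, 4):
        ov = sn.hypergeometric_overlap(set(assign.members(c)), ids & universe,
                                       universe)
        print(f"{name} x cluster {c}: overlap {ov.overlap}/{ov.size_a}, "
              f"fold {ov.fold:.1f}, p = {ov.p:.2e}")

length = sn.te_length_comparison(cargo["AGO5_cargo"], adata.var)
print(f"cargo TEs vs others, length U-test p = {length.p:.2e}, "
      f"medians {length.median_a:.0f} vs {length.median_b:.0f} bp")
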