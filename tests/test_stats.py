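"""Marker classification, Mann-Whitney paths, hypergeometric overlap."""

from itertools import combinations
from math import comb

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

import samniche as sn
from samniche.stats import mann_whitney


def _marker_adata(rows):
    """rows: list of (AGO5, AGO9, HTR13, CDT1A, CYCB1.1) counts."""
    genes = ["AGO5", "AGO9", "HTR13", "CDT1A", "CYCB1.1"]
    X = np.array(rows, dtype=np.int64)
    var = pd.DataFrame({"kind": "gene"}, index=genes)
    obs = pd.DataFrame(index=[f"n{i}" for i in range(len(rows))])
    return ad.AnnData(X=X, obs=obs, var=var)


class TestMarkerClassification:
    @pytest.mark.parametrize("ago5,ago9,expected", [
        (2, 3, "AGO5_AGO9"),   # both at the 2-read threshold
        (1, 2, "AGO9_only"),
        (5, 0, "AGO5_only"),
        (0, 0, "none"),
        (1, 1, "none"),
    ])
    def test_threshold_rule(self, ago5, ago9, expected):
        adata = _marker_adata([(ago5, ago9, 0, 0, 0)])
        got = sn.classify_nuclei_by_markers(adata)
        assert got.iloc[0] == expected

    def test_labels_partition_nuclei(self, qc_dataset):
        adata, _ = qc_dataset
        groups = sn.classify_nuclei_by_markers(adata)
        assert groups.notna().all()
        assert len(groups) == adata.n_obs

    def test_missing_marker_raises(self):
        adata = _marker_adata([(1, 1, 0, 0, 0)])
        with pytest.raises(KeyError, match="AGO7"):
            sn.classify_nuclei_by_markers(adata, ago5="AGO7")

    def test_l2_nuclei_dominate_double_positive_group(self, qc_dataset):
        adata, truth = qc_dataset
        groups = sn.classify_nuclei_by_markers(adata)
        niche = truth.niche_per_nucleus.loc[adata.obs_names]
        double = groups == "AGO5_AGO9"
        assert (niche[double] == "L2").mean() > 0.8


class TestCellCycleAssignment:
    @pytest.mark.parametrize("htr13,cdt1a,cycb,expected", [
        (0, 3, 0, "G1"),
        (4, 0, 1, "S-G2"),
        (0, 0, 2, "G2-M"),
        (1, 0, 1, "unassigned"),  # tie
        (0, 0, 0, "unassigned"),
    ])
    def test_argmax_rule(self, htr13, cdt1a, cycb, expected):
        adata = _marker_adata([(0, 0, htr13, cdt1a, cycb)])
        assert sn.assign_cell_cycle(adata).iloc[0] == expected

    def test_recovers_planted_phases(self, qc_dataset):
        adata, truth = qc_dataset
        got = sn.assign_cell_cycle(adata)
        assigned = got != "unassigned"
        agree = (got[assigned] == truth.cycle_per_nucleus.loc[adata.obs_names][assigned])
        assert assigned.mean() > 0.5
        assert agree.mean() > 0.9


class TestMannWhitney:
    def test_textbook_exact_case(self):
        r = mann_whitney([1, 2], [3, 4])
        assert r.U == 0
        assert r.p == pytest.approx(1 / 3)
        assert r.direction == -1

    def test_identical_groups(self):
        r = mann_whitney([5, 5, 5], [5, 5, 5])
        assert r.p == 1.0
        assert r.direction == 0

    def test_exact_path_matches_scipy_on_tie_free_data(self, rng):
        # scipy's exact distribution is the independent oracle when there
        # are no ties
        for _ in range(25):
            n, m = rng.integers(2, 9, size=2)
            a = rng.permutation(np.arange(1.0, n + m + 1))[:n]
            b = np.setdiff1d(np.arange(1.0, n + m + 1), a)
            ours = mann_whitney(a, b).p
            ref = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_exact_path_handles_ties_by_enumeration(self, rng):
        # with ties, compare against a direct enumeration written here
        a = np.array([0.0, 1.0, 1.0])
        b = np.array([1.0, 2.0, 2.0, 3.0])
        from scipy.stats import rankdata

        pooled = np.concatenate([a, b])
        ranks = rankdata(pooled)
        n = len(a)
        mu = len(a) * len(b) / 2
        u_obs = ranks[:n].sum() - n * (n + 1) / 2
        hits = sum(
            abs(sum(ranks[list(idx)]) - n * (n + 1) / 2 - mu) >= abs(u_obs - mu) - 1e-9
            for idx in combinations(range(len(pooled)), n))
        expected = hits / comb(len(pooled), n)
        assert mann_whitney(a, b).p == pytest.approx(expected)

    def test_normal_approximation_tracks_exact(self, rng):
        # at sizes just above the exact cutoff the approximation should be
        # within 10% relative error of the enumerated p
        for _ in range(5):
            a = rng.normal(size=9)
            b = rng.normal(loc=0.8, size=9)
            approx = mann_whitney(a, b).p          # normal path (9 > 8)
            exact = mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact").pvalue
            assert approx == pytest.approx(exact, rel=0.10)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1.0], [2.0, 3.0])


class TestHypergeometricOverlap:
    def test_known_tail_probability(self):
        universe = {f"x{i}" for i in range(10)}
        a = set(list(universe)[:5])
        b = set(list(universe)[:4])
        r = sn.hypergeometric_overlap(a, b, universe)
        assert r.overlap == 4
        assert r.p == pytest.approx(5 / 210)

    def test_disjoint_small_sets_not_significant(self):
        universe = {f"x{i}" for i in range(1000)}
        r = sn.hypergeometric_overlap({"x1", "x2"}, {"x10", "x11"}, universe)
        assert r.p > 0.99

    def test_full_overlap_boundary(self):
        u = {"a", "b", "c"}
        r = sn.hypergeometric_overlap(u, u, u)
        assert r.overlap == 3
        assert r.p == pytest.approx(1.0)

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            sn.hypergeometric_overlap({"z"}, {"a"}, {"a", "b"})

    def test_matches_enumeration_for_small_universes(self, rng):
        # brute force: enumerate all C(M, N) draws of set_b and count those
        # overlapping set_a at least as much
        for _ in range(40):
            M = int(rng.integers(3, 13))
            universe = [f"u{i}" for i in range(M)]
            K = int(rng.integers(1, M + 1))
            N = int(rng.integers(1, M + 1))
            a = set(rng.choice(universe, size=K, replace=False))
            b = set(rng.choice(universe, size=N, replace=False))
            k_obs = len(a & b)
            hits = sum(1 for draw in combinations(universe, N)
                       if len(a & set(draw)) >= k_obs)
            expected = hits / comb(M, N)
            got = sn.hypergeometric_overlap(a, b, set(universe)).p
            assert got == pytest.approx(expected, abs=1e-12)


class TestTeExpressionComparisons:
    def test_planted_l2_clusters_elevated_in_double_positive(
            self, qc_dataset, adjusted_te_profiles):
        adata, truth = qc_dataset
        _, profiles = adjusted_te_profiles
        assign = sn.cluster_features(profiles, k=3)
        adata = adata.copy()
        adata.obs["marker_group"] = sn.classify_nuclei_by_markers(adata)
        res = sn.compare_te_expression(adata, assign)
        # map recovered clusters to planted programs by majority vote
        prog = truth.program_per_feature
        majority = {}
        for c in range(1, 4):
            members = assign.members(c)
            majority[c] = prog.loc[members].mode().iloc[0]
        res = res[(res.group_a == "AGO5_AGO9") & (res.group_b == "none")]
        for _, row in res.iterrows():
            planted = majority[row.cluster]
            if planted in ("te_cluster2", "te_cluster3"):
                assert row.p < 0.01 and row.direction > 0, planted

    def test_small_groups_skipped(self, qc_dataset, adjusted_te_profiles):
        adata, _ = qc_dataset
        _, profiles = adjusted_te_profiles
        assign = sn.cluster_features(profiles, k=3)
        adata = adata.copy()
        adata.obs["marker_group"] = "none"
        adata.obs.iloc[0, adata.obs.columns.get_loc("marker_group")] = "AGO5_AGO9"
        res = sn.compare_te_expression(adata, assign)
        assert not ((res.get("group_a") == "AGO5_AGO9").any()
                    if len(res) else False)


class TestTeLengthComparison:
    def test_longer_cargo_detected(self):
        feats = pd.DataFrame({
            "kind": "transposon",
            "length_bp": [5000, 6000, 500, 600],
        }, index=["c1", "c2", "o1", "o2"])
        r = sn.te_length_comparison({"c1", "c2"}, feats)
        assert r.direction == 1
        assert r.p == pytest.approx(1 / 3)

    def test_cargo_tes_longer_on_synthetic_defaults(self, default_dataset):
        adata, truth = default_dataset
        cargo = sn.generate_cargo_sets(truth, 0.8, {"AGO5_cargo": 100}, seed=3)
        r = sn.te_length_comparison(cargo["AGO5_cargo"], adata.var)
        assert r.direction == 1
        assert r.p < 1e-6

    def test_no_comparison_group_rejected(self):
        feats = pd.DataFrame({"kind": "transposon", "length_bp": [100]},
                             index=["c1"])
        with pytest.raises(ValueError, match="non-cargo"):
            sn.te_length_comparison({"c1"}, feats)
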