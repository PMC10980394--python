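"""sRNA profiles, metaplots, and cargo enrichment."""

import numpy as np
import pandas as pd
import pytest

import samniche as sn


def _reads(rows):
    """rows: (feature_id, length, first_nt, rel_pos, weight)."""
    return pd.DataFrame(
        [{"read_id": f"r{i}", "feature_id": f, "length": ln, "first_nt": nt,
          "rel_pos": pos, "weight": w}
         for i, (f, ln, nt, pos, w) in enumerate(rows)])


def _features(ids, length=1000, strand=None):
    df = pd.DataFrame({"kind": "transposon", "length_bp": length,
                       "superfamily": "LTR/Gypsy"}, index=ids)
    if strand is not None:
        df["strand"] = strand
    return df


class TestSize5pProfile:
    def test_point_mass(self):
        reads = _reads([("t", 24, "A", 0.5, 1.0)] * 10)
        prof = sn.size_5p_profile(reads)
        assert prof.proportions_overall.loc[24, "A"] == pytest.approx(1.0)
        assert prof.total_weight == pytest.approx(10.0)

    def test_marginal_length_proportions(self):
        reads = _reads([("t", 21, "C", 0.1, 1.0)] * 5
                       + [("t", 24, "A", 0.1, 1.0)] * 5)
        prof = sn.size_5p_profile(reads)
        marginal = prof.proportions_overall.sum(axis=1)
        assert marginal.loc[21] == pytest.approx(0.5)
        assert marginal.loc[24] == pytest.approx(0.5)

    def test_per_length_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        reads = sn.generate_srna_reads({"a"}, 2000, seed=4)
        reads["weight"] = rng.uniform(0.1, 1.0, len(reads))
        prof = sn.size_5p_profile(reads)
        sums = prof.proportions_per_length.sum(axis=1)
        nonzero = prof.counts.sum(axis=1) > 0
        assert np.allclose(sums[nonzero], 1.0)

    def test_recovers_planted_bias(self):
        reads = sn.generate_srna_reads(
            {"a"}, 10_000, length_dist={24: 1.0},
            p5_bias={"A": 0.7, "C": 0.1, "G": 0.1, "U": 0.1}, seed=5)
        prof = sn.size_5p_profile(reads)
        est = prof.proportions_per_length.loc[24, "A"]
        se = np.sqrt(0.7 * 0.3 / 10_000)
        assert abs(est - 0.7) < 3 * se

    def test_empty_reads_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sn.size_5p_profile(_reads([]))


class TestMetaplot:
    def test_single_read_lands_in_expected_bin(self):
        reads = _reads([("t", 21, "A", 0.505, 1.0)])
        meta = sn.metaplot(reads, _features(["t"]), body_bins=100)
        col = np.flatnonzero(meta.matrix.to_numpy().sum(axis=0))
        assert list(col) == [50]

    def test_minus_strand_flipped(self):
        reads = _reads([("t", 21, "A", 0.05, 1.0)])
        meta = sn.metaplot(reads, _features(["t"], strand="-"), body_bins=10)
        col = np.flatnonzero(meta.matrix.to_numpy().sum(axis=0))
        assert list(col) == [9]

    def test_raw_mass_conserved_exactly(self):
        rng = np.random.default_rng(1)
        reads = sn.generate_srna_reads({"a", "b", "c"}, 5000,
                                       positional_profile="end_biased", seed=6)
        reads["weight"] = rng.uniform(0.05, 1.0, len(reads))
        meta = sn.metaplot(reads, _features(["a", "b", "c"]), body_bins=50)
        assert meta.matrix.to_numpy().sum() == pytest.approx(
            reads["weight"].sum(), abs=1e-9)

    def test_uniform_reads_fill_bins_evenly(self):
        n, bins = 20_000, 20
        reads = sn.generate_srna_reads({"a"}, n, positional_profile="uniform",
                                       seed=7)
        meta = sn.metaplot(reads, _features(["a"]), body_bins=bins)
        per_bin = meta.matrix.sum(axis=0).to_numpy()
        expect = n / bins
        se = np.sqrt(n * (1 / bins) * (1 - 1 / bins))
        assert np.all(np.abs(per_bin - expect) < 4 * se)

    def test_end_biased_mass_concentrates_at_extremes(self):
        reads = sn.generate_srna_reads({"a"}, 10_000,
                                       length_dist={21: 1.0},
                                       positional_profile="end_biased", seed=8)
        meta = sn.metaplot(reads, _features(["a"]), body_bins=10)
        per_bin = meta.matrix.loc["21"].to_numpy()
        ends = per_bin[0] + per_bin[-1]
        middle = per_bin[4] + per_bin[5]
        assert ends > 2 * middle

    def test_unknown_feature_rejected(self):
        reads = _reads([("ghost", 21, "A", 0.5, 1.0)])
        with pytest.raises(KeyError, match="ghost"):
            sn.metaplot(reads, _features(["t"]))

    def test_out_of_body_read_needs_flank(self):
        reads = _reads([("t", 21, "A", 0.5, 1.0)])
        reads.loc[0, "rel_pos"] = -0.01
        with pytest.raises(ValueError, match="flank"):
            sn.metaplot(reads, _features(["t"]))
        meta = sn.metaplot(reads, _features(["t"]), flank_bp=100)
        assert meta.matrix.to_numpy().sum() == pytest.approx(1.0)
        assert np.flatnonzero(meta.matrix.to_numpy().sum(axis=0))[0] < meta.upstream_bins


class TestCargoEnrichment:
    def _series(self, vals, n=None):
        idx = [f"f{i}" for i in range(len(vals))]
        return pd.Series(vals, index=idx, dtype=float)

    def test_strongly_enriched_feature_called(self):
        cargo = self._series([90] + [910 / 9] * 9)
        inp = self._series([10] + [990 / 9] * 9)
        res = sn.cargo_enrichment(cargo, inp)
        assert res.loc["f0", "log2fc"] == pytest.approx(np.log2(9), abs=0.01)
        assert bool(res.loc["f0", "enriched"])

    def test_identical_libraries_give_no_calls(self):
        vals = self._series([50, 100, 200, 400])
        res = sn.cargo_enrichment(vals, vals.copy())
        assert not res["enriched"].any()

    def test_low_abundance_filtered_before_testing(self):
        # feature at 4 reads-per-million in both libraries is removed
        cargo = self._series([4, 10 ** 6 - 4])
        inp = self._series([4, 10 ** 6 - 4])
        res = sn.cargo_enrichment(cargo, inp, min_normalized=5)
        assert "f0" not in res.index
        assert "f1" in res.index

    def test_swapped_libraries_flip_log2fc(self):
        rng = np.random.default_rng(2)
        cargo = self._series(rng.integers(0, 500, size=40).astype(float))
        inp = self._series(rng.integers(1, 500, size=40).astype(float))
        fwd = sn.cargo_enrichment(cargo, inp)
        rev = sn.cargo_enrichment(inp, cargo)
        common = fwd.index.intersection(rev.index)
        np.testing.assert_allclose(fwd.loc[common, "log2fc"],
                                   -rev.loc[common, "log2fc"], atol=1e-9)

    def test_binomial_tail_oracle(self):
        from scipy.stats import binomtest

        cargo = self._series([90] + [91] * 9)
        inp = self._series([10] + [110] * 9)
        res = sn.cargo_enrichment(cargo, inp, min_normalized=0.001)
        n = int(cargo.sum())
        expected = binomtest(90, n, 10 / inp.sum()).pvalue
        assert res.loc["f0", "p"] == pytest.approx(expected)


class TestSuperfamilyTable:
    def test_proportions(self):
        feats = pd.DataFrame(
            {"superfamily": ["LTR/Gypsy"] * 6 + ["RC/Helitron"] * 2 + ["other"] * 2},
            index=[f"t{i}" for i in range(10)])
        tab = sn.classify_cargo_by_superfamily([f"t{i}" for i in range(10)], feats)
        assert tab.set_index("superfamily").loc["LTR/Gypsy", "proportion"] == \
            pytest.approx(0.6)

    def test_empty_set(self):
        tab = sn.classify_cargo_by_superfamily([], pd.DataFrame({"superfamily": []}))
        assert len(tab) == 0

    def test_synthetic_cargo_is_gypsy_dominated(self, default_dataset):
        adata, truth = default_dataset
        cargo = sn.generate_cargo_sets(truth, 0.8, {"AGO5_cargo": 100}, seed=9)
        tab = sn.classify_cargo_by_superfamily(cargo["AGO5_cargo"], adata.var)
        assert tab.iloc[0]["superfamily"] == "LTR/Gypsy"
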