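"""Association: probe collapsing, per-batch correlations, fixed-effect pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import coexmeta as cm
from coexmeta.association import (batch_correlations, collapse_probes,
                                  fisher_z, meta_fixed_effect, rank_genes,
                                  seed_profile)


def _brute_force_meta(pairs):
    """Independent weighted-average oracle for inverse-variance pooling."""
    ws = [1.0 / se**2 for _, se in pairs]
    zbar = sum(w * z for (z, _), w in zip(pairs, ws)) / sum(ws)
    se = (1.0 / sum(ws)) ** 0.5
    return zbar, se, zbar / se


class TestCollapseProbes:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["s1", "s2"])

    def test_single_probe_identity(self):
        data = pd.DataFrame([[1.0, 2.0]], index=["G1.p1"], columns=["s1", "s2"])
        pm = pd.DataFrame({"probe_id": ["G1.p1"], "gene_symbol": ["G1"]})
        out = collapse_probes(data, pm, ["G1"])
        np.testing.assert_allclose(out.loc["G1"].to_numpy(), [1.0, 2.0])

    def test_mean_of_probes(self):
        data = pd.DataFrame([[2.0, 1.0], [4.0, 2.0], [6.0, 6.0]],
                            index=["G1.a", "G1.b", "G1.c"], columns=["s1", "s2"])
        pm = pd.DataFrame({"probe_id": ["G1.a", "G1.b", "G1.c"],
                           "gene_symbol": ["G1"] * 3})
        out = collapse_probes(data, pm, ["G1"])
        brute = data.to_numpy().mean(axis=0)
        np.testing.assert_allclose(out.loc["G1"].to_numpy(), brute)
        assert out.loc["G1", "s1"] == pytest.approx(4.0)

    def test_missing_gene_raises_with_name(self):
        data = pd.DataFrame([[1.0, 2.0]], index=["G1.p1"], columns=["s1", "s2"])
        pm = pd.DataFrame({"probe_id": ["G1.p1"], "gene_symbol": ["G1"]})
        with pytest.raises(KeyError, match="G2"):
            collapse_probes(data, pm, ["G2"])


class TestBatchCorrelations:
    def _batch(self, rows, index):
        cols = [f"s{i}" for i in range(len(rows[0]))]
        return cm.ExpressionBatch("B", pd.DataFrame(rows, index=index, columns=cols))

    def test_self_correlation_is_one(self):
        seed = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0],
                         index=[f"s{i}" for i in range(5)])
        batch = self._batch([[1, 2, 3, 4, 5.0]], ["g"])
        out = batch_correlations(batch, seed)
        assert out.loc["g", "r"] == pytest.approx(1.0)

    def test_negated_seed_gives_minus_one(self):
        seed = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0],
                         index=[f"s{i}" for i in range(5)])
        batch = self._batch([[-1, -2, -3, -4, -5.0]], ["g"])
        out = batch_correlations(batch, seed)
        assert out.loc["g", "r"] == pytest.approx(-1.0)

    def test_matches_brute_force_covariance_formula(self):
        # the hand example: brute two-pass Pearson of (1..5) vs (2,1,4,3,6)
        s = [1.0, 2.0, 3.0, 4.0, 5.0]
        g = [2.0, 1.0, 4.0, 3.0, 6.0]
        n = 5
        ms, mg = sum(s) / n, sum(g) / n
        cov = sum((a - ms) * (b - mg) for a, b in zip(s, g))
        brute = cov / (sum((a - ms) ** 2 for a in s)
                       * sum((b - mg) ** 2 for b in g)) ** 0.5
        seed = pd.Series(s, index=[f"s{i}" for i in range(5)])
        out = batch_correlations(self._batch([g], ["g"]), seed)
        assert out.loc["g", "r"] == pytest.approx(brute, abs=1e-12)
        assert out.loc["g", "se"] == pytest.approx(1.0 / np.sqrt(2))

    def test_zero_variance_gene_recorded_missing(self):
        seed = pd.Series([1.0, 2, 3, 4, 5], index=[f"s{i}" for i in range(5)])
        out = batch_correlations(self._batch([[7.0] * 5], ["flat"]), seed)
        assert np.isnan(out.loc["flat", "r"])

    def test_too_few_samples_rejected(self):
        seed = pd.Series([1.0, 2, 3], index=["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="n=3"):
            batch_correlations(self._batch([[1, 2, 3.0]], ["g"]), seed)


class TestFisherZ:
    def test_zero_correlation(self):
        z, se = fisher_z(0.0, 10)
        assert z == 0.0

    def test_se_exact_at_n7(self):
        assert fisher_z(0.3, 7)[1] == pytest.approx(0.5)

    def test_atanh_value(self):
        # atanh(0.5) via its series/log form: 0.5*ln(3)
        assert fisher_z(0.5, 20)[0] == pytest.approx(0.5 * np.log(3.0), abs=1e-12)

    def test_extreme_r_clipped_finite(self):
        z, _ = fisher_z(1.0, 10)
        assert np.isfinite(z)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(0.5, 3)


class TestMetaFixedEffect:
    def test_single_batch_identity(self):
        z, se = 0.42, 0.1
        zbar, sep, stat, _ = meta_fixed_effect([(z, se)])
        assert zbar == pytest.approx(z)
        assert sep == pytest.approx(se)
        assert stat == pytest.approx(z / se)

    def test_two_identical_batches_scale_by_sqrt2(self):
        z, se = 0.3, 0.2
        _, _, single, _ = meta_fixed_effect([(z, se)])
        zbar, _, double, _ = meta_fixed_effect([(z, se), (z, se)])
        assert zbar == pytest.approx(z)
        assert double == pytest.approx(single * np.sqrt(2), abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            pairs = [(rng.normal(), rng.uniform(0.05, 1.0))
                     for _ in range(rng.integers(1, 6))]
            zbar, sep, stat, _ = meta_fixed_effect(pairs)
            ozbar, ose, ostat = _brute_force_meta(pairs)
            assert zbar == pytest.approx(ozbar, abs=1e-12)
            assert sep == pytest.approx(ose, abs=1e-12)
            assert stat == pytest.approx(ostat, abs=1e-12)

    def test_matches_statsmodels_combine_effects(self):
        from statsmodels.stats.meta_analysis import combine_effects
        rng = np.random.default_rng(9)
        effects = rng.normal(size=4)
        ses = rng.uniform(0.1, 0.5, size=4)
        zbar, _, _, _ = meta_fixed_effect(list(zip(effects, ses)))
        res = combine_effects(effects, ses**2)
        assert zbar == pytest.approx(res.summary_frame().loc["fixed effect",
                                                             "eff"], abs=1e-10)

    @given(st.permutations(range(4)))
    def test_invariant_to_batch_order(self, order):
        pairs = [(0.1, 0.3), (-0.2, 0.15), (0.4, 0.5), (0.05, 0.08)]
        base = meta_fixed_effect(pairs)
        perm = meta_fixed_effect([pairs[i] for i in order])
        assert base[2] == pytest.approx(perm[2], abs=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            meta_fixed_effect([])

    def test_nan_batches_skipped(self):
        full = meta_fixed_effect([(0.2, 0.1)])
        with_nan = meta_fixed_effect([(0.2, 0.1), (np.nan, np.nan)])
        assert full == pytest.approx(with_nan)


class TestRanking:
    def test_rank_is_sort_permutation(self, fitted_meta):
        table = fitted_meta.table_
        stats = table["statistic"].to_numpy()
        assert (np.diff(stats) <= 1e-12).all()
        assert sorted(table["rank"]) == list(range(1, len(table) + 1))

    def test_k_equals_universe(self, fitted_meta):
        table = fitted_meta.table_
        k = int((~table["is_seed"]).sum())
        _, top, _ = rank_genes(table, k)
        assert len(top) == k

    def test_seed_attains_max_statistic_and_is_excluded(self, fitted_meta):
        table = fitted_meta.table_
        assert table.iloc[0]["is_seed"]
        assert not fitted_meta.top_["is_seed"].any()

    def test_pooled_correlation_strictly_inside_unit_interval(self, fitted_meta):
        r = fitted_meta.table_["r_pooled"].to_numpy()
        assert (np.abs(r) < 1).all()

    def test_planted_genes_dominate_top_k(self, small_compendium,
                                          small_probe_map, fitted_meta):
        _, truth = small_compendium
        planted = set(truth.associated_genes)
        _, top, _ = rank_genes(fitted_meta.table_, len(planted))
        hits = set(top["gene_symbol"]) & planted
        assert len(hits) >= len(planted) - 1


class TestSeedAssociationMeta:
    def test_single_batch_pooled_equals_per_batch(self, small_probe_map):
        cfg = cm.SimConfig(n_batches=1, samples_per_batch=(60,), n_genes=100,
                           module_size=5, n_outliers=0, rng_seed=3)
        batches, _ = cm.generate_compendium(cfg)
        from coexmeta.simulate import probe_map_frame
        pm = probe_map_frame(batches)
        meta = cm.SeedAssociationMeta(top_k=10).fit(batches, pm)
        per = batch_correlations(batches[0],
                                 seed_profile(batches[0], pm, "MS4A1"))
        merged = meta.table_.set_index("probe_id").join(per, rsuffix="_batch")
        valid = merged.dropna(subset=["z"])
        np.testing.assert_allclose(valid["statistic"],
                                   valid["z"] / valid["se"], atol=1e-10)

    def test_gene_level_mode_collapses_first(self):
        cfg = cm.SimConfig(n_batches=1, samples_per_batch=(50,), n_genes=40,
                           module_size=3, probes_per_gene=2, n_outliers=0,
                           rng_seed=6)
        batches, _ = cm.generate_compendium(cfg)
        from coexmeta.simulate import probe_map_frame
        pm = probe_map_frame(batches)
        meta = cm.SeedAssociationMeta(top_k=10, level="gene").fit(batches, pm)
        assert (meta.table_["probe_id"] == meta.table_["gene_symbol"]).all()
        assert len(meta.table_) == 40

    def test_pooled_r_recovers_planted_correlation(self):
        rho = 0.7
        pooled = []
        for seed in range(15):
            cfg = cm.SimConfig(n_batches=2, samples_per_batch=(500, 500),
                               n_genes=30, module_size=1,
                               module_correlations=[rho], n_outliers=0,
                               probe_noise_sd=0.0, rng_seed=100 + seed)
            batches, truth = cm.generate_compendium(cfg)
            from coexmeta.simulate import probe_map_frame
            meta = cm.SeedAssociationMeta(top_k=5).fit(
                batches, probe_map_frame(batches))
            (gene,) = truth.associated_genes
            row = meta.table_[meta.table_["gene_symbol"] == gene]
            pooled.append(float(row["r_pooled"].iloc[0]))
        assert abs(np.mean(pooled) - rho) < 0.02
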