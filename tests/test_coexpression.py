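import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from regkit import coexpression as C
from regkit import synthetic as S


def planted_two_tissue(n_genes=400, n_samples=60, noise=0.5, seed=3,
                       shared_flags=(True, False, True, False, True)):
    cfg = S.ExprSimConfig(
        n_genes, n_samples,
        modules=[(60, 1.0, flag) for flag in shared_flags],
        noise_sd=noise, seed=seed)
    return S.gen_two_tissue_expression(cfg)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0]})
        out = C.quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m)

    def test_forced_two_column_example(self):
        m = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 6.0]})
        out = C.quantile_normalize(m)
        assert np.allclose(out["a"], [1.5, 4.5])
        assert np.allclose(out["b"], [1.5, 4.5])

    def test_column_means_equal(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(50, 6)) * [1, 2, 3, 4, 5, 6])
        out = C.quantile_normalize(m)
        means = out.mean(axis=0).to_numpy()
        assert np.allclose(means, means[0], atol=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(40, 5)))
        once = C.quantile_normalize(m)
        twice = C.quantile_normalize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_missing_values_rejected(self):
        m = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(C.CoexpressionError):
            C.quantile_normalize(m)


class TestWgcnaModules:
    def test_two_noise_free_blocks(self):
        cfg = S.ExprSimConfig(80, 20, modules=[(40, 1.0, True), (40, 1.0, True)],
                              noise_sd=0.0, seed=5)
        a, _, labels = S.gen_two_tissue_expression(cfg)
        # zero noise makes rows exactly collinear; add a whisper of jitter
        rng = np.random.default_rng(0)
        a = a + rng.normal(0, 1e-6, a.shape)
        ms = C.wgcna_modules(a, min_size=30, cut_height=0.9)
        assert len(ms) == 2
        found = sorted(tuple(sorted(m.genes)) for m in ms.modules)
        truth = sorted(
            tuple(sorted(labels[labels == f"m{i}"].index)) for i in (1, 2))
        assert found == truth

    def test_beta_one_adjacency_is_abs_r(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(2, 30))
        r = abs(np.corrcoef(x)[0, 1])
        adj = np.abs(np.corrcoef(x)) ** 1
        assert np.isclose(adj[0, 1], r)

    def test_planted_recovery_ari(self):
        a, _, labels = planted_two_tissue()
        an = C.quantile_normalize(a)
        ms = C.wgcna_modules(an, min_size=30, cut_height=0.95)
        g2m = ms.gene_to_module()
        pred = [g2m.get(g, "unclustered") for g in labels.index]
        assert adjusted_rand_score(labels.tolist(), pred) >= 0.9

    def test_constant_gene_dropped_with_warning(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(40, 10)))
        m.iloc[0] = 3.0
        with pytest.warns(UserWarning):
            ms = C.wgcna_modules(m, min_size=5, cut_height=0.99)
        assert 0 not in ms.gene_to_module()


class TestTightClusters:
    def test_noise_free_module_single_cluster(self):
        cfg = S.ExprSimConfig(20, 20, modules=[(20, 1.0, True)],
                              noise_sd=0.0, seed=9)
        a, _, _ = S.gen_two_tissue_expression(cfg)
        mod = C.Module("f-1", tuple(a.index), "wgcna")
        ms = C.tight_clusters(a, mod, seed=1)
        assert len(ms) == 1
        assert set(ms.modules[0].genes) == set(a.index)

    def test_two_halves_recovered(self):
        cfg = S.ExprSimConfig(40, 40, modules=[(20, 2.0, True), (20, 2.0, True)],
                              noise_sd=0.3, seed=10)
        a, _, labels = S.gen_two_tissue_expression(cfg)
        mod = C.Module("f-1", tuple(a.index), "wgcna")
        ms = C.tight_clusters(a, mod, seed=2)
        halves = [set(labels[labels == f"m{i}"].index) for i in (1, 2)]
        best = []
        for half in halves:
            jac = max((len(half & set(m.genes)) / len(half | set(m.genes)))
                      for m in ms.modules)
            best.append(jac)
        assert min(best) >= 0.8

    def test_consensus_one_shrinks_clusters(self):
        cfg = S.ExprSimConfig(30, 30, modules=[(30, 1.0, True)],
                              noise_sd=1.0, seed=11)
        a, _, _ = S.gen_two_tissue_expression(cfg)
        mod = C.Module("f-1", tuple(a.index), "wgcna")
        loose = C.tight_clusters(a, mod, consensus=0.7, seed=3)
        strict = C.tight_clusters(a, mod, consensus=1.0, seed=3)
        assert sum(m.size for m in strict.modules) <= \
               sum(m.size for m in loose.modules)

    def test_small_module_rejected(self):
        rng = np.random.default_rng(12)
        a = pd.DataFrame(rng.normal(size=(2, 10)), index=["g1", "g2"])
        with pytest.raises(C.CoexpressionError):
            C.tight_clusters(a, C.Module("f-1", ("g1", "g2"), "wgcna"),
                             min_size=3)


class TestCoherentClusters:
    def test_shared_cluster_retained(self):
        cfg = S.ExprSimConfig(10, 30, modules=[(10, 1.0, True)],
                              noise_sd=0.0, seed=13)
        a, b, _ = S.gen_two_tissue_expression(cfg)
        tight = C.ModuleSet("tight", [C.Module("f-1-1", tuple(a.index), "tight")])
        coherent, specific = C.coherent_clusters(tight, b)
        assert len(coherent) == 1
        assert set(coherent.modules[0].genes) == set(a.index)
        assert coherent.modules[0].name == "f-1-1-1"
        assert not specific.modules

    def test_uncorrelated_cluster_all_specific(self):
        cfg = S.ExprSimConfig(10, 30, modules=[(10, 2.0, False)],
                              noise_sd=0.2, seed=14)
        a, b, _ = S.gen_two_tissue_expression(cfg)
        tight = C.ModuleSet("tight", [C.Module("f-1-1", tuple(a.index), "tight")])
        coherent, specific = C.coherent_clusters(tight, b)
        assert not coherent.modules
        assert set(specific.modules[0].genes) == set(a.index)

    def test_half_shared_recovers_shared_half(self):
        rng = np.random.default_rng(15)
        genes = [f"g{i:03d}" for i in range(20)]
        factor = rng.normal(size=40)
        b = pd.DataFrame(rng.normal(0, 1.0, size=(20, 40)), index=genes)
        b.iloc[:10] = 2.0 * factor + rng.normal(0, 0.3, size=(10, 40))
        tight = C.ModuleSet("tight", [C.Module("f-1-1", tuple(genes), "tight")])
        coherent, specific = C.coherent_clusters(tight, b, min_r=0.5)
        shared = set(genes[:10])
        got = set(coherent.modules[0].genes)
        jaccard = len(shared & got) / len(shared | got)
        assert jaccard >= 0.8

    def test_partition_exact(self):
        a, b, _ = planted_two_tissue(n_genes=200, shared_flags=(True, False))
        an, bn = C.quantile_normalize(a), C.quantile_normalize(b)
        wg = C.wgcna_modules(an, min_size=30, cut_height=0.95)
        tight = C.tight_clusters_all(an, wg, seed=4)
        coherent, specific = C.coherent_clusters(tight, bn)
        assignment = {}
        for ms in (coherent, specific):
            for m in ms.modules:
                for g in m.genes:
                    assert g not in assignment
                    assignment[g] = m.name
        tight_genes = {g for m in tight.modules for g in m.genes}
        assert set(assignment) == tight_genes

    def test_nesting_invariant(self):
        a, b, _ = planted_two_tissue(n_genes=200, shared_flags=(True, True))
        an, bn = C.quantile_normalize(a), C.quantile_normalize(b)
        wg = C.wgcna_modules(an, min_size=30, cut_height=0.95)
        tight = C.tight_clusters_all(an, wg, seed=5)
        coherent, _ = C.coherent_clusters(tight, bn)
        wg_by_name = {m.name: set(m.genes) for m in wg.modules}
        tight_by_name = {m.name: set(m.genes) for m in tight.modules}
        for m in tight.modules:
            parent = "-".join(m.name.split("-")[:2])
            assert set(m.genes) <= wg_by_name[parent]
        for m in coherent.modules:
            parent = "-".join(m.name.split("-")[:3])
            assert set(m.genes) <= tight_by_name[parent]

    def test_gene_mismatch_rejected(self):
        rng = np.random.default_rng(16)
        b = pd.DataFrame(rng.normal(size=(3, 10)), index=["x", "y", "z"])
        tight = C.ModuleSet("tight", [C.Module("f-1-1", ("a", "b", "c"), "tight")])
        with pytest.raises(C.CoexpressionError):
            C.coherent_clusters(tight, b)


class TestSurvivalFractions:
    def test_shared_vs_independent_simulations(self):
        surv_shared, surv_indep = [], []
        for rep in range(10):
            for shared, out in ((True, surv_shared), (False, surv_indep)):
                cfg = S.ExprSimConfig(120, 60, modules=[(60, 1.5, shared)],
                                      noise_sd=0.5, seed=100 + rep)
                a, b, _ = S.gen_two_tissue_expression(cfg)
                mod = C.Module("f-1", tuple(a.index[:60]), "wgcna")
                tight = C.tight_clusters(a, mod, seed=rep)
                if not tight.modules:
                    continue
                coherent, _ = C.coherent_clusters(tight, b)
                out.append(len(coherent) / len(tight))
        assert np.mean(surv_shared) >= 0.9
        assert np.mean(surv_indep) <= 0.1


class TestModuleEnrichment:
    def test_module_identical_to_list(self):
        import math
        universe = [f"g{i}" for i in range(100)]
        mod = C.Module("m1", tuple(universe[:10]), "coherent")
        ms = C.ModuleSet("coherent", [mod])
        df = C.module_enrichment(ms, {"list": universe[:10]}, universe)
        assert np.isclose(df["pvalue"].iloc[0], 1 / math.comb(100, 10), rtol=1e-9)
        assert df["enriched"].iloc[0]

    def test_disjoint_module_depleted(self):
        universe = [f"g{i}" for i in range(100)]
        mod = C.Module("m1", tuple(universe[:10]), "coherent")
        ms = C.ModuleSet("coherent", [mod])
        df = C.module_enrichment(ms, {"list": universe[50:100]}, universe)
        assert not df["enriched"].iloc[0]
        assert df["pvalue"].iloc[0] < 0.05  # significant depletion

    def test_empty_module_set_rejected(self):
        with pytest.raises(C.CoexpressionError):
            C.module_enrichment(C.ModuleSet("coherent"), {}, ["g1"])

    def test_planted_contingency_significant(self):
        # modules loaded with genes from both lists produce a dependent
        # enrichment pattern; summary contingency must detect it
        rng = np.random.default_rng(20)
        universe = [f"g{i}" for i in range(1200)]
        modules = []
        list_x, list_y = [], []
        for i in range(30):
            genes = universe[i * 20:(i + 1) * 20]
            modules.append(C.Module(f"m{i}", tuple(genes), "coherent"))
            if i < 15:  # hormone + maturation loaded modules
                list_x.extend(genes[:12])
                list_y.extend(genes[:12])
        list_x.extend(rng.choice(universe[600:], 30, replace=False))
        list_y.extend(rng.choice(universe[600:], 30, replace=False))
        ms = C.ModuleSet("coherent", modules)
        df = C.module_enrichment(ms, {"x": set(list_x), "y": set(list_y)},
                                 universe)
        summary = C.enrichment_contingency(df, "x", "y")
        assert summary["p_fisher"] < 0.01
        assert summary["p_chi2"] < 0.01
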