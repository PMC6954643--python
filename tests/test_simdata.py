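"""Properties of the synthetic-study generator."""

import networkx as nx
import numpy as np
import pytest

from cnmtf.simdata import (
    SimConfig,
    plant_phenotypes,
    simulate_annotations_and_ppi,
    simulate_block_genotypes,
    simulate_bundle,
    simulate_genotypes,
)


class TestGenotypes:
    def test_no_differentiation_means_shared_frequencies(self):
        cfg = SimConfig(n_snvs=1000, m_subjects=100, differentiation=0.0, n_causal=0,
                        effect_size=0, seed=3)
        _, _, freqs = simulate_genotypes(cfg)
        assert np.abs(freqs.p_pop0 - freqs.p_pop1).mean() < 0.02

    def test_fst_matches_differentiation_parameter(self):
        # Hudson-style Fst estimator on two populations should recover F ~ 0.1
        cfg = SimConfig(n_snvs=2000, m_subjects=400, differentiation=0.1, n_causal=0,
                        effect_size=0, seed=4)
        geno, ancestry, _ = simulate_genotypes(cfg)
        g = geno.values
        p1 = g[:, ancestry == 0].mean(axis=1) / 2
        p2 = g[:, ancestry == 1].mean(axis=1) / 2
        num = (p1 - p2) ** 2
        den = p1 * (1 - p2) + p2 * (1 - p1)
        ok = den > 0
        fst = num[ok].mean() / den[ok].mean()
        assert 0.05 < fst < 0.15

    def test_fixed_seed_reproducible(self):
        cfg = SimConfig(n_snvs=50, m_subjects=40, seed=9, n_causal=5)
        a, _, _ = simulate_genotypes(cfg)
        b, _, _ = simulate_genotypes(cfg)
        assert np.array_equal(a.values, b.values)

    def test_entries_in_dosage_range(self):
        geno, _, _ = simulate_genotypes(SimConfig(n_snvs=100, m_subjects=50, n_causal=0,
                                                  effect_size=0, seed=1))
        assert set(np.unique(geno.values)) <= {0, 1, 2}


@pytest.fixture(scope="module")
def geno():
    cfg = SimConfig(n_snvs=400, m_subjects=500, n_causal=0, effect_size=0, seed=21)
    g, anc, _ = simulate_genotypes(cfg)
    return g, anc


class TestPhenotypes:
    def test_global_null_has_no_association(self, geno):
        from scipy import stats

        g, anc = geno
        phen = plant_phenotypes(g, anc, [], 0.0, 0.0, seed=5, prevalence=0.4)
        y = (phen["label"] == "case").to_numpy().astype(float)
        # case-minus-control dosage differences should center on zero
        diffs = g.values[:, y == 1].mean(axis=1) - g.values[:, y == 0].mean(axis=1)
        assert abs(diffs.mean()) < 0.02
        assert stats.kstest(diffs / diffs.std(), "norm").pvalue > 0.01

    def test_prevalence_hits_target(self, geno):
        g, anc = geno
        for prev in (0.2, 0.5):
            phen = plant_phenotypes(g, anc, [], 0.0, 0.0, seed=5, prevalence=prev)
            assert abs((phen["label"] == "case").mean() - prev) < 0.07

    def test_confounding_acts_through_population(self, geno):
        g, anc = geno
        phen = plant_phenotypes(g, anc, [], 0.0, 1.0, seed=5, prevalence=0.4)
        y = (phen["label"] == "case").to_numpy()
        prev_by_pop = [y[anc == k].mean() for k in (0, 1)]
        assert abs(prev_by_pop[0] - prev_by_pop[1]) > 0.3

    def test_causal_snvs_show_dosage_shift(self, geno):
        g, anc = geno
        causal = g.snv_ids[:20]
        phen = plant_phenotypes(g, anc, causal, 0.8, 0.0, seed=5, prevalence=0.4)
        y = (phen["label"] == "case").to_numpy()
        diffs = g.values[:, y].mean(axis=1) - g.values[:, ~y].mean(axis=1)
        assert diffs[:20].mean() > diffs[20:].mean() + 0.02


class TestAnnotationsAndPpi:
    def test_same_gene_mode_concentrates_causal(self):
        cfg = SimConfig(n_snvs=200, n_genes=10, n_causal=8, causal_clustering="same_gene",
                        seed=2)
        rng = np.random.default_rng(0)
        ann, _, causal = simulate_annotations_and_ppi(cfg, [f"rs{i}" for i in range(200)], rng)
        genes = ann.set_index("snv_id").loc[causal, "gene"]
        assert genes.nunique() == 1

    def test_gene_blocks_partition_snvs(self):
        cfg = SimConfig(n_snvs=137, n_genes=9, n_causal=5, seed=2)
        rng = np.random.default_rng(0)
        ann, _, _ = simulate_annotations_and_ppi(cfg, [f"rs{i}" for i in range(137)], rng)
        assert len(ann) == 137
        assert ann["gene"].value_counts().sum() == 137
        assert (ann.groupby("gene")["position"].apply(lambda p: p.is_monotonic_increasing)).all()

    def test_network_neighbours_mode_connected_causal_subgraph(self):
        cfg = SimConfig(n_snvs=400, n_genes=20, n_causal=12,
                        causal_clustering="network_neighbours", seed=7)
        rng = np.random.default_rng(1)
        ann, ppi, causal = simulate_annotations_and_ppi(cfg, [f"rs{i}" for i in range(400)], rng)
        genes = set(ann.set_index("snv_id").loc[causal, "gene"])
        G = nx.Graph(ppi)
        assert nx.is_connected(G.subgraph(genes))

    def test_seed_genes_cover_causal_neighbourhood(self):
        bundle = simulate_bundle(SimConfig(seed=13))
        G = nx.Graph(bundle.ppi_edges)
        seeds = set(bundle.known_genes)
        reach = set(seeds)
        for s in seeds & set(G.nodes):
            reach |= set(G.neighbors(s))
        assert set(bundle.causal_genes) <= reach


class TestBundle:
    def test_bit_reproducible(self):
        a = simulate_bundle(SimConfig(m_subjects=60, n_snvs=40, n_genes=5, n_causal=4, seed=5))
        b = simulate_bundle(SimConfig(m_subjects=60, n_snvs=40, n_genes=5, n_causal=4, seed=5))
        assert np.array_equal(a.genotypes.values, b.genotypes.values)
        assert a.phenotypes.equals(b.phenotypes)
        assert a.causal_snvs == b.causal_snvs

    def test_ld_duplicates_are_perfect_copies(self):
        b = simulate_bundle(
            SimConfig(m_subjects=60, n_snvs=40, n_genes=5, n_causal=4,
                      n_ld_duplicates=6, seed=5)
        )
        dups = [s for s in b.genotypes.snv_ids if s.endswith("_dup")]
        assert len(dups) == 6
        idx = {s: i for i, s in enumerate(b.genotypes.snv_ids)}
        for d in dups:
            orig = d[:-4]
            assert np.array_equal(b.genotypes.values[idx[d]], b.genotypes.values[idx[orig]])
            # twin resides in the same gene, right after the original
            ann = b.annotations.set_index("snv_id")
            assert ann.loc[d, "gene"] == ann.loc[orig, "gene"]

    def test_invariants(self):
        b = simulate_bundle(SimConfig(m_subjects=80, n_snvs=60, n_genes=6, n_causal=6, seed=8))
        assert len(b.causal_snvs) == 6
        assert set(np.unique(b.genotypes.values)) <= {0, 1, 2}
        prev = (b.labels == "case").mean()
        assert 0 < prev < 1


class TestBlockGenotypes:
    def test_blocks_have_distinct_profiles(self):
        R, blocks, groups = simulate_block_genotypes(n_snvs=90, m_subjects=120, seed=3)
        means = np.zeros((3, 2))
        for b in range(3):
            for g in range(2):
                means[b, g] = R[np.ix_(blocks == b, groups == g)].mean()
        # three distinct (freq_A, freq_B) profiles
        assert len({tuple(np.round(row, 1)) for row in means}) == 3
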