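"""Tests for the synthetic-data engine."""

import numpy as np
import pytest

from pathlancaster import (
    SimScenario,
    assign_effects,
    build_pathways,
    gene_weights,
    run_scenario,
    scale_noise_to_heritability,
    simulate_genotypes,
)


class TestGenotypes:
    def test_allele_frequency_matches_target(self, rng):
        n, target = 10_000, 0.25
        G = simulate_genotypes(n, 4, maf_spectrum=[target] * 4, ld_rho=0.0, seed=1)
        se = np.sqrt(target * (1 - target) / (2 * n))
        freq = G.dosages.mean(axis=0) / 2
        assert np.all(np.abs(freq - target) < 4 * se)

    def test_no_ld_means_no_dosage_correlation(self):
        n = 2000
        G = simulate_genotypes(n, 6, maf_spectrum=[0.3] * 6, ld_rho=0.0, seed=2)
        corr = np.corrcoef(G.dosages.T)
        off = corr[~np.eye(6, dtype=bool)]
        assert np.max(np.abs(off)) < 3.5 / np.sqrt(n)

    def test_strong_ld_induces_dosage_correlation(self):
        G = simulate_genotypes(
            4000, 4, maf_spectrum=[0.4] * 4, ld_block_size=4, ld_rho=0.8, seed=3
        )
        corr = np.corrcoef(G.dosages.T)
        assert np.min(corr[~np.eye(4, dtype=bool)]) > 0.5

    def test_rare_heavy_default_spectrum(self):
        G = simulate_genotypes(50, 2000, seed=4)
        assert 0.7 < np.mean(G.maf < 0.03) < 0.9

    def test_invalid_spectrum_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(10, 2, maf_spectrum=[0.0, 0.1], seed=0)


class TestPathways:
    def test_partition_mode(self):
        scn = SimScenario(n_pathways=5, n_genes=100, genes_per_pathway=(5, 15))
        st = build_pathways(scn, seed=1, overlap_fraction=0.0)
        all_genes = [g for genes in st.db.pathways.values() for g in genes]
        assert len(all_genes) == len(set(all_genes))  # disjoint
        for genes in st.db.pathways.values():
            assert 5 <= len(genes) <= 15

    def test_partition_infeasible_sizes_rejected(self):
        scn = SimScenario(n_pathways=10, n_genes=20, genes_per_pathway=(5, 15))
        with pytest.raises(ValueError, match="infeasible"):
            build_pathways(scn, seed=1, overlap_fraction=0.0)

    def test_shared_pool_mode_sizes_in_range(self):
        scn = SimScenario(n_pathways=20, n_genes=150, genes_per_pathway=(10, 100))
        st = build_pathways(scn, seed=2)
        for genes in st.db.pathways.values():
            assert 10 <= len(genes) <= 100

    def test_overlap_fraction_shares_expected_gene_count(self):
        scn = SimScenario(n_pathways=10, n_genes=500, genes_per_pathway=(20, 20))
        shared_counts = []
        for seed in range(30):
            st = build_pathways(scn, seed=seed, overlap_fraction=0.1)
            seen: dict = {}
            for genes in st.db.pathways.values():
                for g in genes:
                    seen[g] = seen.get(g, 0) + 1
            shared_counts.append(sum(1 for v in seen.values() if v > 1))
        # 9 pathways re-draw 2 genes each from the used set; some collide
        assert 10 < np.mean(shared_counts) <= 18

    def test_every_pathway_gene_has_variants(self):
        scn = SimScenario(n_pathways=4, n_genes=30, genes_per_pathway=(5, 10),
                          variants_per_gene_mean=3)
        st = build_pathways(scn, seed=5)
        assert np.all(st.snp_counts >= 1)
        assert st.n_variants == sum(
            st.gene_slices[g].stop - st.gene_slices[g].start for g in st.gene_ids
        )


class TestEffects:
    def _structure(self, seed=0):
        scn = SimScenario(
            n_pathways=6, n_genes=60, genes_per_pathway=(8, 12),
            variants_per_gene_mean=5, effect_law="log10maf",
        )
        st = build_pathways(scn, seed=seed)
        maf = np.random.default_rng(seed).uniform(0.001, 0.5, st.n_variants)
        return scn, st, maf

    def test_null_law_zeroes_everything(self):
        scn, st, maf = self._structure()
        scn_null = SimScenario(**{**scn.__dict__, "effect_law": "null"})
        eff = assign_effects(scn_null, maf, st, seed=1)
        assert not np.any(eff.beta)
        assert eff.central_pathway is None

    def test_log10_law_upweights_rare_variants(self):
        scn, st, _ = self._structure()
        maf = np.full(st.n_variants, 0.1)
        maf[0] = 0.001
        # force variant 0 causal by retrying seeds until its gene is picked
        for seed in range(100):
            eff = assign_effects(scn, maf, st, seed=seed)
            if eff.causal_variants[0]:
                break
        else:
            pytest.fail("variant 0 never causal")
        rare_beta = abs(eff.beta[0])
        common = np.abs(eff.beta[(maf == 0.1) & eff.causal_variants])
        assert rare_beta == pytest.approx(3.0)
        assert np.all(common == pytest.approx(1.0))
        assert rare_beta > common.max()

    def test_causal_gene_fraction_recovered(self):
        scn, st, maf = self._structure()
        fracs = []
        for seed in range(200):
            eff = assign_effects(scn, maf, st, seed=seed)
            members = st.db.pathways[eff.central_pathway]
            fracs.append(len(eff.causal_genes) / len(members))
        se = np.sqrt(0.25 / (200 * 10))
        assert np.mean(fracs) == pytest.approx(0.5, abs=4 * se + 0.02)

    def test_sign_fractions_follow_configuration(self):
        scn, st, maf = self._structure()
        signs = []
        for seed in range(100):
            eff = assign_effects(scn, maf, st, seed=seed)
            signs.extend(np.sign(eff.beta[eff.causal_variants]))
        # P(+) = 0.8*0.8 + 0.2*0.2 = 0.68 under the two-level sign model
        assert np.mean(np.array(signs) > 0) == pytest.approx(0.68, abs=0.05)


class TestHeritability:
    def test_algebraic_identities(self):
        x = np.array([0.0, 2.0])  # Var = 1
        assert scale_noise_to_heritability(x, 0.2) == pytest.approx(4.0)
        assert scale_noise_to_heritability(x, 0.5) == pytest.approx(1.0)

    def test_zero_genetic_variance_rejected(self):
        with pytest.raises(ValueError):
            scale_noise_to_heritability(np.zeros(10), 0.2)

    def test_realized_heritability_on_simulated_traits(self, rng):
        n, h2 = 1000, 0.2
        realized = []
        for _ in range(50):
            gval = rng.standard_normal(n) * rng.uniform(0.5, 2.0)
            s2 = scale_noise_to_heritability(gval, h2)
            noise = rng.standard_normal(n) * np.sqrt(s2)
            realized.append(np.var(gval) / (np.var(gval) + np.var(noise)))
        assert np.mean(realized) == pytest.approx(h2, abs=0.01)


class TestGeneWeights:
    def test_uniform_and_equal_sizes(self):
        assert np.all(gene_weights("uniform", snp_counts=np.array([3, 5])) == 2.0)
        w = gene_weights("gene_size", snp_counts=np.array([4, 4, 4]))
        assert np.all(w == 2.0)

    def test_gene_size_downweights_large_genes(self):
        w = gene_weights("gene_size", snp_counts=np.array([2, 4, 8]))
        assert w == pytest.approx([4.0, 2.0, 1.0])

    def test_maf_based_case_study_weights(self):
        assert gene_weights("maf_common", mean_maf=np.array([0.5]))[0] == pytest.approx(1.0)
        assert gene_weights("maf_rare", mean_maf=np.array([0.5]))[0] == pytest.approx(4.0)

    def test_criterion_weights_floored_positive(self):
        delta = np.array([-6.0, -4.0, 0.5, -5.0])
        w = gene_weights("aic", criterion_delta=delta)
        assert np.all(w >= 0.1)
        assert w[1] == pytest.approx(2.0 * -4.0 / -4.5)


class TestRunScenario:
    SCN = dict(
        n_subjects=150, n_pathways=8, n_genes=50, genes_per_pathway=(5, 15),
        variants_per_gene_mean=4,
    )

    def test_null_scenario_reports_type1_and_lambda(self):
        scn = SimScenario(**self.SCN, effect_law="null")
        rep = run_scenario(scn, 24, seed=5, batches=2, B_perm=150)
        for res in rep.scheme_results.values():
            assert res.stringent_power is None
            assert 0.0 <= res.type1_error <= 0.05
            assert res.inflation_lambda > 0
        assert rep.alpha_per_pathway == pytest.approx(0.05 / 8)

    def test_power_increases_with_heritability(self):
        lo = SimScenario(**self.SCN, effect_law="log10maf", h2=0.02)
        hi = SimScenario(**self.SCN, effect_law="log10maf", h2=0.4)
        rep_lo = run_scenario(lo, 30, weight_schemes=("uniform",), seed=9,
                              batches=3, B_perm=150)
        rep_hi = run_scenario(hi, 30, weight_schemes=("uniform",), seed=9,
                              batches=3, B_perm=150)
        assert (
            rep_hi.scheme_results["uniform"].stringent_power
            >= rep_lo.scheme_results["uniform"].stringent_power
        )
        assert rep_hi.scheme_results["uniform"].lenient_power >= (
            rep_hi.scheme_results["uniform"].stringent_power
        )

    def test_seed_determinism(self):
        scn = SimScenario(**self.SCN, effect_law="null")
        r1 = run_scenario(scn, 20, weight_schemes=("uniform",), seed=3,
                          batches=1, B_perm=120)
        r2 = run_scenario(scn, 20, weight_schemes=("uniform",), seed=3,
                          batches=1, B_perm=120)
        assert np.array_equal(
            r1.pathway_pvalues["uniform"], r2.pathway_pvalues["uniform"]
        )

    def test_too_few_replicates_rejected(self):
        scn = SimScenario(**self.SCN)
        with pytest.raises(ValueError):
            run_scenario(scn, 5, seed=1)
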