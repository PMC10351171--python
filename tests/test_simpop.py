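import math

import numpy as np
import pandas as pd
import pytest

from conftest import desk_config, toy_population
from genodim import SimConfig, simulate
from genodim.simpop import (
    ConfigError,
    GenomeMap,
    SimulationError,
    assign_phenotypes,
    filter_segregating_maf,
    random_genome_map,
    recombine_gamete,
    sample_qtn_effects,
    select_founders,
    simulate_historical,
    simulate_recent,
)
from genodim.simpop import _gamete_batch


def two_locus_map(d):
    return GenomeMap(
        pd.DataFrame(
            {"chrom": [1, 1], "pos": [0.0, d], "locus_id": [0, 1], "cls": "SNP"}
        )
    )


class TestConfig:
    def test_maf_bounds(self):
        with pytest.raises(ConfigError):
            desk_config(maf_min=0.5)
        with pytest.raises(ConfigError):
            desk_config(maf_min=0.0)

    def test_schedule_must_increase(self):
        with pytest.raises(ConfigError):
            desk_config(hist_schedule=((0, 100), (0, 50)))

    def test_schedule_min_size(self):
        with pytest.raises(ConfigError):
            desk_config(hist_schedule=((-5, 1), (0, 100)))

    def test_full_scale_genome_length(self):
        cfg = SimConfig()
        assert cfg.lengths.sum() == pytest.approx(23.19)
        assert len(cfg.lengths) == 29

    def test_scale_factor_shrinks(self):
        cfg = SimConfig(scale_factor=0.01).scaled()
        assert cfg.n_snp_target == 5000
        assert cfg.n_qtn_target == 2
        assert cfg.total_length == pytest.approx(0.2319)
        assert cfg.hist_schedule[0][0] == -20
        # breeding design untouched
        assert cfg.n_sires == 50 and cfg.n_dams == 15_000


class TestRecombination:
    def test_zero_length_chromosome_returns_one_parental_haplotype(self):
        gmap = two_locus_map(0.0)
        parents = np.array([[0, 0], [1, 1]], dtype=np.int8)
        seen = set()
        for seed in range(20):
            g = recombine_gamete(parents, gmap, rng=seed)
            assert tuple(g) in {(0, 0), (1, 1)}
            seen.add(tuple(g))
        assert len(seen) == 2  # both haplotypes occur with prob 1/2

    def test_identical_parental_haplotypes(self):
        gmap = two_locus_map(0.3)
        parents = np.array([[1, 0], [1, 0]], dtype=np.int8)
        for seed in range(5):
            assert np.array_equal(recombine_gamete(parents, gmap, rng=seed), [1, 0])

    @pytest.mark.parametrize("d", [0.05, 0.2, 1.0])
    def test_recombinant_fraction_matches_haldane(self, d):
        # c = (1 - exp(-2d)) / 2, Monte Carlo over 1e5 gametes
        gmap = two_locus_map(d)
        n = 100_000
        parents = np.tile(np.array([[0, 0], [1, 1]], dtype=np.int8), (n, 1, 1))
        rng = np.random.default_rng(42)
        gametes = _gamete_batch(parents, gmap, rng)
        rec = np.mean(gametes[:, 0] != gametes[:, 1])
        c = 0.5 * (1.0 - math.exp(-2.0 * d))
        se = math.sqrt(c * (1.0 - c) / n)
        assert abs(rec - c) < 3.0 * se

    def test_independent_assortment_across_chromosomes(self):
        gmap = GenomeMap(
            pd.DataFrame(
                {"chrom": [1, 2], "pos": [0.0, 0.0], "locus_id": [0, 1], "cls": "SNP"}
            )
        )
        n = 50_000
        parents = np.tile(np.array([[0, 0], [1, 1]], dtype=np.int8), (n, 1, 1))
        gametes = _gamete_batch(parents, gmap, np.random.default_rng(0))
        rec = np.mean(gametes[:, 0] != gametes[:, 1])
        assert abs(rec - 0.5) < 3.0 * math.sqrt(0.25 / n)

    def test_mutation_flips_alleles(self):
        gmap = two_locus_map(0.0)
        parents = np.zeros((2, 2), dtype=np.int8)
        rng = np.random.default_rng(1)
        flips = sum(
            recombine_gamete(parents, gmap, rng=rng, mutation_rate=0.5).sum()
            for _ in range(200)
        )
        assert 100 < flips < 300  # ~200 expected


class TestHistorical:
    def test_single_generation_schedule_is_founder_draw(self):
        cfg = desk_config(hist_schedule=((0, 50),), mutation_rate=0.0)
        gmap = random_genome_map(cfg, np.random.default_rng(0), n_loci=100)
        rng = np.random.default_rng(123)
        pop = simulate_historical(cfg, rng, genome_map=gmap)
        expected = np.random.default_rng(123).integers(
            0, 2, size=(50, 2, 100), dtype=np.int8
        )
        assert np.array_equal(pop.haplotypes, expected)

    def test_schedule_endpoints_determine_size(self):
        cfg = desk_config(hist_schedule=((-10, 30), (-5, 80), (0, 40)))
        gmap = random_genome_map(cfg, np.random.default_rng(0), n_loci=20)
        pop = simulate_historical(cfg, 7, genome_map=gmap)
        assert len(pop) == 40

    def test_allele_frequency_preserved_in_expectation(self):
        # one drift step, mean change over 50 reps within 3 Monte-Carlo SE
        cfg = desk_config(hist_schedule=((-1, 400), (0, 400)), mutation_rate=0.0)
        gmap = random_genome_map(cfg, np.random.default_rng(5), n_loci=50)
        n_reps = 50
        deltas = []
        for seed in range(n_reps):
            rng = np.random.default_rng(seed)
            founders = np.random.default_rng(seed).integers(0, 2, size=(400, 2, 50))
            pop = simulate_historical(cfg, rng, genome_map=gmap)
            deltas.append(pop.allele_freqs().mean() - founders.mean())
        # per-rep SE of the locus-averaged frequency ~ sqrt(p q / (2N L))
        se = math.sqrt(0.25 / (2 * 400 * 50) / n_reps)
        assert abs(np.mean(deltas)) < 3.0 * se

    def test_heterozygosity_decay_wright_fisher(self):
        # constant N, no mutation: E[2pq] after t generations is
        # 0.5 * (1 - 1/(2N))^(t+1)  (the +1 is the founder sampling step)
        N, t = 60, 30
        cfg = desk_config(
            hist_schedule=((-t, N), (0, N)),
            mutation_rate=0.0,
            n_chromosomes=1,
            total_length=1.0,
        )
        gmap = random_genome_map(cfg, np.random.default_rng(9), n_loci=300)
        ratios = []
        for seed in range(20):
            pop = simulate_historical(cfg, seed, genome_map=gmap)
            p = pop.allele_freqs()
            ratios.append(np.mean(2.0 * p * (1.0 - p)))
        expected = 0.5 * (1.0 - 1.0 / (2 * N)) ** (t + 1)
        mean = np.mean(ratios)
        se = np.std(ratios, ddof=1) / math.sqrt(len(ratios))
        assert abs(mean - expected) < 3.0 * se


class TestRecent:
    def test_total_animal_count_formula(self):
        cfg = desk_config(n_sires=5, n_dams=40, n_generations_recent=12)
        gmap = random_genome_map(cfg, np.random.default_rng(0), n_loci=30)
        hist = simulate_historical(
            desk_config(hist_schedule=((0, 60),)), 3, genome_map=gmap
        )
        pop = simulate_recent(hist, cfg, 4)
        assert len(pop) == 5 + 40 + 12 * 40

    def test_genotyped_flags(self):
        cfg = desk_config(n_sires=4, n_dams=30, genotyped_generations=(16, 17, 18, 19, 20))
        gmap = random_genome_map(cfg, np.random.default_rng(0), n_loci=10)
        hist = simulate_historical(desk_config(hist_schedule=((0, 40),)), 1, genome_map=gmap)
        pop = simulate_recent(hist, cfg, 2)
        counts = pop.pedigree.groupby("generation")["genotyped"].sum()
        for g in range(16, 21):
            assert counts.loc[g] == 30
        assert pop.pedigree["genotyped"].sum() == 150

    def test_pedigree_topological_order(self):
        cfg = desk_config(n_sires=4, n_dams=30)
        gmap = random_genome_map(cfg, np.random.default_rng(0), n_loci=10)
        hist = simulate_historical(desk_config(hist_schedule=((0, 40),)), 1, genome_map=gmap)
        ped = simulate_recent(hist, cfg, 2).pedigree
        pos = pd.Series(np.arange(len(ped)), index=ped["id"])
        for col in ("sire", "dam"):
            parents = ped.loc[ped[col] != 0]
            assert (pos.loc[parents[col]].to_numpy() < pos.loc[parents["id"]].to_numpy()).all()
        gen = ped.set_index("id")["generation"]
        nonf = ped[ped["generation"] > 0]
        assert (gen.loc[nonf["sire"]].to_numpy() < nonf["generation"].to_numpy()).all()
        assert (gen.loc[nonf["dam"]].to_numpy() < nonf["generation"].to_numpy()).all()

    def test_insufficient_replacements_raise(self):
        # 3 sires at 100% replacement but only 2 offspring per generation
        cfg = desk_config(
            n_sires=3, n_dams=2, replacement_sire=1.0, replacement_dam=0.0,
            n_generations_recent=5,
        )
        gmap = random_genome_map(cfg, np.random.default_rng(0), n_loci=10)
        hist = simulate_historical(desk_config(hist_schedule=((0, 10),)), 1, genome_map=gmap)
        with pytest.raises(SimulationError):
            simulate_recent(hist, cfg, 0)

    def test_founder_pool_too_small(self):
        cfg = desk_config(n_sires=10, n_dams=100)
        gmap = random_genome_map(cfg, np.random.default_rng(0), n_loci=5)
        hist = simulate_historical(desk_config(hist_schedule=((0, 20),)), 1, genome_map=gmap)
        with pytest.raises(SimulationError):
            select_founders(hist, cfg, 0)


class TestMafFilter:
    def _pop_with_freqs(self, counts, n=50):
        # counts = number of alt alleles among 2n
        haps = np.zeros((n, 2, len(counts)), dtype=np.int8)
        for j, c in enumerate(counts):
            flat = np.zeros(2 * n, dtype=np.int8)
            flat[:c] = 1
            haps[:, :, j] = flat.reshape(n, 2)
        return toy_population(haps)

    def test_strict_inequality_at_threshold(self):
        pop = self._pop_with_freqs([4, 5, 6])  # freqs 0.04, 0.05, 0.06
        kept = filter_segregating_maf(pop, 0.05)
        assert list(kept.locus_ids) == [2]

    def test_zero_threshold_keeps_segregating(self):
        pop = self._pop_with_freqs([0, 1, 50, 100])
        kept = filter_segregating_maf(pop, 1e-9)
        assert list(kept.locus_ids) == [1, 2]

    def test_all_fixed_raises_with_targets(self):
        pop = self._pop_with_freqs([0, 100])
        assert len(filter_segregating_maf(pop, 0.05)) == 0
        with pytest.raises(ConfigError):
            filter_segregating_maf(pop, 0.05, n_snp=1, n_qtn=1, rng=0)

    def test_target_sampling_classes(self):
        pop = self._pop_with_freqs([40, 50, 60, 30, 70, 45])
        gmap = filter_segregating_maf(pop, 0.05, n_snp=3, n_qtn=2, rng=1)
        assert (gmap.cls == "SNP").sum() == 3
        assert (gmap.cls == "QTN").sum() == 2
        assert np.all(np.diff(gmap.pos) >= 0)


class TestTraitArchitecture:
    def test_variance_rescaled_exactly(self):
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, size=(200, 30)).astype(float)
        for target in (0.3, 0.9, 0.99):
            arch = sample_qtn_effects(geno, sigma_u2=target, rng=1)
            assert arch.tbv(geno).var() == pytest.approx(target, abs=1e-12)

    def test_single_qtn_balanced_genotypes(self):
        # genotypes {0,1,2} equally frequent: var = (2/3) beta^2, so the
        # rescaled |beta| must be sqrt(3 sigma_u2 / 2)
        geno = np.array([[0.0], [1.0], [2.0]] * 20)
        arch = sample_qtn_effects(geno, sigma_u2=0.3, rng=5)
        assert abs(arch.beta[0]) == pytest.approx(math.sqrt(3 * 0.3 / 2))

    def test_scale_invariance_of_raw_effects(self):
        rng = np.random.default_rng(3)
        geno = rng.integers(0, 3, size=(100, 10)).astype(float)
        arch = sample_qtn_effects(geno, sigma_u2=0.5, rng=7)
        doubled = 2.0 * arch.beta
        rescaled = doubled * math.sqrt(0.5 / (geno @ doubled).var())
        np.testing.assert_allclose(rescaled, arch.beta, rtol=1e-12)

    def test_monomorphic_qtn_raise(self):
        geno = np.ones((50, 3))
        with pytest.raises(SimulationError):
            sample_qtn_effects(geno, sigma_u2=0.3, rng=0)

    def test_gamma_magnitudes_with_random_signs(self):
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, size=(500, 400)).astype(float)
        arch = sample_qtn_effects(geno, sigma_u2=0.9, rng=2)
        signs = np.sign(arch.beta)
        assert 0.35 < (signs > 0).mean() < 0.65


class TestPhenotypes:
    def _sim_pop(self, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        haps = rng.integers(0, 2, size=(n, 2, 5)).astype(np.int8)
        return toy_population(haps, cls=["QTN"] * 5)

    def test_high_heritability_residual_variance(self):
        pop = self._sim_pop(20_000)
        geno = pop.genotypes()
        arch = sample_qtn_effects(geno.astype(float), sigma_u2=0.99, rng=1)
        phen = assign_phenotypes(arch, pop, rng=2)
        assert phen.table["residual"].var() == pytest.approx(0.01, rel=0.1)

    def test_h2_one_limit(self):
        pop = self._sim_pop(100)
        geno = pop.genotypes().astype(float)
        arch = sample_qtn_effects(geno, sigma_u2=1.0, rng=1)
        phen = assign_phenotypes(arch, pop, rng=2)
        np.testing.assert_allclose(
            phen.table["phenotype"] - arch.mu, phen.table["tbv"], atol=1e-12
        )

    def test_excess_additive_variance_raises(self):
        pop = self._sim_pop(50)
        arch = sample_qtn_effects(pop.genotypes().astype(float), sigma_u2=1.0, rng=1)
        arch.sigma_u2 = 1.5
        with pytest.raises(ConfigError):
            assign_phenotypes(arch, pop, rng=0)

    def test_phenotypic_variance_near_one(self):
        pop = self._sim_pop(100_000, seed=3)
        geno = pop.genotypes().astype(float)
        arch = sample_qtn_effects(geno, sigma_u2=0.3, rng=4)
        phen = assign_phenotypes(arch, pop, rng=5)
        # var(P) = var(TBV) + var(E); SE of a sample variance ~ sqrt(2/(n-1))
        se = math.sqrt(2.0 / (len(phen.table) - 1))
        assert abs(phen.table["phenotype"].var() - 1.0) < 3.0 * se

    def test_only_requested_generations_phenotyped(self, desk_sim):
        gens = np.unique(desk_sim.phenotypes.table["generation"])
        assert gens.min() == 11 and gens.max() == 20


class TestEndToEnd:
    def test_counts_and_classes(self, desk_sim):
        cfg = desk_sim.config
        gmap = desk_sim.genome_map
        assert gmap.snp_mask.sum() == cfg.n_snp_target
        assert gmap.qtn_mask.sum() == cfg.n_qtn_target
        assert len(desk_sim.population) == cfg.n_sires + cfg.n_dams * (
            1 + cfg.n_generations_recent
        )

    def test_founder_tbv_variance_exact(self, desk_sim):
        pop = desk_sim.population
        qtn = np.flatnonzero(desk_sim.genome_map.qtn_mask)
        tbv = desk_sim.architecture.tbv(pop.genotypes(ids=pop.founder_ids(), loci=qtn))
        assert tbv.var() == pytest.approx(desk_sim.config.sigma_u2, abs=1e-10)

    def test_maf_filter_holds_in_founders(self, desk_sim):
        pop = desk_sim.population
        p = pop.allele_freqs(ids=pop.founder_ids())
        assert np.minimum(p, 1 - p).min() > desk_sim.config.maf_min

    def test_determinism(self):
        cfg = desk_config(n_snp_target=100, n_qtn_target=5, n_dams=40,
                          hist_schedule=((-20, 40), (0, 60)))
        a = simulate(cfg)
        b = simulate(cfg)
        assert np.array_equal(a.population.haplotypes, b.population.haplotypes)
        pd.testing.assert_frame_equal(a.phenotypes.table, b.phenotypes.table)
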