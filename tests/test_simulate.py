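"""Forward simulator: drift, autozygosity, crosses, determinism, truth."""

from __future__ import annotations

import numpy as np
import pytest

import rohscan as rs

SMALL_GENOME = dict(n_chrom=2, chrom_length_bp=10_000_000, snp_spacing_bp=25_000)


def small_genome():
    return rs.Genome(2, 10_000_000, 25_000, 1.0)


def base_freqs(genome, seed=99):
    return np.random.default_rng(seed).uniform(0.05, 0.95, genome.n_snps)


class TestSimulateBreed:
    def test_founder_generation_heterozygosity_matches_expectation(self):
        genome = small_genome()
        freqs = base_freqs(genome)
        pool = rs.simulate_breed(
            genome, freqs, rs.BreedSpec("B", n_founders=50, n_generations=0),
            np.random.default_rng(0),
        )
        expected = float(np.mean(2 * freqs * (1 - freqs)))
        obs = pool.heterozygosity()
        se = obs.std(ddof=1) / np.sqrt(obs.size)
        assert abs(obs.mean() - expected) < 3 * max(se, 1e-3)

    def test_single_founder_is_fully_autozygous(self):
        genome = small_genome()
        pool = rs.simulate_breed(
            genome, base_freqs(genome),
            rs.BreedSpec("B", n_founders=1, n_generations=5, census_size=10),
            np.random.default_rng(1),
        )
        assert np.all(pool.f_realized() == 1.0)
        # every genotype homozygous -> F_ROH covers the whole map
        g = _pool_to_matrix(genome, pool, "B")
        froh = rs.froh_all_samples(rs.call_roh(g), g)
        assert all(r.froh == pytest.approx(1.0, abs=1e-6) for r in froh)

    def test_inbreeding_grows_with_generations(self):
        genome = small_genome()
        freqs = base_freqs(genome)
        means = []
        for gens in (2, 10, 25):
            pool = rs.simulate_breed(
                genome, freqs,
                rs.BreedSpec("B", n_founders=2, n_generations=gens, census_size=20),
                np.random.default_rng(7),
            )
            f = pool.f_pedigree.mean()
            assert 0.0 < f < 1.0
            means.append(f)
        assert means[0] < means[1] < means[2]

    def test_drift_preserves_expected_allele_frequency(self):
        genome = small_genome()
        freqs = base_freqs(genome)
        reps = [
            rs.simulate_breed(
                genome, freqs,
                rs.BreedSpec("B", n_founders=10, n_generations=10, census_size=20),
                np.random.default_rng(100 + k),
            ).alleles.mean()
            for k in range(8)
        ]
        grand = float(np.mean(reps))
        se = float(np.std(reps, ddof=1) / np.sqrt(len(reps)))
        assert abs(grand - freqs.mean()) < 3 * se


class TestMakeCross:
    def test_fully_diverged_fixed_lines_give_all_het_offspring(self):
        genome = small_genome()
        rng = np.random.default_rng(3)
        a = rs.simulate_breed(genome, np.zeros(genome.n_snps),
                              rs.BreedSpec("A", 2, 0), rng)
        b = rs.simulate_breed(genome, np.ones(genome.n_snps),
                              rs.BreedSpec("B", 2, 0), rng)
        f1 = rs.make_cross(a, b, 10, rng)
        assert np.all(f1.dosages() == 1)
        g = _pool_to_matrix(genome, f1, "F1")
        assert rs.call_roh(g) == []

    def test_f1_heterozygosity_exceeds_parental(self):
        genome = small_genome()
        freqs = base_freqs(genome)
        rng = np.random.default_rng(5)
        spec = dict(n_founders=4, n_generations=15, census_size=20)
        a = rs.simulate_breed(genome, freqs, rs.BreedSpec("A", **spec), rng)
        b = rs.simulate_breed(genome, freqs, rs.BreedSpec("B", **spec), rng)
        f1 = rs.make_cross(a, b, 20, rng)
        assert f1.heterozygosity().mean() >= a.heterozygosity().mean()
        assert f1.heterozygosity().mean() >= b.heterozygosity().mean()

    def test_self_cross_resembles_next_generation(self):
        genome = small_genome()
        freqs = base_freqs(genome)
        spec = rs.BreedSpec("A", n_founders=6, n_generations=8, census_size=30)
        pool = rs.simulate_breed(genome, freqs, spec, np.random.default_rng(8))
        selfed = rs.make_cross(pool, pool, 30, np.random.default_rng(9))
        nextgen = rs.simulate_breed(
            genome, freqs,
            rs.BreedSpec("A", n_founders=6, n_generations=9, census_size=30),
            np.random.default_rng(8),
        )
        h1, h2 = selfed.heterozygosity(), nextgen.heterozygosity()
        pooled_se = np.sqrt(
            h1.var(ddof=1) / h1.size + h2.var(ddof=1) / h2.size
        )
        assert abs(h1.mean() - h2.mean()) < 3 * max(pooled_se, 1e-3)

    def test_three_way_cross_breed_fractions(self):
        genome = small_genome()
        freqs = base_freqs(genome)
        rng = np.random.default_rng(10)
        pools = {
            name: rs.simulate_breed(genome, freqs, rs.BreedSpec(name, 4, 3), rng)
            for name in ("C", "SL", "A")
        }
        f1 = rs.resolve_cross("C x (SL x A)", pools, 12, rng)
        assert np.allclose(f1.breed_fractions["C"], 0.5)
        assert np.allclose(f1.breed_fractions["SL"], 0.25)
        assert np.allclose(f1.breed_fractions["A"], 0.25)
        total = sum(f1.breed_fractions[b] for b in ("C", "SL", "A"))
        assert np.allclose(total, 1.0)

    def test_expression_parser_rejects_garbage(self):
        genome = small_genome()
        pools = {}
        with pytest.raises(ValueError):
            rs.resolve_cross("(A x B", pools, 5, np.random.default_rng(0))
        with pytest.raises(KeyError):
            rs.resolve_cross("A x B", pools, 5, np.random.default_rng(0))


class TestSimulatePanel:
    def test_round_trips_through_plink_io(self, tmp_path, default_panel):
        g, truth = default_panel
        rs.write_genotypes(g, tmp_path / "panel", format="bed")
        g2 = rs.read_genotypes(tmp_path / "panel")
        assert g2 == g

    def test_identical_seed_gives_byte_identical_files(self, tmp_path):
        scen = rs.SimScenario(
            breeds=[rs.BreedSpec("B1", 4, 5, 10), rs.BreedSpec("B2", 4, 5, 10)],
            crosses=[rs.CrossSpec("X", "B1 x B2", 6)],
            seed=42,
            **SMALL_GENOME,
        )
        rs.simulate_panel(scen, out_prefix=tmp_path / "a")
        rs.simulate_panel(scen, out_prefix=tmp_path / "b")
        for ext in (".ped", ".map", ".truth.tsv"):
            assert (tmp_path / f"a{ext}").read_bytes() == (
                tmp_path / f"b{ext}"
            ).read_bytes()

    def test_truth_fractions_sum_to_one(self, default_panel):
        g, truth = default_panel
        frac_cols = [c for c in truth.columns if c.startswith("frac_")]
        assert np.allclose(truth[frac_cols].sum(axis=1), 1.0)

    def test_mean_froh_increases_with_closed_generations(self):
        from scipy.stats import spearmanr

        depths = [3, 8, 14, 20]
        scen = rs.SimScenario(
            breeds=[
                rs.BreedSpec(f"G{d}", n_founders=10, n_generations=d,
                             census_size=20)
                for d in depths
            ],
            sample_sizes={f"G{d}": 10 for d in depths},
            seed=17,
        )
        g, truth = rs.simulate_panel(scen)
        froh = rs.froh_all_samples(rs.call_roh(g), g)
        by_pop = {}
        labels = g.population_map()
        for r in froh:
            by_pop.setdefault(labels[r.sample_id], []).append(r.froh)
        means = [np.mean(by_pop[f"G{d}"]) for d in depths]
        rho, _ = spearmanr(depths, means)
        assert rho > 0


def _pool_to_matrix(genome, pool, name):
    samples = [
        rs.Sample(sample_id=f"{name}_{i}", population=name)
        for i in range(pool.n_individuals)
    ]
    return rs.GenotypeMatrix(samples, genome.snp_records(), pool.dosages())
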