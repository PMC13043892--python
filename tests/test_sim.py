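"""Wright-Fisher engine: resampling law, selection, conditioning, demography."""

import math

import numpy as np
import pytest

from sweepdann.sim import (
    Demography,
    Epoch,
    InvalidStateError,
    SimParams,
    SweepConditioningError,
    SweepParams,
    WFPopulation,
    advance_generation,
    nucleotide_diversity,
    sample_heterozygosity,
    simulate_neutral,
    simulate_sweep,
)

from conftest import focal_population


NO_MUT = SimParams(L=1000.0, mu=0.0, r=0.0, n_sample=2)


class TestAdvanceGeneration:
    def test_neutral_offspring_frequency_is_binomial_mean(self, rng):
        """Mean offspring frequency over many single-generation steps matches
        the binomial resampling expectation p0 (allele-frequency martingale)."""
        n, p0, reps = 100, 0.3, 1000
        freqs = np.empty(reps)
        for i in range(reps):
            pop = focal_population(n, p0)
            advance_generation(pop, None, NO_MUT, rng)
            freqs[i] = pop.focal_frequency()
        se = math.sqrt(p0 * (1 - p0) / (2 * n) / reps)
        assert abs(freqs.mean() - p0) < 3 * se

    def test_infinite_selection_only_beneficial_homozygotes_reproduce(self, rng):
        # weights (0, 0, 1): only genotype-2 parents have positive fitness
        pop = focal_population(50, 0.5, rng=rng)
        advance_generation(pop, (0.0, 0.0, 1.0), NO_MUT, rng)
        assert pop.focal_frequency() == 1.0

    def test_all_zero_fitness_raises(self, rng):
        pop = focal_population(10, 0.0)  # no beneficial copies at all
        with pytest.raises(InvalidStateError):
            advance_generation(pop, (0.0, 0.0, 1.0), NO_MUT, rng)

    def test_empty_population_raises(self, rng):
        pop = WFPopulation(np.zeros((0, 0), dtype=np.uint8), np.empty(0), 100.0)
        with pytest.raises(InvalidStateError):
            advance_generation(pop, None, NO_MUT, rng)

    def test_population_size_change(self, rng):
        pop = focal_population(20, 0.5)
        advance_generation(pop, None, NO_MUT, rng, next_size=7)
        assert pop.n_diploid == 7


class TestNeutralSimulation:
    def test_no_mutation_means_no_segregating_sites(self):
        params = SimParams(L=1000.0, mu=0.0, r=1e-5, n_sample=5, seed=3)
        s = simulate_neutral(params, Demography.constant(20, duration=5))
        assert s.n_sites == 0

    def test_fixed_seed_is_bit_reproducible(self, tiny_params):
        demo = Demography.constant(50, duration=10)
        a = simulate_neutral(tiny_params, demo, rng=np.random.default_rng(5))
        b = simulate_neutral(tiny_params, demo, rng=np.random.default_rng(5))
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.alleles, b.alleles)

    def test_sample_shape_and_segregation(self, tiny_params):
        demo = Demography.constant(40, duration=8)
        s = simulate_neutral(tiny_params, demo, rng=np.random.default_rng(11))
        assert s.alleles.shape == (2 * tiny_params.n_sample, s.n_sites)
        counts = s.alleles.sum(axis=0)
        assert ((counts > 0) & (counts < 2 * tiny_params.n_sample)).all()
        assert (np.diff(s.positions) > 0).all()

    def test_heterozygosity_decay_matches_drift_formula(self, rng):
        """E[H_t] = H0 (1 - 1/2N)^t for pure drift at a single site."""
        n, t, reps, p0 = 50, 20, 600, 0.5
        h = np.empty(reps)
        params = SimParams(L=100.0, mu=0.0, r=0.0, n_sample=2)
        for i in range(reps):
            pop = focal_population(n, p0)
            for _ in range(t):
                advance_generation(pop, None, params, rng)
            p = pop.focal_frequency()
            h[i] = 2 * p * (1 - p)
        expected = 0.5 * (1 - 1 / (2 * n)) ** t
        se = h.std(ddof=1) / math.sqrt(reps)
        assert abs(h.mean() - expected) < 3 * se

    def test_bottleneck_lowers_sample_heterozygosity(self, rng):
        """Matched mu and L: the bottleneck demography loses diversity."""
        params = SimParams(L=3000.0, mu=1.25e-5, r=1.25e-5, n_sample=10)
        const = Demography.constant(100, duration=20)
        bottl = Demography.bottleneck(100)
        reps = 500
        h_const = np.empty(reps)
        h_bottl = np.empty(reps)
        for i in range(reps):
            h_const[i] = sample_heterozygosity(
                simulate_neutral(params, const, rng=np.random.default_rng(1000 + i))
            )
            h_bottl[i] = sample_heterozygosity(
                simulate_neutral(params, bottl, rng=np.random.default_rng(5000 + i))
            )
        se = math.sqrt(h_const.var(ddof=1) / reps + h_bottl.var(ddof=1) / reps)
        assert h_bottl.mean() < h_const.mean() - 3 * se


class TestSweepSimulation:
    def test_fixation_probability_matches_diffusion(self, rng):
        """Single-copy fixation frequency vs the diffusion approximation.

        With genotype fitnesses (1, 1+hs, 1+s) and h=1/2 the diffusion gives
        u = (1 - e^{-s}) / (1 - e^{-2Ns}) from one initial copy.
        """
        n, s = 500, 0.05
        params = SimParams(L=100.0, mu=0.0, r=0.0, n_sample=2)
        weights = SweepParams(s=s, h=0.5).fitness_weights()
        attempts, fixed = 5000, 0
        for i in range(attempts):
            pop = focal_population(n, 0.0)
            pop.focal[0] = 1
            while True:
                advance_generation(pop, weights, params, rng)
                f = pop.focal_frequency()
                if f == 0.0 or f == 1.0:
                    fixed += f == 1.0
                    break
        u = (1 - math.exp(-s)) / (1 - math.exp(-2 * n * s))
        se = math.sqrt(u * (1 - u) / attempts)
        assert abs(fixed / attempts - u) < 3 * se

    def test_accepted_sweeps_satisfy_conditioning(self, tiny_params):
        demo = Demography.constant(50, duration=10)
        sweep = SweepParams(s=0.5, min_final_freq=0.8)
        for i in range(10):
            s = simulate_sweep(tiny_params, demo, sweep, rng=np.random.default_rng(i))
            assert s.final_freq is not None and s.final_freq >= 0.8
            assert s.label == "sweep"

    def test_conditioning_failure_raises_with_attempt_count(self, tiny_params):
        demo = Demography.constant(50, duration=10)
        # s=0: a single neutral copy essentially never fixes within the window
        sweep = SweepParams(s=0.0, min_final_freq=1.0, max_attempts=3, origin_time=5)
        with pytest.raises(SweepConditioningError) as exc:
            simulate_sweep(tiny_params, demo, sweep, rng=np.random.default_rng(0))
        assert exc.value.attempts == 3

    def test_partial_sweep_keeps_focal_site_segregating(self):
        params = SimParams(L=5000.0, mu=1.25e-5, r=1.25e-5, n_sample=10, seed=1)
        demo = Demography.constant(50, duration=10)
        sweep = SweepParams(s=0.8, min_final_freq=0.5, origin_time=15)
        found = 0
        for i in range(20):
            s = simulate_sweep(params, demo, sweep, rng=np.random.default_rng(100 + i))
            if s.final_freq < 1.0:
                # beneficial site should appear as an ordinary column when
                # still segregating in the sample
                at_focal = np.isclose(s.positions, 2500.0)
                if at_focal.any():
                    found += 1
        assert found > 0

    def test_hitchhiking_erodes_central_diversity(self):
        """Mean pairwise diversity in the central 10% of accepted sweep
        replicates is below the outer 20%, the classic hitchhiking valley."""
        params = SimParams(L=20_000.0, mu=1.25e-5, r=2.5e-5, n_sample=10)
        demo = Demography.constant(100, duration=20)
        sweep = SweepParams(s=0.6)
        reps = 200
        central = np.empty(reps)
        outer = np.empty(reps)
        for i in range(reps):
            s = simulate_sweep(params, demo, sweep, rng=np.random.default_rng(i))
            central[i] = nucleotide_diversity(s, 9_000, 11_000)
            outer[i] = 0.5 * (
                nucleotide_diversity(s, 0, 2_000)
                + nucleotide_diversity(s, 18_000, 20_000)
            )
        diff = outer - central
        se = diff.std(ddof=1) / math.sqrt(reps)
        assert diff.mean() > 3 * se


class TestTypes:
    def test_demography_validation(self):
        with pytest.raises(ValueError):
            Demography(epochs=())
        with pytest.raises(ValueError):
            Demography(epochs=((0, 100),))
        with pytest.raises(ValueError):
            Demography(epochs=((10, 1),))
        d = Demography(epochs=((5, 100), (10, 10), (5, 100)))
        assert d.min_size == 10 and d.total_generations == 20
        assert list(d.size_schedule()) == [100] * 5 + [10] * 10 + [100] * 5

    def test_sample_size_must_fit_smallest_epoch(self):
        params = SimParams(n_sample=20)
        with pytest.raises(ValueError):
            params.validate_against(Demography.bottleneck(100))  # crash size 10

    def test_sweep_params_validation(self):
        with pytest.raises(ValueError):
            SweepParams(s=-0.1)
        with pytest.raises(ValueError):
            SweepParams(position_fraction=1.0)
        with pytest.raises(ValueError):
            SweepParams(min_final_freq=0.0)
        assert SweepParams().position_fraction == 0.5
        assert SweepParams().min_final_freq == 1.0
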