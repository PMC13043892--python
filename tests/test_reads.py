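"""Read-model layer: pileups, genotype likelihoods, EM frequency, dosage."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepdann.reads import (
    DosageError,
    GLMatrix,
    GenotypeMatrix,
    ReadPileup,
    collapse_to_genotypes,
    dosage_from_reads,
    estimate_freq_em,
    estimate_frequencies,
    genotype_loglik,
    genotype_loglik_matrix,
    posterior_dosage,
    simulate_pileup,
    write_vcf,
)

from conftest import make_sample


class TestCollapse:
    def test_hand_case_and_phase_invariance(self):
        s = make_sample(
            [[1, 0, 1],
             [1, 1, 0],
             [0, 1, 0],
             [1, 0, 0]],
            positions=[1.0, 2.0, 3.0],
        )
        g = collapse_to_genotypes(s)
        assert np.array_equal(g.values, [[2, 1, 1], [1, 1, 0]])
        # swapping the two haplotypes of an individual changes nothing
        s2 = make_sample(
            [[1, 1, 0],
             [1, 0, 1],
             [1, 0, 0],
             [0, 1, 0]],
            positions=[1.0, 2.0, 3.0],
        )
        assert np.array_equal(collapse_to_genotypes(s2).values, g.values)

    def test_odd_row_count_rejected(self):
        from sweepdann.sim import HaplotypeSample

        with pytest.raises(ValueError):
            HaplotypeSample(
                positions=np.array([1.0]),
                alleles=np.array([[1], [0], [1]], dtype=np.uint8),
                label="neutral",
            )


class TestPileup:
    def test_zero_depth(self, rng):
        g = GenotypeMatrix(values=np.array([[0, 1, 2]]), positions=np.arange(3.0))
        p = simulate_pileup(g, mean_depth=0.0, error=0.01, rng=rng)
        assert (p.depth == 0).all()

    def test_error_free_homozygote_has_no_discordant_reads(self, rng):
        g = GenotypeMatrix(values=np.full((5, 20), 2), positions=np.arange(20.0))
        p = simulate_pileup(g, mean_depth=8.0, error=0.0, rng=rng)
        assert (p.a0 == 0).all()

    def test_heterozygote_read_balance(self, rng):
        g = GenotypeMatrix(values=np.full((100, 100), 1), positions=np.arange(100.0))
        p = simulate_pileup(g, mean_depth=5.0, error=0.0, rng=rng)
        total = p.depth.sum()
        frac = p.a1.sum() / total
        se = math.sqrt(0.25 / total)
        assert abs(frac - 0.5) < 4 * se

    def test_parameter_validation(self, rng):
        g = GenotypeMatrix(values=np.array([[1]]), positions=np.array([0.0]))
        with pytest.raises(ValueError):
            simulate_pileup(g, mean_depth=-1.0, error=0.0, rng=rng)
        with pytest.raises(ValueError):
            simulate_pileup(g, mean_depth=1.0, error=0.5, rng=rng)


class TestGenotypeLoglik:
    def test_no_data_is_flat(self):
        assert genotype_loglik(0, 0, 0.005) == (0.0, 0.0, 0.0)

    def test_hand_arithmetic_example(self):
        """(a0, a1) = (0, 5) at eps = 0.005: pre-normalization values are
        l2 = 5 ln 0.995, l1 = 5 ln 0.5, l0 = 5 ln 0.005."""
        raw = np.array([5 * math.log(0.005), 5 * math.log(0.5), 5 * math.log(0.995)])
        expected = tuple(raw - raw.max())
        got = genotype_loglik(0, 5, 0.005)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert got[2] == 0.0  # maximum is normalized to zero

    def test_swapping_counts_mirrors_homozygotes(self):
        a = genotype_loglik(3, 1, 0.01)
        b = genotype_loglik(1, 3, 0.01)
        assert a[0] == pytest.approx(b[2], abs=1e-12)
        assert a[2] == pytest.approx(b[0], abs=1e-12)
        assert a[1] == pytest.approx(b[1], abs=1e-12)

    def test_zero_error_discordance_gives_minus_inf(self):
        l0, l1, l2 = genotype_loglik(2, 3, 0.0)
        assert l0 == -math.inf and l2 == -math.inf and l1 == 0.0

    def test_matrix_version_matches_scalar(self, rng):
        a0 = rng.integers(0, 6, size=(4, 7))
        a1 = rng.integers(0, 6, size=(4, 7))
        pile = ReadPileup(a0=a0, a1=a1, mean_depth=5.0, error=0.01)
        gl = genotype_loglik_matrix(pile)
        for i in range(4):
            for j in range(7):
                np.testing.assert_allclose(
                    gl.loglik[i, j], genotype_loglik(a0[i, j], a1[i, j], 0.01),
                    atol=1e-12,
                )


class TestFrequencyEM:
    def test_deep_error_free_data_recovers_genotype_frequency(self, rng):
        genos = rng.choice([0, 1, 2], size=200, p=[0.64, 0.32, 0.04])
        a1 = genos * 15
        a0 = (2 - genos) * 15
        gl = genotype_loglik_matrix(
            ReadPileup(a0=a0[:, None], a1=a1[:, None], mean_depth=30, error=0.001)
        )
        q, degen = estimate_freq_em(gl.loglik[:, 0, :])
        assert not degen
        assert q == pytest.approx(genos.sum() / 400, abs=1e-6)

    def test_all_missing_returns_half_with_flag(self):
        flat = np.zeros((5, 3))
        q, degen = estimate_freq_em(flat)
        assert q == 0.5 and degen

    def test_em_loglik_is_monotone(self, rng):
        """Observed-data log-likelihood never decreases across EM iterations."""
        genos = rng.choice([0, 1, 2], size=60)
        depth = rng.poisson(3.0, size=60)
        p1 = genos / 2 * 0.99 + (1 - genos / 2) * 0.01
        a1 = rng.binomial(depth, p1)
        gl = genotype_loglik_matrix(
            ReadPileup(a0=(depth - a1)[:, None], a1=a1[:, None], mean_depth=3, error=0.01)
        )
        lik = np.exp(gl.loglik[:, 0, :])

        def obs_loglik(q):
            hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
            return np.log((lik * hwe).sum(axis=1)).sum()

        lls = []
        for k in range(1, 12):
            q, _ = estimate_freq_em(gl.loglik[:, 0, :], tol=0.0, max_iter=k)
            lls.append(obs_loglik(q))
        assert all(b >= a - 1e-10 for a, b in zip(lls, lls[1:]))

    def test_batched_frequencies_match_per_site_em(self, rng):
        genos = rng.choice([0, 1, 2], size=(30, 8))
        depth = rng.poisson(5.0, size=(30, 8))
        p1 = genos / 2 * 0.995 + (1 - genos / 2) * 0.005
        a1 = rng.binomial(depth, p1)
        gl = genotype_loglik_matrix(
            ReadPileup(a0=depth - a1, a1=a1, mean_depth=5, error=0.005)
        )
        freq, degen = estimate_frequencies(gl)
        for j in range(8):
            qj, dj = estimate_freq_em(gl.loglik[:, j, :])
            assert freq[j] == pytest.approx(qj, abs=1e-6)
            assert degen[j] == dj


class TestPosteriorDosage:
    def test_depth_zero_equals_prior_mean(self):
        gl = GLMatrix(loglik=np.zeros((3, 2, 3)), error=0.005)
        d = posterior_dosage(gl, np.array([0.3, 0.9]))
        np.testing.assert_array_equal(d.dosage[:, 0], 0.6)
        np.testing.assert_array_equal(d.dosage[:, 1], 1.8)

    def test_hand_case_three_concordant_reads(self):
        """eps=0, reads (0,3), q=0.5: E[g] = (2*.25 + 1*.5*.125)/(.25 + .5*.125) = 1.8."""
        ll = np.array([[[genotype_loglik(0, 3, 0.0)]]], dtype=float).reshape(1, 1, 3)
        gl = GLMatrix(loglik=ll, error=0.0)
        d = posterior_dosage(gl, np.array([0.5]))
        assert d.dosage[0, 0] == pytest.approx(1.8, abs=1e-12)

    def test_impossible_data_raises(self):
        ll = np.array([genotype_loglik(0, 3, 0.0)]).reshape(1, 1, 3)
        gl = GLMatrix(loglik=ll, error=0.0)
        with pytest.raises(DosageError):
            posterior_dosage(gl, np.array([0.0]))  # prior forbids carrying allele 1

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        a0=st.integers(0, 30),
        a1=st.integers(0, 30),
        err=st.floats(1e-4, 0.4),
        q=st.floats(0.001, 0.999),
    )
    def test_dosage_always_in_range(self, a0, a1, err, q):
        gl = GLMatrix(
            loglik=np.array(genotype_loglik(a0, a1, err)).reshape(1, 1, 3), error=err
        )
        d = posterior_dosage(gl, np.array([q]))
        assert 0.0 <= d.dosage[0, 0] <= 2.0

    def test_pipeline_from_reads(self, rng):
        s = make_sample(rng.integers(0, 2, size=(20, 15)), L=1000.0,
                        positions=np.sort(rng.uniform(0, 1000, 15)))
        pile = simulate_pileup(collapse_to_genotypes(s), 5.0, 0.005, rng)
        d = dosage_from_reads(pile)
        assert d.dosage.shape == (10, 15)
        assert (d.dosage >= 0).all() and (d.dosage <= 2).all()
        assert (d.freq >= 0).all() and (d.freq <= 1).all()


def test_vcf_export(tmp_path, rng):
    s = make_sample(rng.integers(0, 2, size=(6, 4)), L=500.0,
                    positions=[10.0, 20.0, 30.0, 400.0])
    geno = collapse_to_genotypes(s)
    dos = dosage_from_reads(simulate_pileup(geno, 8.0, 0.005, rng))
    path = tmp_path / "out.vcf"
    write_vcf(path, geno, dos, contig_length=500)
    text = path.read_text()
    assert text.count("\n") >= 4
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        recs = list(vcf)
        assert len(recs) == 4
        gt = recs[0].samples["ind0"]["GT"]
        assert sum(gt) == geno.values[0, 0]
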