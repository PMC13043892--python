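"""Low-coverage sequencing emulation and genotype-likelihood inference.

This is the uncertainty layer between simulated truth and the classifier:
diploid genotypes are observed only through a shallow pileup of error-prone
reads (depth ~ Poisson, per-read allele flips with probability ``error``),
and downstream code works with genotype likelihoods, an EM estimate of the
per-site allele frequency, and the posterior expected allele dosage under a
Hardy-Weinberg prior at that frequency -- the standard low-coverage workflow
(ANGSD-style), re-implemented for the biallelic flip-error model.

The same flip-error model is used for simulation and for the likelihood, so
inference here is correctly specified by construction; this is a deliberate
simplification of the four-base epsilon/3 error model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np

from .sim import HaplotypeSample

__all__ = [
    "GenotypeMatrix",
    "ReadPileup",
    "GLMatrix",
    "DosageMatrix",
    "DosageError",
    "collapse_to_genotypes",
    "simulate_pileup",
    "genotype_loglik",
    "genotype_loglik_matrix",
    "estimate_freq_em",
    "estimate_frequencies",
    "posterior_dosage",
    "dosage_from_reads",
    "write_vcf",
]

GENOTYPES = np.array([0.0, 1.0, 2.0])


class DosageError(ValueError):
    """Posterior dosage undefined (zero total probability) at some entry."""


@dataclass
class GenotypeMatrix:
    """n_sample x S matrix counting derived-allele copies (0/1/2)."""

    values: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != self.positions.shape[0]:
            raise ValueError("values/positions mismatch")

    @property
    def n_sample(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]


@dataclass
class ReadPileup:
    """Per (individual, site) read counts supporting allele 0 and allele 1."""

    a0: np.ndarray
    a1: np.ndarray
    mean_depth: float
    error: float
    positions: Optional[np.ndarray] = None

    def __post_init__(self):
        self.a0 = np.asarray(self.a0, dtype=np.int64)
        self.a1 = np.asarray(self.a1, dtype=np.int64)
        if self.a0.shape != self.a1.shape:
            raise ValueError("a0/a1 shape mismatch")
        if (self.a0 < 0).any() or (self.a1 < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.a0 + self.a1


@dataclass
class GLMatrix:
    """Per (individual, site) max-normalized genotype log-likelihoods.

    ``loglik[i, j]`` is the (3,) vector for genotypes 0/1/2; entries are <= 0
    with the per-entry maximum at 0, and depth-0 entries are (0, 0, 0).
    """

    loglik: np.ndarray  # (n, S, 3)
    error: float
    positions: Optional[np.ndarray] = None

    def __post_init__(self):
        self.loglik = np.asarray(self.loglik, dtype=np.float64)
        if self.loglik.ndim != 3 or self.loglik.shape[2] != 3:
            raise ValueError("loglik must have shape (n, S, 3)")

    def likelihoods(self) -> np.ndarray:
        """Natural-scale likelihoods (per-entry max = 1)."""
        return np.exp(self.loglik)


@dataclass
class DosageMatrix:
    """Posterior expected derived-allele count per (individual, site)."""

    dosage: np.ndarray  # (n, S) in [0, 2]
    freq: np.ndarray  # per-site estimated derived-allele frequency
    degenerate: Optional[np.ndarray] = None  # sites where the EM had no data
    positions: Optional[np.ndarray] = None


def collapse_to_genotypes(sample: HaplotypeSample) -> GenotypeMatrix:
    """Sum haplotype rows (2i, 2i+1) into unphased genotypes."""
    alleles = sample.alleles
    if alleles.shape[0] % 2 != 0:
        raise ValueError("haplotype count must be even")
    geno = alleles[0::2].astype(np.int8) + alleles[1::2]
    return GenotypeMatrix(values=geno, positions=sample.positions)


def simulate_pileup(
    genotypes: GenotypeMatrix,
    mean_depth: float = 5.0,
    error: float = 0.005,
    rng: Optional[np.random.Generator] = None,
) -> ReadPileup:
    """Sample a read pileup: Poisson depth, uniform allele choice per read,
    and per-read flips with probability ``error``."""
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    if not 0.0 <= error < 0.5:
        raise ValueError("error must be in [0, 0.5)")
    rng = rng if rng is not None else np.random.default_rng()
    g = genotypes.values.astype(np.float64)
    depth = rng.poisson(mean_depth, size=g.shape)
    # P(read shows allele 1 | genotype g) under the flip-error model
    p1 = (g / 2.0) * (1.0 - error) + (1.0 - g / 2.0) * error
    a1 = rng.binomial(depth, p1)
    return ReadPileup(
        a0=depth - a1, a1=a1, mean_depth=mean_depth, error=error,
        positions=genotypes.positions,
    )


def _log_read_probs(error: float) -> Tuple[np.ndarray, np.ndarray]:
    pg = GENOTYPES / 2.0 * (1.0 - error) + (1.0 - GENOTYPES / 2.0) * error
    with np.errstate(divide="ignore"):
        return np.log(pg), np.log1p(-pg)


def genotype_loglik(a0: int, a1: int, error: float) -> Tuple[float, float, float]:
    """Max-normalized genotype log-likelihoods for one pileup entry.

    l_g = a1*log(p_g) + a0*log(1 - p_g) with p_g = (g/2)(1-e) + (1-g/2)e.
    Zero depth gives the non-informative (0, 0, 0); with error=0, a genotype
    contradicted by the reads gets -inf (never an exception).
    """
    if a0 < 0 or a1 < 0:
        raise ValueError("read counts must be non-negative")
    if a0 + a1 == 0:
        return (0.0, 0.0, 0.0)
    log_p, log_q = _log_read_probs(error)
    # 0 * log(0) is "no reads of that kind", i.e. a zero contribution
    ll = (a1 * log_p if a1 else np.zeros(3)) + (a0 * log_q if a0 else np.zeros(3))
    ll = ll - ll.max()
    return (float(ll[0]), float(ll[1]), float(ll[2]))


def genotype_loglik_matrix(pileup: ReadPileup) -> GLMatrix:
    """Vectorized :func:`genotype_loglik` over a whole pileup."""
    log_p, log_q = _log_read_probs(pileup.error)
    a0 = pileup.a0[..., None]
    a1 = pileup.a1[..., None]
    with np.errstate(invalid="ignore"):
        t1 = np.where(a1 == 0, 0.0, a1 * log_p)
        t0 = np.where(a0 == 0, 0.0, a0 * log_q)
    ll = t1 + t0
    ll = ll - ll.max(axis=-1, keepdims=True)
    return GLMatrix(loglik=ll, error=pileup.error, positions=pileup.positions)


def estimate_freq_em(
    site_loglik: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> Tuple[float, bool]:
    """ML derived-allele frequency for one site by EM over genotype likelihoods.

    ``site_loglik`` is (n, 3) max-normalized log-likelihoods.  The update is
    q' = (1/2n) * sum_i sum_g g * w_ig with w_ig proportional to
    L_ig * HWE_g(q).  Returns (q_hat, degenerate); a site where every
    individual is non-informative (flat likelihoods) returns (0.5, True).
    """
    lik = np.exp(np.asarray(site_loglik, dtype=np.float64))
    if lik.ndim != 2 or lik.shape[1] != 3:
        raise ValueError("site_loglik must have shape (n, 3)")
    n = lik.shape[0]
    if n < 1:
        raise ValueError("need at least one individual")
    informative = np.ptp(lik, axis=1) > 0
    if not informative.any():
        return 0.5, True
    q = 0.2
    for _ in range(max_iter):
        hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
        w = lik * hwe
        denom = w.sum(axis=1, keepdims=True)
        # a flat-likelihood individual still contributes its prior mean
        w = w / denom
        q_new = float((w @ GENOTYPES).sum() / (2 * n))
        if abs(q_new - q) < tol:
            q = q_new
            break
        q = q_new
    return q, False


def estimate_frequencies(gl: GLMatrix, tol: float = 1e-8, max_iter: int = 200):
    """Per-site EM frequencies; returns (freq array, degenerate-flag array).

    Runs the :func:`estimate_freq_em` update for all sites simultaneously
    (each site's EM is independent; batching only changes how many updates a
    site receives after its own convergence, which moves q by less than tol).
    """
    lik = np.exp(gl.loglik)  # (n, S, 3)
    n, S, _ = lik.shape
    if S == 0:
        return np.empty(0), np.zeros(0, dtype=bool)
    informative = (np.ptp(lik, axis=2) > 0).any(axis=0)
    q = np.full(S, 0.2)
    for _ in range(max_iter):
        hwe = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q * q], axis=1)  # (S, 3)
        w = lik * hwe[None, :, :]
        w /= w.sum(axis=2, keepdims=True)
        q_new = (w @ GENOTYPES).sum(axis=0) / (2 * n)
        done = np.abs(q_new - q)[informative] < tol
        q = q_new
        if done.all():
            break
    q = np.where(informative, q, 0.5)
    return q, ~informative


def posterior_dosage(
    gl: GLMatrix,
    freq: np.ndarray,
    degenerate: Optional[np.ndarray] = None,
    flat_prior: bool = False,
) -> DosageMatrix:
    """Posterior mean derived-allele count under a HWE prior at ``freq``.

    E[g | reads] = sum_g g L_g HWE_g(q) / sum_g L_g HWE_g(q).  With zero
    depth this reduces exactly to the prior mean 2q.  ``flat_prior`` replaces
    HWE with (1/3, 1/3, 1/3).
    """
    freq = np.asarray(freq, dtype=np.float64)
    if freq.ndim != 1 or freq.shape[0] != gl.loglik.shape[1]:
        raise ValueError("freq must have one entry per site")
    if (freq < 0).any() or (freq > 1).any():
        raise ValueError("frequencies must be in [0, 1]")
    lik = gl.likelihoods()
    if flat_prior:
        prior = np.full((freq.size, 3), 1.0 / 3.0)
    else:
        prior = np.stack([(1 - freq) ** 2, 2 * freq * (1 - freq), freq**2], axis=1)
    post = lik * prior[None, :, :]
    denom = post.sum(axis=2)
    bad = denom <= 0
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DosageError(
            f"zero posterior mass for individual {i} at site {j} "
            "(data impossible under the prior)"
        )
    dosage = (post @ GENOTYPES) / denom
    # flat-likelihood entries (zero depth) reduce to the prior mean exactly
    if not flat_prior:
        flat = np.ptp(lik, axis=2) == 0
        if flat.any():
            dosage = np.where(flat, 2.0 * freq[None, :], dosage)
    return DosageMatrix(
        dosage=dosage, freq=freq, degenerate=degenerate, positions=gl.positions
    )


def dosage_from_reads(
    pileup: ReadPileup, tol: float = 1e-8, max_iter: int = 200, flat_prior: bool = False
) -> DosageMatrix:
    """Pileup -> genotype likelihoods -> EM frequency -> posterior dosage."""
    gl = genotype_loglik_matrix(pileup)
    freq, degen = estimate_frequencies(gl, tol=tol, max_iter=max_iter)
    return posterior_dosage(gl, freq, degenerate=degen, flat_prior=flat_prior)


def write_vcf(
    path: Union[str, Path],
    genotypes: GenotypeMatrix,
    dosage: Optional[DosageMatrix] = None,
    contig: str = "1",
    contig_length: Optional[int] = None,
    sample_prefix: str = "ind",
) -> None:
    """Export hard-called genotypes (GT) and optional dosages (DS) as VCF."""
    import pysam

    n, S = genotypes.values.shape
    if contig_length is None:
        contig_length = int(np.ceil(genotypes.positions.max())) + 1 if S else 1
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    header.add_line('##INFO=<ID=AF,Number=1,Type=Float,Description="Derived allele frequency">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected derived dosage">')
    for i in range(n):
        header.add_sample(f"{sample_prefix}{i}")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j in range(S):
            rec = vcf.new_record(
                contig=contig,
                start=int(genotypes.positions[j]),
                alleles=("A", "T"),
            )
            g_col = genotypes.values[:, j]
            rec.info["AF"] = float(g_col.sum() / (2 * n))
            for i, name in enumerate(vcf.header.samples):
                g = int(g_col[i])
                rec.samples[name]["GT"] = [(0, 0), (0, 1), (1, 1)][g]
                if dosage is not None:
                    rec.samples[name]["DS"] = float(dosage.dosage[i, j])
            vcf.write(rec)
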