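# Methods

This note documents the models implemented in `sweepdann`, the defaults and
the reasoning behind them, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter when reproducing or
extending the results.

## Forward Wright–Fisher engine (`sweepdann.sim`)

The engine evolves a full diploid population of `2N` binary haplotypes on a
continuous sequence of length `L` under the infinite-sites model. One
generation consists of: fitness-weighted multinomial choice of a parent
diploid per gamete, recombination of the parent's two haplotypes with a
Poisson(`r·L`) number of uniformly placed crossovers, and Poisson(`mu·L`)
new mutations at fresh uniform positions. Selection acts on a single focal
site with genotype fitnesses `(1, 1+hs, 1+s)` for 0/1/2 beneficial copies.
Demography is a piecewise-constant schedule of diploid sizes whose final
epoch ends at the sampling time; the sample is `n` diploids drawn without
replacement, and only sites segregating in the sample are emitted.

**Initialization.** Populations start at neutral mutation–drift equilibrium
drawn from the coalescent with recombination (msprime, binary mutation model
on a continuous genome) at the first epoch's size. This is the stationary
distribution of the neutral forward model, so the forward phase only needs
to cover the demographic events and the sweep itself. A monomorphic start
with an explicit forward burn-in remains available (`init="monomorphic"`,
`SimParams.burn_in`) for validation at small scale, but a `10N`-generation
burn-in per replicate is orders of magnitude more expensive and adds nothing
once the coalescent start is exact.

**Sweep conditioning.** A single beneficial copy is introduced at
`position_fraction·L` (default 0.5), `origin_time` generations before
sampling. By default `origin_time` is `ceil(2.5·ln(2N)/(h·s))`, the
deterministic semidominant sweep duration `~(2/hs)·ln(2N)` plus ~25% slack,
so conditioned runs usually complete fixation shortly before sampling — a
recent hard sweep. A run is accepted only if the final beneficial frequency
is ≥ `min_final_freq` (default 1.0); otherwise the selected phase restarts
from the saved pre-sweep state, up to `max_attempts` times. Early loss
aborts an attempt immediately, which keeps conditioning cheap (acceptance
per attempt is roughly the diffusion fixation probability
`(1−e^{−s})/(1−e^{−2Ns})` for `h=1/2`). If the beneficial site is still
segregating at sampling (possible when `min_final_freq < 1`), it is emitted
as an ordinary site; once fixed it is invariant in the sample and therefore
excluded like any other monomorphic column.

**Default locus.** `L = 100 kb` with per-bp population-scaled rates
`4N·mu = 4N·r = 0.005` at the reference size `N = 500` (i.e.
`mu = r = 2.5e-6`). Per-bp diversity of 0.005 sits inside the empirically
common range (human ~0.001, Drosophila ~0.01) and keeps a full 400-replicate
validation experiment at this locus size within minutes on one CPU; engine
cost scales linearly with the number of segregating sites carried by the
population (~`4N·mu·L·ln(2N)`). When running at a different `N`, rescale
`mu`, `r`, `s` to preserve `4Nmu`, `4Nr`, `2Ns`. All of these are config
knobs, not hard-coded constants.

**Internal representation.** Polymorphic sites are split between a
position-sorted "core" matrix — so each crossover is a contiguous
column-slice copy located by binary search — and a small unsorted buffer of
recent mutations that is merged (and purged of fixed/lost columns) whenever
it exceeds a fixed width. This is purely an implementation detail; the
emitted samples are independent of the compaction schedule.

## Read model (`sweepdann.reads`)

Sequencing is emulated per (individual, site): depth `d ~ Poisson(mean_depth)`
(default 5), each read copies one of the two alleles uniformly and is
flipped with probability `error` (default 0.005). Zero depth is legal and
represents missing data. Genotype log-likelihoods follow the same biallelic
flip model, `l_g = a1·log(p_g) + a0·log(1−p_g)` with
`p_g = (g/2)(1−e) + (1−g/2)e`, max-normalized per entry; with `error = 0` a
contradicted homozygote gets `-inf`, never an exception. Because simulation
and inference share the identical error model, the likelihood is correctly
specified by construction — a deliberate simplification of the four-base
(`e/3`) model used by full variant callers.

Per-site derived-allele frequencies are maximized by EM
(`q' = (1/2n)·Σ_i Σ_g g·w_ig`, `w_ig ∝ L_ig·HWE_g(q)`), initialized at
`q = 0.2`, tolerance `1e-8`, at most 200 iterations; a site where every
individual has zero depth returns `q̂ = 0.5` with a degeneracy flag. The
batched implementation runs all sites' independent EMs simultaneously.
Expected dosages are posterior means under the Hardy–Weinberg prior at the
EM frequency; zero-depth entries reduce to the prior mean `2q̂` *exactly*
(special-cased so floating-point normalization cannot break the identity).
A flat-prior variant is available behind a flag. Frequencies are estimated
from the sampled panel itself (as a real low-coverage workflow must); with
10 diploids this adds noticeable noise to the polarization step, which is
part of the intended target-domain difficulty.

## Image encoding (`sweepdann.images`)

Each replicate becomes an `n × W` image (default `W = 64`): windows
partition `[0, L)` evenly; a pixel is the window mean of the individual's
major-allele dosage divided by 2, hence in `[0, 1]` with 1 = homozygous for
the sample-wise major allele at every site. The major allele is allele 1 iff
its frequency exceeds 0.5, with ties (exactly 0.5) assigned to allele 0;
windows containing no segregating site are filled with 1.0, because an
invariant region is all-major by definition. Rows keep sampling order — no
resorting — so row identity is stable and saliency maps refer to fixed
individuals; an optional row-sorting flag exists but is off by default.

One caveat worth knowing: at sites whose sample frequency is exactly 0.5
(common with 20 haplotypes) the major-allele polarity is unidentifiable from
reads, so the noisy and exact encodings of such sites legitimately disagree
regardless of depth. The encoder-convergence test therefore compares the
two paths on unambiguous sites only.

## Classifiers (`sweepdann.nn`)

Both models share one convolutional feature extractor implemented directly
in numpy (float64) with hand-written backpropagation; the suite verifies all
gradients against central finite differences. Default blocks: 3×3
same-padding convolutions (stride 1), optional per-channel batch
normalization, ReLU, and max-pooling. The label head and (for the DANN) the
domain head are small dense networks on the feature vector. Two feature
reductions are supported: `flatten` (default — sweeps are *positional*
signals, and flattening preserves the window coordinate) and `gap` (global
average pooling, location-free). Inputs are standardized by the mean and
standard deviation of the training source images; the constants are stored
with the model and applied identically at test time.

Training uses Adam (lr `1e-3`, batch 64, default 20 epochs), with every
stochastic choice (initialization, shuffling, target resampling) drawn from
named substreams of one seed, so training is bit-reproducible. The DANN adds
the domain cross-entropy on source ∪ target batches, routed into the feature
extractor through a gradient-reversal layer (forward identity, backward
gain `−lambda`), with `lambda(p) = 2/(1+e^{−gamma·p}) − 1`, `gamma = 10`,
and a 1:1 loss weighting (both exposed as knobs). Unlabeled target batches
are drawn with replacement to match the source batch count. Batch-norm
running statistics are updated only on source passes: target batches are
normalized by their own batch statistics during training but never touch the
inference statistics. This keeps an exact invariant: with `gamma = 0`
(hence `lambda ≡ 0`) the DANN's label path reproduces the source-only CNN's
updates bit for bit under shared seed and batching.

## Evaluation and explanation (`sweepdann.evaluate`)

Accuracy thresholds sweep probabilities at 0.5, with ties classified
neutral. Power at false-positive rate `alpha` uses a conservative empirical
quantile: the threshold is the `ceil((1−alpha)·m)`-th order statistic of the
`m` neutral scores and detections are *strictly* above it, so the realized
FPR never exceeds `alpha`; this equals the brute-force maximum power subject
to that constraint. ROC curves are delegated to scikit-learn and checked
against the O(n²) pairwise-ranking formula in the tests. Grad-CAM targets
the final convolution block: channel weights are spatial means of
`∂(class logit)/∂(activation)`, the map is the rectified weighted activation
sum, bilinearly upsampled to image resolution and max-normalized (an
all-zero map stays all-zero, bypassing normalization). Class-mean maps
average the per-image normalized maps and renormalize.

## The experiment and its reduced-scale configuration

The showcased experiment trains on clean images from a constant-size history
(source) and evaluates on a bottlenecked history observed through the read
model (target): a compound domain shift in both demography and data quality.
The pipeline defaults mirror the full design (1,000 source images per class,
500 unlabeled target, 500 labeled target test per class, `N = 500`).

For single-CPU validation the package fixes one *reduced-scale*
configuration (`sweepdann.pipeline.reduced_config`): `N = 100` diploids,
`L = 20 kb`, per-bp `4Nmu = 0.005` and `4Nr = 0.01` — the doubled
recombination keeps the hitchhiking footprint (`~s/(r·ln 2Ns)` ≈ 5 kb) at
about a quarter of the locus, so the sweep stays a *localized* central band
rather than a genome-wide darkening — `s = 0.6` (`2Ns = 120`, a strong hard
sweep), a 5-fold bottleneck lasting `0.12N` generations ending `0.06N`
generations before sampling, `W = 64` windows, conv channels (8, 16, 32)
with batch normalization, flattened features, 12 epochs, and 500/250/250
replicates. These sizes were chosen once, for scientific interpretability at
tractable cost, and are recorded here rather than scattered through the
tests.

**What the reduced-scale comparison shows — and does not.** Within this
configuration the sweep task itself behaves as expected: source-domain power
approaches 1, target-domain AUC sits near 0.85, and Grad-CAM attention on
sweep images concentrates in the central columns. The CNN-vs-DANN contrast,
however, is a dead heat: across master seeds the two models' target-domain
power at 5% FPR differs by a few points in either direction, with no
reliable DANN advantage. Diagnostics in the development history (domain-head
accuracy reaching ~0.5, i.e. successful feature alignment; no gain from
oracle moment-matching of the target inputs) indicate that at this scale the
bottleneck-plus-reads shift simply does not corrupt the *ranking* induced by
a source-trained CNN — the fixed-FPR threshold is recomputed on target
neutral scores, so purely global score shifts are already discounted by the
metric. A reproducible DANN advantage presumably needs shifts that mislead
source-learned features themselves (or the far larger training scale of the
original design). The acceptance test records this comparison honestly
rather than tuning the generator until the expected ordering appears.

## What the generator does and does not emulate

Emulated: finite-population drift, recombination, infinite-sites mutation,
hard selective sweeps with conditioning, stepwise demography, shallow
error-prone sequencing, genotype-likelihood-based dosage estimation,
unphased data, small panels. Not emulated: mapping/alignment artifacts,
indels, base-quality variation and recalibration, multi-allelic sites, SNP
discovery/filtering (the site list comes from the true sample polymorphisms),
gene conversion, crossover interference, background selection, soft or
partial standing-variation sweeps, population structure, and non-equilibrium
mutation processes. Passing tests therefore demonstrate correctness of the
implemented models and the qualitative geometry of sweep signatures under
this idealization — not calibrated performance on real resequencing data.

## Numerical conventions

- Positions are 0-based, half-open in `[0, L)`, emitted as fractions of `L`
  in ms output (full double precision, so round trips are lossless).
- Frequency ties at 0.5 polarize to allele 0; score ties at the accuracy
  threshold classify neutral; the power threshold uses the "higher" order
  statistic with strict inequality (realized FPR ≤ alpha by construction).
- EM: init 0.2, tol 1e-8, ≤200 iterations; flat-likelihood sites → 0.5 +
  degeneracy flag; zero-depth dosage ≡ 2q̂ exactly.
- Empty image windows fill with 1.0; all-zero saliency maps skip
  max-normalization.
- Every stage seed derives from the master seed via
  `SeedSequence([master, crc32(stage_name), replicate_index])`; derived
  integer seeds stay below 2^31.
- Sub-batch numerics: the DANN forwards source and target batches through
  the feature extractor separately, so its source-batch arithmetic is
  bitwise identical to the CNN's.

## Known limitations

- The forward engine's cost grows with `4Nmu·L·ln(2N)`; population-scale
  parameters far above the defaults call for stronger rescaling.
- Fixation-time heuristics behind the default `origin_time` assume
  `h ≈ 1/2`; fully recessive beneficial alleles (`h = 0`) fall back to a
  conservative guess and may need an explicit `origin_time`.
- The classifiers are deliberately small (tens of thousands of parameters);
  they are meant for controlled methodological comparison, not maximal
  benchmark accuracy.
- Batch-norm inference uses source-derived statistics for both domains; this
  is the honest source-only deployment convention, not the adaptive variant.
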