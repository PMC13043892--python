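"""Forward-in-time Wright-Fisher simulation of neutral and sweep loci.

The engine evolves a full diploid population (2N binary haplotypes over an
infinite-sites continuous sequence) one non-overlapping generation at a time:
fitness-weighted parent sampling, Poisson crossovers with uniform breakpoints,
and Poisson infinite-sites mutation.  Demographic history is a piecewise-
constant schedule of diploid sizes; selection acts at a single focal site with
genotype fitnesses (1, 1+hs, 1+s).

Populations are initialized at neutral mutation-drift equilibrium by a
coalescent simulation (msprime) under the first epoch's size, so the forward
phase only has to cover the demographic events and the sweep itself rather
than an O(10N)-generation burn-in.  A monomorphic start plus explicit forward
burn-in remains available through ``SimParams.burn_in`` /
``init="monomorphic"`` for validation work at small scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import msprime
import numpy as np

__all__ = [
    "Demography",
    "Epoch",
    "SimParams",
    "SweepParams",
    "HaplotypeSample",
    "WFPopulation",
    "InvalidStateError",
    "SweepConditioningError",
    "advance_generation",
    "initial_population",
    "simulate_neutral",
    "simulate_sweep",
    "sample_heterozygosity",
    "nucleotide_diversity",
]

logger = logging.getLogger(__name__)

NEUTRAL = "neutral"
SWEEP = "sweep"
SOURCE = "source"
TARGET = "target"

# Fresh-mutation buffer width that triggers compaction into the sorted core.
_FRESH_LIMIT = 3000


class InvalidStateError(RuntimeError):
    """Population state cannot produce a next generation."""


class SweepConditioningError(RuntimeError):
    """All restart attempts failed to satisfy the sweep frequency condition."""

    def __init__(self, attempts: int, min_final_freq: float):
        self.attempts = attempts
        super().__init__(
            f"beneficial allele failed to reach frequency {min_final_freq} "
            f"at sampling in {attempts} attempts"
        )


@dataclass(frozen=True)
class Epoch:
    """One constant-size demographic interval (duration in generations)."""

    duration: int
    size: int

    def __post_init__(self):
        if self.duration < 1:
            raise ValueError(f"epoch duration must be >= 1, got {self.duration}")
        if self.size < 2:
            raise ValueError(f"epoch size must be >= 2, got {self.size}")


@dataclass(frozen=True)
class Demography:
    """Piecewise-constant diploid population sizes, oldest epoch first.

    The end of the final epoch is the sampling time.
    """

    epochs: Tuple[Epoch, ...]

    def __post_init__(self):
        if len(self.epochs) == 0:
            raise ValueError("demography needs at least one epoch")
        object.__setattr__(
            self, "epochs", tuple(e if isinstance(e, Epoch) else Epoch(*e) for e in self.epochs)
        )

    @property
    def min_size(self) -> int:
        return min(e.size for e in self.epochs)

    @property
    def total_generations(self) -> int:
        return sum(e.duration for e in self.epochs)

    def size_schedule(self) -> np.ndarray:
        """Diploid size of the offspring generation, one entry per forward step."""
        return np.concatenate([np.full(e.duration, e.size, dtype=np.int64) for e in self.epochs])

    @classmethod
    def constant(cls, size: int, duration: Optional[int] = None) -> "Demography":
        """Single constant-size epoch (default duration 0.2*N generations)."""
        if duration is None:
            duration = max(1, size // 5)
        return cls(epochs=(Epoch(duration, size),))

    @classmethod
    def bottleneck(
        cls,
        size: int,
        severity: int = 10,
        bottleneck_duration: Optional[int] = None,
        recovery_duration: Optional[int] = None,
        pre_duration: Optional[int] = None,
    ) -> "Demography":
        """Ancestral size, a crash to size/severity, then recovery.

        Defaults: crash lasts 0.1*N generations and ends 0.05*N generations
        before sampling.
        """
        if bottleneck_duration is None:
            bottleneck_duration = max(1, size // 10)
        if recovery_duration is None:
            recovery_duration = max(1, size // 20)
        if pre_duration is None:
            pre_duration = max(1, size // 20)
        small = max(2, size // severity)
        return cls(
            epochs=(
                Epoch(pre_duration, size),
                Epoch(bottleneck_duration, small),
                Epoch(recovery_duration, size),
            )
        )


@dataclass(frozen=True)
class SimParams:
    """Locus and sampling parameters.

    Defaults give a 100 kb locus with per-bp population-scaled rates
    4*N*mu = 4*N*r = 0.005 at the reference size N=500; when running at a
    different N, pass rescaled mu and r to preserve the population-scaled
    rates (see docs/methods.md).
    """

    L: float = 100_000.0
    mu: float = 2.5e-6
    r: float = 2.5e-6
    n_sample: int = 10
    burn_in: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.mu < 0 or self.r < 0:
            raise ValueError("mutation/recombination rates must be non-negative")
        if self.n_sample < 1:
            raise ValueError("n_sample must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")

    def validate_against(self, demography: Demography) -> None:
        if self.n_sample > demography.min_size:
            raise ValueError(
                f"n_sample={self.n_sample} exceeds smallest epoch size "
                f"{demography.min_size}"
            )


@dataclass(frozen=True)
class SweepParams:
    """Hard-sweep settings: single beneficial mutation, genotype fitnesses
    (1, 1+h*s, 1+s), conditioned on a minimum final frequency at sampling."""

    s: float = 0.25
    h: float = 0.5
    position_fraction: float = 0.5
    min_final_freq: float = 1.0
    max_attempts: int = 200
    origin_time: Optional[int] = None  # generations before sampling; None = auto

    def __post_init__(self):
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must be in [0, 1]")
        if not 0.0 < self.position_fraction < 1.0:
            raise ValueError("position_fraction must be in (0, 1)")
        if not 0.0 < self.min_final_freq <= 1.0:
            raise ValueError("min_final_freq must be in (0, 1]")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")

    def fitness_weights(self) -> Tuple[float, float, float]:
        return (1.0, 1.0 + self.h * self.s, 1.0 + self.s)

    def auto_origin_time(self, n_diploid: int) -> int:
        """Generations before sampling to introduce the single copy.

        Uses the deterministic semidominant sweep duration
        ~ (2/(h*s)) * ln(2N) plus 25% slack so that conditioned runs
        usually complete fixation just before sampling.
        """
        if self.origin_time is not None:
            return self.origin_time
        hs = max(self.h * self.s, 0.5 * self.s, 1e-9)
        return int(math.ceil(2.5 * math.log(2 * n_diploid) / hs))


@dataclass
class HaplotypeSample:
    """Binary haplotype alignment of ``2*n_sample`` rows.

    Rows ``2i`` and ``2i+1`` are the two haplotypes of diploid individual
    ``i``; columns are segregating sites at strictly increasing positions in
    ``[0, L)``; 0 = ancestral, 1 = derived.
    """

    positions: np.ndarray
    alleles: np.ndarray
    label: str
    domain: str = SOURCE
    params: Optional[SimParams] = None
    demography: Optional[Demography] = None
    sweep: Optional[SweepParams] = None
    seed: Optional[int] = None
    final_freq: Optional[float] = None  # beneficial-allele frequency at sampling

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D")
        if self.alleles.shape[0] % 2 != 0:
            raise ValueError("alleles must have an even number of rows")
        if self.alleles.shape[1] != self.positions.shape[0]:
            raise ValueError("positions/alleles column mismatch")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.label not in (NEUTRAL, SWEEP):
            raise ValueError(f"label must be '{NEUTRAL}' or '{SWEEP}'")
        if self.domain not in (SOURCE, TARGET):
            raise ValueError(f"domain must be '{SOURCE}' or '{TARGET}'")

    @property
    def n_sample(self) -> int:
        return self.alleles.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def L(self) -> float:
        return self.params.L if self.params is not None else float(
            self.positions[-1] + 1 if self.positions.size else 1.0
        )


class WFPopulation:
    """Mutable population state for the forward engine.

    Polymorphic sites are split between a position-sorted ``core`` matrix
    (so crossovers translate into contiguous column-slice copies) and a small
    unsorted ``fresh`` buffer holding mutations younger than the last
    compaction; both are (2N, S_part) uint8.  A focal selected site, when
    present, is tracked separately in ``focal`` so its frequency is known
    even while fixed or absent from the polymorphic matrices.
    """

    __slots__ = ("core", "core_pos", "fresh", "fresh_pos", "L", "focal", "focal_pos")

    def __init__(
        self,
        haps: np.ndarray,
        positions: np.ndarray,
        L: float,
        focal: Optional[np.ndarray] = None,
        focal_pos: Optional[float] = None,
    ):
        haps = np.ascontiguousarray(haps, dtype=np.uint8)
        positions = np.asarray(positions, dtype=np.float64)
        if haps.shape[1] != positions.shape[0]:
            raise ValueError("positions/haps mismatch")
        if haps.shape[0] % 2 != 0:
            raise ValueError("haplotype count must be even")
        order = np.argsort(positions, kind="stable")
        self.core = np.ascontiguousarray(haps[:, order])
        self.core_pos = positions[order]
        n_hap = haps.shape[0]
        self.fresh = np.zeros((n_hap, 0), dtype=np.uint8)
        self.fresh_pos = np.empty(0, dtype=np.float64)
        self.L = float(L)
        self.focal = None if focal is None else np.asarray(focal, dtype=np.uint8)
        self.focal_pos = focal_pos

    @property
    def haps(self) -> np.ndarray:
        """All polymorphic columns in sorted-position order (compacts first)."""
        self.prune()
        return self.core

    @property
    def positions(self) -> np.ndarray:
        self.prune()
        return self.core_pos

    @property
    def n_diploid(self) -> int:
        return self.core.shape[0] // 2

    def copy(self) -> "WFPopulation":
        pop = WFPopulation.__new__(WFPopulation)
        pop.core = self.core.copy()
        pop.core_pos = self.core_pos.copy()
        pop.fresh = self.fresh.copy()
        pop.fresh_pos = self.fresh_pos.copy()
        pop.L = self.L
        pop.focal = None if self.focal is None else self.focal.copy()
        pop.focal_pos = self.focal_pos
        return pop

    def focal_frequency(self) -> float:
        if self.focal is None:
            raise InvalidStateError("no focal site is being tracked")
        return float(self.focal.mean())

    def set_focal(self, position: float, carrier_haplotype: int) -> None:
        """Introduce a single derived copy at ``position`` on one haplotype."""
        self.focal = np.zeros(self.core.shape[0], dtype=np.uint8)
        self.focal[carrier_haplotype] = 1
        self.focal_pos = float(position)

    def prune(self) -> None:
        """Merge fresh mutations into the core, dropping fixed/lost columns
        and restoring sorted position order."""
        n_hap = self.core.shape[0]
        if self.fresh.shape[1] == 0 and self.core.shape[1] == 0:
            return
        if self.fresh.shape[1]:
            haps = np.concatenate([self.core, self.fresh], axis=1)
            positions = np.concatenate([self.core_pos, self.fresh_pos])
        else:
            haps, positions = self.core, self.core_pos
        counts = np.count_nonzero(haps, axis=0)
        keep = np.flatnonzero((counts > 0) & (counts < n_hap))
        order = keep[np.argsort(positions[keep], kind="stable")]
        self.core = np.take(haps, order, axis=1)
        self.core_pos = positions[order]
        self.fresh = np.zeros((n_hap, 0), dtype=np.uint8)
        self.fresh_pos = np.empty(0, dtype=np.float64)

    # ------------------------------------------------------------------
    def advance(
        self,
        params: SimParams,
        rng: np.random.Generator,
        weights: Optional[Tuple[float, float, float]] = None,
        next_size: Optional[int] = None,
    ) -> None:
        """Produce the next generation in place.

        Each of the ``2*next_size`` offspring haplotypes is a gamete from a
        fitness-chosen parent diploid: the parent's two haplotypes are
        recombined with a Poisson(r*L) number of uniform crossovers, and
        Poisson(mu*L) new mutations land at fresh uniform positions.
        """
        n_hap = self.core.shape[0]
        if n_hap == 0:
            raise InvalidStateError("population is empty")
        n_dip = n_hap // 2
        if next_size is None:
            next_size = n_dip
        n_off = 2 * next_size

        # Fitness-weighted parent choice (uniform when no selection).
        if weights is None or self.focal is None:
            parents = rng.integers(0, n_dip, size=n_off)
        else:
            w = np.asarray(weights, dtype=np.float64)
            geno = self.focal[0::2].astype(np.int64) + self.focal[1::2]
            fit = w[geno]
            total = fit.sum()
            if not np.isfinite(total) or total <= 0:
                raise InvalidStateError("all parent fitnesses are zero")
            cum = np.cumsum(fit)
            parents = np.searchsorted(cum, rng.random(n_off) * total, side="right")
            parents = np.minimum(parents, n_dip - 1)

        start = rng.integers(0, 2, size=n_off)
        hap_a = 2 * parents + start
        hap_b = 2 * parents + 1 - start

        Sc = self.core.shape[1]
        Sf = self.fresh.shape[1]
        exp_co = params.r * params.L
        k = rng.poisson(exp_co, size=n_off) if exp_co > 0 else None
        n_mut = int(rng.poisson(n_off * params.mu * params.L)) if params.mu > 0 else 0

        core_off = self.core[hap_a] if Sc else np.zeros((n_off, 0), dtype=np.uint8)
        fresh_off = np.zeros((n_off, Sf + n_mut), dtype=np.uint8)
        if Sf:
            fresh_off[:, :Sf] = self.fresh[hap_a]
        focal_off = self.focal[hap_a] if self.focal is not None else None

        if k is not None:
            # one crossover: a single suffix swap in the sorted core
            one = np.flatnonzero(k == 1)
            if one.size:
                bps = rng.uniform(0.0, self.L, size=one.size)
                if Sc:
                    cuts = np.searchsorted(self.core_pos, bps)
                    if one.size * Sc < 400_000:
                        # small matrices: one vectorized masked copy
                        m = np.arange(Sc)[None, :] >= cuts[:, None]
                        core_off[one] = np.where(m, self.core[hap_b[one]], core_off[one])
                    else:
                        # large matrices: contiguous per-gamete suffix copies
                        for i, j in zip(one, cuts):
                            core_off[i, j:] = self.core[hap_b[i], j:]
                if Sf:
                    m = self.fresh_pos[None, :] >= bps[:, None]
                    fresh_off[one, :Sf] = np.where(
                        m, self.fresh[hap_b[one]], fresh_off[one, :Sf]
                    )
                if focal_off is not None:
                    swap = self.focal_pos >= bps
                    focal_off[one] = np.where(swap, self.focal[hap_b[one]], focal_off[one])
            # multiple crossovers: alternate slices between the cut points
            for i in np.flatnonzero(k >= 2):
                ki = int(k[i])
                bp = np.sort(rng.uniform(0.0, self.L, size=ki))
                hb = hap_b[i]
                if Sc:
                    cuts = np.searchsorted(self.core_pos, bp)
                    for seg in range(0, ki, 2):
                        lo = cuts[seg]
                        hi = cuts[seg + 1] if seg + 1 < ki else Sc
                        core_off[i, lo:hi] = self.core[hb, lo:hi]
                if Sf:
                    odd = (np.searchsorted(bp, self.fresh_pos) % 2).astype(bool)
                    fresh_off[i, :Sf][odd] = self.fresh[hb][odd]
                if focal_off is not None and np.searchsorted(bp, self.focal_pos) % 2:
                    focal_off[i] = self.focal[hb]

        if n_mut:
            rows = rng.integers(0, n_off, size=n_mut)
            fresh_off[rows, Sf + np.arange(n_mut)] = 1
            self.fresh_pos = np.concatenate(
                [self.fresh_pos, rng.uniform(0.0, self.L, size=n_mut)]
            )

        self.core = core_off
        self.fresh = fresh_off
        self.focal = focal_off
        if self.fresh.shape[1] > _FRESH_LIMIT:
            self.prune()

    def run_schedule(
        self,
        params: SimParams,
        sizes: Sequence[int],
        rng: np.random.Generator,
        weights: Optional[Tuple[float, float, float]] = None,
        stop_on_focal_loss: bool = False,
    ) -> bool:
        """Advance through a per-generation size schedule.

        Returns False if ``stop_on_focal_loss`` is set and the focal allele
        was lost before the schedule completed, True otherwise.
        """
        for size in sizes:
            self.advance(params, rng, weights=weights, next_size=int(size))
            if stop_on_focal_loss and self.focal is not None and not self.focal.any():
                return False
        return True


def advance_generation(
    population: WFPopulation,
    fitness: Optional[Tuple[float, float, float]],
    params: SimParams,
    rng: np.random.Generator,
    next_size: Optional[int] = None,
) -> WFPopulation:
    """One Wright-Fisher generation; returns the same (mutated) population.

    ``fitness`` gives genotype weights for 0/1/2 beneficial copies at the
    tracked focal site; pass None (or leave the focal site untracked) for
    neutral resampling.
    """
    population.advance(params, rng, weights=fitness, next_size=next_size)
    return population


# ----------------------------------------------------------------------
# Initialization and sampling


def _rng_from(params: SimParams, rng: Optional[np.random.Generator]) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(params.seed)


def initial_population(
    params: SimParams,
    n_diploid: int,
    rng: np.random.Generator,
    init: str = "coalescent",
) -> WFPopulation:
    """Whole population of 2N haplotypes at neutral equilibrium.

    ``init="coalescent"`` draws the state from msprime under constant size
    ``n_diploid`` (the stationary distribution of the forward model);
    ``init="monomorphic"`` returns an invariant population, to be combined
    with an explicit forward burn-in.
    """
    if init == "monomorphic":
        return WFPopulation(
            np.zeros((2 * n_diploid, 0), dtype=np.uint8),
            np.empty(0, dtype=np.float64),
            params.L,
        )
    if init != "coalescent":
        raise ValueError(f"unknown init mode {init!r}")
    anc_seed = int(rng.integers(1, 2**31 - 1))
    mut_seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=n_diploid,
        ploidy=2,
        population_size=n_diploid,
        sequence_length=params.L,
        recombination_rate=params.r,
        discrete_genome=False,
        random_seed=anc_seed,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=params.mu,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=mut_seed,
    )
    geno = ts.genotype_matrix().T.astype(np.uint8)  # (2N, S)
    return WFPopulation(geno, ts.sites_position.copy(), params.L)


def _sample_from_population(
    pop: WFPopulation,
    params: SimParams,
    rng: np.random.Generator,
    label: str,
    domain: str,
    demography: Demography,
    sweep: Optional[SweepParams],
    include_focal: bool,
    final_freq: Optional[float] = None,
) -> HaplotypeSample:
    pop.prune()
    n_dip = pop.n_diploid
    ids = rng.choice(n_dip, size=params.n_sample, replace=False)
    rows = np.empty(2 * params.n_sample, dtype=np.int64)
    rows[0::2] = 2 * ids
    rows[1::2] = 2 * ids + 1

    alleles = pop.haps[rows]
    positions = pop.positions
    if include_focal and pop.focal is not None and pop.focal_pos is not None:
        focal_col = pop.focal[rows]
        c = int(focal_col.sum())
        if 0 < c < focal_col.size:  # still segregating: keep as ordinary site
            j = np.searchsorted(positions, pop.focal_pos)
            positions = np.insert(positions, j, pop.focal_pos)
            alleles = np.insert(alleles, j, focal_col, axis=1)

    counts = alleles.sum(axis=0, dtype=np.int64)
    seg = (counts > 0) & (counts < alleles.shape[0])
    alleles = np.ascontiguousarray(alleles[:, seg])
    positions = positions[seg]
    if positions.size == 0:
        logger.warning("sample has zero segregating sites (label=%s)", label)
    return HaplotypeSample(
        positions=positions,
        alleles=alleles,
        label=label,
        domain=domain,
        params=params,
        demography=demography,
        sweep=sweep,
        seed=params.seed,
        final_freq=final_freq,
    )


def simulate_neutral(
    params: SimParams,
    demography: Demography,
    rng: Optional[np.random.Generator] = None,
    domain: str = SOURCE,
    init: str = "coalescent",
) -> HaplotypeSample:
    """One neutral replicate: equilibrium start, epoch schedule, then sampling."""
    params.validate_against(demography)
    rng = _rng_from(params, rng)
    n0 = demography.epochs[0].size
    pop = initial_population(params, n0, rng, init=init)
    if params.burn_in:
        pop.run_schedule(params, np.full(params.burn_in, n0), rng)
    pop.run_schedule(params, demography.size_schedule(), rng)
    return _sample_from_population(
        pop, params, rng, NEUTRAL, domain, demography, None, include_focal=False
    )


def simulate_sweep(
    params: SimParams,
    demography: Demography,
    sweep: SweepParams,
    rng: Optional[np.random.Generator] = None,
    domain: str = SOURCE,
    init: str = "coalescent",
) -> HaplotypeSample:
    """One hard-sweep replicate conditioned on the final beneficial frequency.

    A single beneficial copy is introduced at ``position_fraction * L``,
    ``origin_time`` generations before sampling, and the run is accepted only
    if its frequency at sampling is >= ``min_final_freq``; otherwise the
    selected phase restarts from the pre-sweep state with fresh randomness,
    up to ``max_attempts`` times.
    """
    params.validate_against(demography)
    rng = _rng_from(params, rng)
    n0 = demography.epochs[0].size
    schedule = demography.size_schedule()
    origin = sweep.auto_origin_time(n0)
    if origin > schedule.size:
        # Introduce before the recorded schedule starts: extend at the
        # ancestral size so the sweep has `origin` generations to complete.
        schedule = np.concatenate(
            [np.full(origin - schedule.size, n0, dtype=np.int64), schedule]
        )
    intro_at = schedule.size - origin

    pop = initial_population(params, n0, rng, init=init)
    if params.burn_in:
        pop.run_schedule(params, np.full(params.burn_in, n0), rng)
    pop.run_schedule(params, schedule[:intro_at], rng)

    focal_pos = sweep.position_fraction * params.L
    weights = sweep.fitness_weights()
    base = pop.copy()
    tail = schedule[intro_at:]
    for _ in range(sweep.max_attempts):
        attempt = base.copy()
        carrier = int(rng.integers(0, attempt.haps.shape[0]))
        attempt.set_focal(focal_pos, carrier)
        survived = attempt.run_schedule(
            params, tail, rng, weights=weights, stop_on_focal_loss=True
        )
        if not survived:
            continue
        freq = attempt.focal_frequency()
        if freq >= sweep.min_final_freq:
            include = sweep.min_final_freq < 1.0
            return _sample_from_population(
                attempt, params, rng, SWEEP, domain, demography, sweep,
                include_focal=include, final_freq=freq,
            )
    raise SweepConditioningError(sweep.max_attempts, sweep.min_final_freq)


# ----------------------------------------------------------------------
# Small summary helpers used for engine validation


def sample_heterozygosity(sample: HaplotypeSample) -> float:
    """Mean per-site expected heterozygosity 2*p*(1-p), summed over sites."""
    if sample.n_sites == 0:
        return 0.0
    p = sample.alleles.mean(axis=0)
    return float(np.sum(2.0 * p * (1.0 - p)))


def nucleotide_diversity(
    sample: HaplotypeSample, start: float = 0.0, end: Optional[float] = None
) -> float:
    """Mean pairwise difference per bp within [start, end)."""
    if end is None:
        end = sample.L
    span = end - start
    if span <= 0:
        raise ValueError("empty interval")
    if sample.n_sites == 0:
        return 0.0
    in_win = (sample.positions >= start) & (sample.positions < end)
    if not in_win.any():
        return 0.0
    n = sample.alleles.shape[0]
    c = sample.alleles[:, in_win].sum(axis=0, dtype=np.int64)
    pair_diff = c * (n - c) / (n * (n - 1) / 2)
    return float(pair_diff.sum() / span)
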