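"""Neutral forward-in-time genome simulation.

Diploid individuals carry two haplotypes over a set of biallelic loci placed
on a genetic map.  Meiosis follows the Haldane model: per chromosome a
Poisson number of crossovers with expectation equal to the chromosome length
in Morgans, crossover positions uniform, no interference.  Mutation is a
symmetric per-locus allele flip applied independently to every locus of the
gamete.

The burn-in drives a constant-size Wright-Fisher-like population (every
individual contributes exactly two gametes, selfing excluded) to
mutation-drift equilibrium, starting from equifrequent alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneticMap",
    "MeiosisParams",
    "DiploidPopulation",
    "meiose",
    "meiose_many",
    "equal_contribution_pairing",
    "run_burnin",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticMap:
    """Genetic map: loci at known positions (Morgans) on linear chromosomes.

    Parameters
    ----------
    chromosome_lengths
        Length of each chromosome in Morgans.
    locus_chrom
        Chromosome index (0-based) of each locus, non-decreasing.
    locus_pos
        Position of each locus in Morgans within its chromosome, strictly
        increasing within a chromosome.
    """

    chromosome_lengths: np.ndarray
    locus_chrom: np.ndarray
    locus_pos: np.ndarray

    def __post_init__(self) -> None:
        cl = np.asarray(self.chromosome_lengths, dtype=float)
        lc = np.asarray(self.locus_chrom, dtype=np.int64)
        lp = np.asarray(self.locus_pos, dtype=float)
        object.__setattr__(self, "chromosome_lengths", cl)
        object.__setattr__(self, "locus_chrom", lc)
        object.__setattr__(self, "locus_pos", lp)
        if lc.shape != lp.shape:
            raise ValueError("locus_chrom and locus_pos must have equal length")
        if np.any(np.diff(lc) < 0):
            raise ValueError("locus_chrom must be sorted")
        if lc.size and (lc.min() < 0 or lc.max() >= cl.size):
            raise ValueError("locus_chrom out of range")
        for c in range(cl.size):
            pos = lp[lc == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
            if pos.size and (pos.min() < 0 or pos.max() > cl[c]):
                raise ValueError(f"locus outside chromosome {c}")

    @property
    def n_chromosomes(self) -> int:
        return int(self.chromosome_lengths.size)

    @property
    def n_loci(self) -> int:
        return int(self.locus_chrom.size)

    @property
    def total_length(self) -> float:
        return float(self.chromosome_lengths.sum())

    def cumulative_pos(self) -> np.ndarray:
        """Locus positions on a single concatenated axis (Morgans)."""
        offsets = np.concatenate([[0.0], np.cumsum(self.chromosome_lengths)[:-1]])
        return self.locus_pos + offsets[self.locus_chrom]

    @classmethod
    def uniform(
        cls,
        n_chromosomes: int = 16,
        total_length: float = 17.0,
        n_loci: int = 20000,
    ) -> "GeneticMap":
        """Equal-length chromosomes with equally spaced loci (study default:
        16 chromosomes, 17 Morgans, 20000 loci)."""
        if n_chromosomes < 1 or n_loci < 1 or total_length <= 0:
            raise ValueError("parameters must be positive")
        chrom_len = total_length / n_chromosomes
        # Loci equally spaced over the whole genome, then cut into chromosomes.
        step = total_length / n_loci
        gpos = (np.arange(n_loci) + 0.5) * step
        locus_chrom = np.minimum((gpos // chrom_len).astype(np.int64), n_chromosomes - 1)
        locus_pos = gpos - locus_chrom * chrom_len
        return cls(np.full(n_chromosomes, chrom_len), locus_chrom, locus_pos)


@dataclass(frozen=True)
class MeiosisParams:
    """Meiosis parameters: symmetric per-locus mutation rate (default 1e-5)."""

    mutation_rate: float = 1e-5

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")


@dataclass
class DiploidPopulation:
    """A cohort of diploid individuals with haplotypes and pedigree links.

    ``haplotypes`` has shape (n, 2, n_loci) with alleles in {0, 1};
    ``sire``/``dam`` hold global individual ids (-1 when unknown).
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    haplotypes: np.ndarray
    generation: int = 0
    label: str = "BASE"
    freq_spectrum: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        n = self.ids.size
        if self.sire.size != n or self.dam.size != n:
            raise ValueError("pedigree arrays must match ids")
        if self.haplotypes.shape[:2] != (n, 2):
            raise ValueError("haplotypes must have shape (n, 2, n_loci)")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("alleles must be 0/1")

    @property
    def size(self) -> int:
        return int(self.ids.size)

    @property
    def n_loci(self) -> int:
        return int(self.haplotypes.shape[2])

    def allele_freq(self) -> np.ndarray:
        """Frequency of allele 1 at every locus."""
        return self.haplotypes.mean(axis=(0, 1))

    def dosages(self) -> np.ndarray:
        """Allele-1 dosage (0/1/2) matrix, individuals x loci."""
        return self.haplotypes.sum(axis=1, dtype=np.int16)

    def subset(self, index: np.ndarray) -> "DiploidPopulation":
        index = np.asarray(index)
        return DiploidPopulation(
            self.ids[index], self.sire[index], self.dam[index],
            self.haplotypes[index], self.generation, self.label,
        )


class IdAllocator:
    """Monotonically increasing global individual ids."""

    def __init__(self, start: int = 0) -> None:
        self._next = int(start)

    def take(self, n: int) -> np.ndarray:
        out = np.arange(self._next, self._next + n, dtype=np.int64)
        self._next += n
        return out


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

def _chromosome_bounds(gmap: GeneticMap) -> np.ndarray:
    """Index of the first locus of each chromosome (plus final sentinel)."""
    return np.searchsorted(gmap.locus_chrom, np.arange(gmap.n_chromosomes + 1))


def meiose(
    parent_haplotypes: np.ndarray,
    gmap: GeneticMap,
    params: MeiosisParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Produce one gamete from a parent's two haplotypes.

    Crossover counts are Poisson(chromosome length in Morgans) with uniform
    positions; each chromosome starts from a random parental haplotype.
    Mutations then flip individual gamete alleles with ``mutation_rate``.
    """
    h = np.asarray(parent_haplotypes)
    if h.shape != (2, gmap.n_loci):
        raise ValueError("parent haplotypes do not match the map")
    source = _gamete_sources(gmap, rng, 1)[0]
    gamete = np.where(source == 0, h[0], h[1]).astype(np.uint8)
    _apply_mutation(gamete[None, :], params.mutation_rate, rng)
    return gamete


def _gamete_sources(gmap: GeneticMap, rng: np.random.Generator, n: int) -> np.ndarray:
    """Source haplotype (0/1) at each locus for ``n`` independent meioses."""
    bounds = _chromosome_bounds(gmap)
    out = np.empty((n, gmap.n_loci), dtype=np.uint8)
    lengths = gmap.chromosome_lengths
    starts = rng.integers(0, 2, size=(n, gmap.n_chromosomes), dtype=np.uint8)
    n_co = rng.poisson(lengths, size=(n, gmap.n_chromosomes))
    for i in range(n):
        for c in range(gmap.n_chromosomes):
            lo, hi = bounds[c], bounds[c + 1]
            k = n_co[i, c]
            if k == 0 or hi == lo:
                out[i, lo:hi] = starts[i, c]
                continue
            breaks = np.sort(rng.uniform(0.0, lengths[c], size=k))
            crossings = np.searchsorted(breaks, gmap.locus_pos[lo:hi], side="right")
            out[i, lo:hi] = (starts[i, c] + crossings) % 2
    return out


def _apply_mutation(gametes: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Flip alleles in place with probability ``rate`` per locus per gamete."""
    if rate <= 0.0:
        return
    n, L = gametes.shape
    n_mut = rng.binomial(n * L, rate)
    if n_mut == 0:
        return
    flat = rng.integers(0, n * L, size=n_mut)
    g = gametes.reshape(-1)
    g[flat] ^= 1


def meiose_many(
    parents: np.ndarray,
    which: np.ndarray,
    gmap: GeneticMap,
    params: MeiosisParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gametes from ``parents`` (n, 2, L) haplotype stacks, one per row of
    ``which`` (indices into ``parents``).  Returns (len(which), L) uint8."""
    which = np.asarray(which)
    sources = _gamete_sources(gmap, rng, which.size)
    h = parents[which]  # (m, 2, L)
    gametes = np.take_along_axis(h, sources[:, None, :].astype(np.int64), axis=1)[:, 0, :]
    gametes = np.ascontiguousarray(gametes, dtype=np.uint8)
    _apply_mutation(gametes, params.mutation_rate, rng)
    return gametes


# ---------------------------------------------------------------------------
# Equal-contribution random mating
# ---------------------------------------------------------------------------

def equal_contribution_pairing(
    n: int, rng: np.random.Generator, max_tries: int = 1000
) -> np.ndarray:
    """Random matings where every individual parents exactly two offspring.

    Returns an (n, 2) array of parent indices; no pair mates an individual
    with itself.  ``n`` must be even and >= 2.
    """
    if n < 2 or n % 2:
        raise ValueError("population size must be even and >= 2")
    for _ in range(max_tries):
        slots = rng.permutation(np.repeat(np.arange(n), 2))
        pairs = slots.reshape(n, 2)
        bad = pairs[:, 0] == pairs[:, 1]
        if not bad.any():
            return pairs
        # Repair self-pairs by swapping with a random other slot.
        ok = True
        for i in np.flatnonzero(bad):
            for _ in range(50):
                j = rng.integers(0, n)
                if j == i:
                    continue
                if (pairs[i, 0] != pairs[j, 1]) and (pairs[j, 0] != pairs[i, 1]):
                    pairs[i, 1], pairs[j, 1] = pairs[j, 1], pairs[i, 1]
                    break
            else:
                ok = False
                break
        if ok and not (pairs[:, 0] == pairs[:, 1]).any():
            return pairs
    raise RuntimeError("could not construct a selfing-free pairing")


# ---------------------------------------------------------------------------
# Burn-in
# ---------------------------------------------------------------------------

def _initial_haplotypes(
    n_ind: int, n_loci: int, rng: np.random.Generator
) -> np.ndarray:
    """Exactly equifrequent alleles: each locus carries n_ind ones among the
    2*n_ind haplotype alleles, in random placement."""
    n_hap = 2 * n_ind
    u = rng.random((n_hap, n_loci))
    ranks = np.argsort(u, axis=0, kind="stable")
    hap = np.zeros((n_hap, n_loci), dtype=np.uint8)
    cols = np.broadcast_to(np.arange(n_loci), (n_ind, n_loci))
    hap[ranks[:n_ind], cols] = 1
    return hap.reshape(n_ind, 2, n_loci)


def random_mating_generation(
    pop: DiploidPopulation,
    gmap: GeneticMap,
    params: MeiosisParams,
    rng: np.random.Generator,
    alloc: IdAllocator,
) -> DiploidPopulation:
    """One generation of equal-contribution random mating without selfing."""
    pairs = equal_contribution_pairing(pop.size, rng)
    g1 = meiose_many(pop.haplotypes, pairs[:, 0], gmap, params, rng)
    g2 = meiose_many(pop.haplotypes, pairs[:, 1], gmap, params, rng)
    haplo = np.stack([g1, g2], axis=1)
    ids = alloc.take(pop.size)
    return DiploidPopulation(
        ids, pop.ids[pairs[:, 0]], pop.ids[pairs[:, 1]], haplo,
        pop.generation + 1, pop.label,
    )


def run_burnin(
    n_ind: int,
    n_gen: int,
    gmap: GeneticMap,
    params: MeiosisParams,
    rng: np.random.Generator,
    alloc: IdAllocator | None = None,
) -> DiploidPopulation:
    """Burn a population of ``n_ind`` individuals for ``n_gen`` generations.

    Starts from exactly equifrequent alleles.  The returned population
    carries its allele-frequency spectrum in ``freq_spectrum``.
    """
    if n_ind < 2 or n_gen < 0:
        raise ValueError("n_ind must be >= 2 and n_gen >= 0")
    alloc = alloc or IdAllocator()
    ids = alloc.take(n_ind)
    pop = DiploidPopulation(
        ids, np.full(n_ind, -1), np.full(n_ind, -1),
        _initial_haplotypes(n_ind, gmap.n_loci, rng),
    )
    for _ in range(n_gen):
        pop = random_mating_generation(pop, gmap, params, rng, alloc)
    pop.freq_spectrum = pop.allele_freq()
    return pop


def n_segregating(pop: DiploidPopulation) -> int:
    """Number of loci with both alleles present."""
    f = pop.allele_freq()
    return int(np.sum((f > 0) & (f < 1)))
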