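"""Stylized breeding-population history.

Turns the equilibrium base population into two calibrated heterotic founder
populations mirroring the known history of the Deli (Asian) and La Me
(African) oil-palm breeding populations: 100 generations of divergent
natural selection (bunch weight in A, bunch number in B), founder
bottlenecks (4 and 19 individuals), expansion with mass selection on the
bunch-production phenotype product, and two cycles of pedigree-era
reciprocal recurrent selection emulated through pseudo progeny tests.

Replicates are accepted only when their genetic parameters (Fst, additive
variances, genetic correlations, inbreeding, LD-profile shape, maximum
single-QTL variance share) fall inside configurable windows around the
published calibration values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import (
    DiploidPopulation,
    GeneticMap,
    IdAllocator,
    MeiosisParams,
    meiose_many,
)
from .relationship import PedigreeTable, pedigree_inbreeding
from .traits import (
    QTLArchitecture,
    TraitParams,
    qtl_variance_shares,
    residual_and_phenotype,
    true_breeding_values,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HistoryConfig",
    "CalibrationTargets",
    "PedigreeRecorder",
    "FounderSet",
    "divergence_phase",
    "mass_select",
    "pseudo_progeny_test",
    "pre_rrs_cycle",
    "build_founders",
    "founder_statistics",
    "accept_replicate",
]

DELI, LAME = "Deli", "LaMe"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HistoryConfig:
    """Schedule of the population-history phases (defaults = study values)."""

    divergence_generations: int = 100
    divergence_size: int = 100
    deli_founders: int = 4
    deli_random_sizes: tuple[int, ...] = (25, 25, 25)
    deli_expansion_sizes: tuple[int, ...] = (50, 50, 60, 75, 100, 150)
    deli_retain: float = 0.70
    lame_founders: int = 19
    lame_expansion_sizes: tuple[int, ...] = (75, 150)
    lame_retain: float = 0.30
    pre_rrs_accuracies: tuple[float, ...] = (0.8, 0.9)
    n_selected: int = 20
    diallel_fraction: float = 0.8
    generation0_size: int = 300
    pedigree_depth: dict = field(
        default_factory=lambda: {DELI: 4, LAME: 2}
    )

    def __post_init__(self) -> None:
        for frac in (self.deli_retain, self.lame_retain, self.diallel_fraction):
            if not 0.0 < frac <= 1.0:
                raise ValueError("fractions must be in (0, 1]")
        if min(self.deli_expansion_sizes + self.lame_expansion_sizes) <= 0:
            raise ValueError("sizes must be positive")


# ---------------------------------------------------------------------------
# Pedigree bookkeeping (records start at the bottleneck founders)
# ---------------------------------------------------------------------------

class PedigreeRecorder:
    """Append-only pedigree; insertion order is topological by construction."""

    def __init__(self) -> None:
        self.ids: list[int] = []
        self.sire: list[int] = []
        self.dam: list[int] = []
        self.label: list[str] = []
        self._known: set[int] = set()

    def add(self, ids, sire, dam, label: str) -> None:
        for i, s, d in zip(np.asarray(ids), np.asarray(sire), np.asarray(dam)):
            i, s, d = int(i), int(s), int(d)
            if i in self._known:
                raise ValueError(f"duplicate pedigree id {i}")
            s = s if s in self._known else -1
            d = d if d in self._known else -1
            self.ids.append(i)
            self.sire.append(s)
            self.dam.append(d)
            self.label.append(label)
            self._known.add(i)

    def add_founders(self, ids, label: str) -> None:
        n = np.asarray(ids).size
        self.add(ids, np.full(n, -1), np.full(n, -1), label)

    def table(self) -> PedigreeTable:
        return PedigreeTable(
            np.array(self.ids), np.array(self.sire), np.array(self.dam)
        )

    def trimmed_table(self, target_ids: np.ndarray, depth: int) -> PedigreeTable:
        """Pedigree of ``target_ids`` with at most ``depth`` ancestor
        generations; deeper ancestry is truncated to unknown parents."""
        parent = {
            i: (s, d) for i, s, d in zip(self.ids, self.sire, self.dam)
        }
        keep_depth: dict[int, int] = {}
        frontier = {int(i): 0 for i in np.asarray(target_ids)}
        while frontier:
            nxt: dict[int, int] = {}
            for i, lvl in frontier.items():
                if i in keep_depth and keep_depth[i] <= lvl:
                    continue
                keep_depth[i] = lvl
                if lvl < depth:
                    for par in parent.get(i, (-1, -1)):
                        if par >= 0:
                            nxt[par] = min(nxt.get(par, lvl + 1), lvl + 1)
            frontier = nxt
        order = [i for i in self.ids if i in keep_depth]
        sire, dam = [], []
        for i in order:
            s, d = parent[i]
            if keep_depth[i] >= depth:
                s, d = -1, -1
            sire.append(s if s in keep_depth and keep_depth[i] < depth else -1)
            dam.append(d if d in keep_depth and keep_depth[i] < depth else -1)
        return PedigreeTable(np.array(order), np.array(sire), np.array(dam))

    def mean_inbreeding(self, ids: np.ndarray) -> float:
        # Restrict to the ancestor closure of the requested ids so the dense
        # tabular computation never has to include unrelated cohorts.
        table = self.trimmed_table(np.asarray(ids), depth=10**6)
        F = pedigree_inbreeding(table)
        pos = table.positions(np.asarray(ids))
        return float(F[pos].mean())


# ---------------------------------------------------------------------------
# Phases
# ---------------------------------------------------------------------------

def _weighted_matings(
    n_offspring: int,
    weights: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_offspring, 2) parent indices: sire ~ weights, dam ~ weights
    excluding the sire (no selfing)."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        logger.warning("all sampling weights non-positive; falling back to uniform")
        w = np.ones_like(w)
    p = w / w.sum()
    sires = rng.choice(w.size, size=n_offspring, p=p)
    dams = np.empty(n_offspring, dtype=np.int64)
    for k, s in enumerate(sires):
        w2 = p.copy()
        w2[s] = 0.0
        tot = w2.sum()
        if tot <= 0:
            choices = np.flatnonzero(np.arange(w.size) != s)
            dams[k] = rng.choice(choices)
        else:
            dams[k] = rng.choice(w.size, p=w2 / tot)
    return np.stack([sires, dams], axis=1)


def _offspring(
    pop: DiploidPopulation,
    matings: np.ndarray,
    gmap: GeneticMap,
    mparams: MeiosisParams,
    rng: np.random.Generator,
    alloc: IdAllocator,
    label: str,
    recorder: PedigreeRecorder | None = None,
) -> DiploidPopulation:
    g1 = meiose_many(pop.haplotypes, matings[:, 0], gmap, mparams, rng)
    g2 = meiose_many(pop.haplotypes, matings[:, 1], gmap, mparams, rng)
    ids = alloc.take(matings.shape[0])
    out = DiploidPopulation(
        ids,
        pop.ids[matings[:, 0]],
        pop.ids[matings[:, 1]],
        np.stack([g1, g2], axis=1),
        pop.generation + 1,
        label,
    )
    if recorder is not None:
        recorder.add(out.ids, out.sire, out.dam, label)
    return out


def divergence_phase(
    base_pop: DiploidPopulation,
    arch: QTLArchitecture,
    trait_params: TraitParams,
    base_freqs: np.ndarray,
    gmap: GeneticMap,
    mparams: MeiosisParams,
    rng: np.random.Generator,
    alloc: IdAllocator,
    n_gen: int = 100,
    size: int = 100,
) -> tuple[DiploidPopulation, DiploidPopulation]:
    """Split the base population and apply divergent fitness-proportional
    selection: bunch weight in population A, bunch number in population B.

    Parents are sampled with probability proportional to max(phenotype, 0)
    of the focal trait; random mating without selfing.
    """
    if base_pop.size < 2 * size:
        raise ValueError("base population too small to split")
    perm = rng.permutation(base_pop.size)
    pops = [base_pop.subset(perm[:size]), base_pop.subset(perm[size : 2 * size])]
    pops[0].label, pops[1].label = "A", "B"
    focal = {0: 0, 1: 1}  # population A -> BW column, B -> BN column
    for g in range(n_gen):
        for k in (0, 1):
            tbv = true_breeding_values(pops[k].haplotypes, arch, base_freqs)
            pheno = residual_and_phenotype(tbv, trait_params, rng)
            weights = np.clip(pheno[:, focal[k]], 0.0, None)
            matings = _weighted_matings(size, weights, rng)
            pops[k] = _offspring(
                pops[k], matings, gmap, mparams, rng, alloc, pops[k].label
            )
    return pops[0], pops[1]


def mass_select(
    phenotypes: np.ndarray, retain_frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices of the ceil(frac*N) individuals with the highest bunch
    production (BW x BN phenotype product); ties broken by the RNG."""
    if not 0.0 < retain_frac <= 1.0:
        raise ValueError("retain_frac must be in (0, 1]")
    pheno = np.asarray(phenotypes, dtype=float)
    if pheno.size == 0:
        raise ValueError("empty population")
    product = pheno[:, 0] * pheno[:, 1]
    n_keep = int(np.ceil(retain_frac * product.size))
    order = np.lexsort((rng.random(product.size), -product))
    return np.sort(order[:n_keep])


def pseudo_progeny_test(
    tbv: np.ndarray, target_r: float, rng: np.random.Generator
) -> np.ndarray:
    """EBV correlated with TBV at ``target_r``, rescaled to the TBV moments.

    Emulates the accuracy of a historical progeny test without simulating
    it: EBV = mean + sd * (r z + sqrt(1-r^2) eps) with z the standardized
    TBV and eps independent standard normal.
    """
    if abs(target_r) > 1:
        raise ValueError("|target_r| must be <= 1")
    tbv = np.asarray(tbv, dtype=float)
    sd = tbv.std()
    noise = rng.normal(size=tbv.shape)
    if sd == 0:
        logger.warning("zero-variance TBV in pseudo progeny test; returning noise")
        return noise
    z = (tbv - tbv.mean()) / sd
    return tbv.mean() + sd * (target_r * z + np.sqrt(1 - target_r**2) * noise)


def _random_mating_sizes(
    pop: DiploidPopulation,
    sizes: tuple[int, ...],
    gmap: GeneticMap,
    mparams: MeiosisParams,
    rng: np.random.Generator,
    alloc: IdAllocator,
    label: str,
    recorder: PedigreeRecorder,
) -> DiploidPopulation:
    for n in sizes:
        matings = _weighted_matings(n, np.ones(pop.size), rng)
        pop = _offspring(pop, matings, gmap, mparams, rng, alloc, label, recorder)
    return pop


def _mass_selection_phase(
    pop: DiploidPopulation,
    sizes: tuple[int, ...],
    retain: float,
    arch: QTLArchitecture,
    trait_params: TraitParams,
    base_freqs: np.ndarray,
    gmap: GeneticMap,
    mparams: MeiosisParams,
    rng: np.random.Generator,
    alloc: IdAllocator,
    label: str,
    recorder: PedigreeRecorder,
) -> DiploidPopulation:
    for n in sizes:
        tbv = true_breeding_values(pop.haplotypes, arch, base_freqs)
        pheno = residual_and_phenotype(tbv, trait_params, rng)
        keep = mass_select(pheno, retain, rng)
        selected = pop.subset(keep)
        matings = _weighted_matings(n, np.ones(selected.size), rng)
        pop = _offspring(selected, matings, gmap, mparams, rng, alloc, label, recorder)
    return pop


def pre_rrs_cycle(
    deli: DiploidPopulation,
    lame: DiploidPopulation,
    arch: QTLArchitecture,
    trait_params: TraitParams,
    base_freqs: np.ndarray,
    target_r: float,
    gmap: GeneticMap,
    mparams: MeiosisParams,
    rng: np.random.Generator,
    alloc: IdAllocator,
    recorder: PedigreeRecorder,
    n_selected: int = 20,
    diallel_fraction: float = 0.8,
    n_offspring: int = 300,
) -> tuple[DiploidPopulation, DiploidPopulation]:
    """One pedigree-era reciprocal-recurrent-selection cycle.

    EBV come from a pseudo progeny test of the stated accuracy; the top
    ``n_selected`` per population (ranked by expected hybrid bunch
    production of their crosses) mate in an 80% half diallel with selfing,
    producing ``n_offspring`` individuals per population.
    """
    from .schemes import make_within_pop_matings, select_parents

    ebv = {}
    for pop in (deli, lame):
        tbv = true_breeding_values(pop.haplotypes, arch, base_freqs)
        ebv[pop.label] = np.stack(
            [pseudo_progeny_test(tbv[:, t], target_r, rng) for t in range(2)],
            axis=1,
        )
    means = np.array([trait_params.mean_bw, trait_params.mean_bn])
    sel_d, sel_l = select_parents(
        0.5 * ebv[deli.label], 0.5 * ebv[lame.label], means, n_selected, rng
    )
    out = []
    for pop, sel in ((deli, sel_d), (lame, sel_l)):
        selected = pop.subset(sel)
        plan = make_within_pop_matings(
            selected.size, diallel_fraction, n_offspring, rng
        )
        matings = np.repeat(plan[:, :2], plan[:, 2], axis=0)
        out.append(
            _offspring(selected, matings, gmap, mparams, rng, alloc, pop.label, recorder)
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Founder construction
# ---------------------------------------------------------------------------

@dataclass
class FounderSet:
    """Generation-0 breeding populations plus the shared simulation state."""

    deli: DiploidPopulation
    lame: DiploidPopulation
    arch: QTLArchitecture
    trait_params: TraitParams
    base_freqs: np.ndarray
    gmap: GeneticMap
    meiosis: MeiosisParams
    recorder: PedigreeRecorder
    alloc: IdAllocator
    config: HistoryConfig

    def tbv(self, pop: DiploidPopulation) -> np.ndarray:
        return true_breeding_values(pop.haplotypes, self.arch, self.base_freqs)


def build_founders(
    base_pop: DiploidPopulation,
    arch: QTLArchitecture,
    trait_params: TraitParams,
    gmap: GeneticMap,
    mparams: MeiosisParams,
    rng: np.random.Generator,
    config: HistoryConfig | None = None,
) -> FounderSet:
    """Run the full history: divergence, bottlenecks, expansion with mass
    selection, and two pseudo-progeny-test RRS cycles, ending with two
    generation-0 populations of ``config.generation0_size`` individuals."""
    config = config or HistoryConfig()
    alloc = IdAllocator(int(base_pop.ids.max()) + 1)
    base_freqs = base_pop.allele_freq()
    recorder = PedigreeRecorder()

    popA, popB = divergence_phase(
        base_pop, arch, trait_params, base_freqs, gmap, mparams, rng, alloc,
        config.divergence_generations, config.divergence_size,
    )

    # Bottlenecks: founders are recorded with unknown parents, so reported
    # inbreeding is relative to the bottleneck.
    deli = popA.subset(rng.choice(popA.size, config.deli_founders, replace=False))
    deli.label = DELI
    recorder.add_founders(deli.ids, DELI)
    lame = popB.subset(rng.choice(popB.size, config.lame_founders, replace=False))
    lame.label = LAME
    recorder.add_founders(lame.ids, LAME)

    deli = _random_mating_sizes(
        deli, config.deli_random_sizes, gmap, mparams, rng, alloc, DELI, recorder
    )
    deli = _mass_selection_phase(
        deli, config.deli_expansion_sizes, config.deli_retain, arch, trait_params,
        base_freqs, gmap, mparams, rng, alloc, DELI, recorder,
    )
    lame = _mass_selection_phase(
        lame, config.lame_expansion_sizes, config.lame_retain, arch, trait_params,
        base_freqs, gmap, mparams, rng, alloc, LAME, recorder,
    )

    for r_cycle in config.pre_rrs_accuracies:
        deli, lame = pre_rrs_cycle(
            deli, lame, arch, trait_params, base_freqs, r_cycle, gmap, mparams,
            rng, alloc, recorder, config.n_selected, config.diallel_fraction,
            config.generation0_size,
        )
    return FounderSet(
        deli, lame, arch, trait_params, base_freqs, gmap, mparams,
        recorder, alloc, config,
    )


# ---------------------------------------------------------------------------
# Calibration statistics and the replicate filter
# ---------------------------------------------------------------------------

def founder_statistics(founders: FounderSet, ld: bool = True) -> dict:
    """Genetic parameters of the generation-0 populations used for the
    replicate acceptance filter and for reporting."""
    from .stats import ld_decay_distance, wc_fst
    from .traits import additive_variance

    out: dict = {}
    d_dos = founders.deli.dosages()
    l_dos = founders.lame.dosages()
    out["fst"] = wc_fst(d_dos, l_dos)
    resid = founders.trait_params.resid_var
    for pop, name in ((founders.deli, DELI), (founders.lame, LAME)):
        freqs = pop.allele_freq()
        tbv = founders.tbv(pop)
        out[f"rg_{name}"] = float(np.corrcoef(tbv[:, 0], tbv[:, 1])[0, 1])
        for t, trait in enumerate(("BW", "BN")):
            va = additive_variance(freqs, founders.arch, trait)
            out[f"va_{name}_{trait}"] = va
            out[f"h2_{name}_{trait}"] = va / (va + resid[trait])
            shares = qtl_variance_shares(freqs, founders.arch, trait)
            tot = shares.sum()
            share_key = f"max_qtl_share_{name}_{trait}"
            out[share_key] = float(shares.max() / tot) if tot > 0 else 0.0
        out[f"F_{name}"] = founders.recorder.mean_inbreeding(pop.ids)
    out["max_qtl_share"] = max(
        v for k, v in out.items() if k.startswith("max_qtl_share_")
    )
    if ld:
        rng = np.random.default_rng(0)
        for pop, name in ((founders.deli, DELI), (founders.lame, LAME)):
            dist, curve = ld_decay_distance(
                pop.haplotypes, founders.gmap, rng=rng, max_pairs=50_000
            )
            out[f"ld_decay_cm_{name}"] = dist
            out[f"ld_short_r2_{name}"] = float(
                curve.loc[curve["distance_cm"] <= 10.0, "r2"].mean()
            )
    return out


#: Calibration values (mean, SD over five replicates) per architecture cell,
#: keyed by (n_qtl, p_pleio).  Additive variances are on the intrapopulation
#: scale.  Used to build default +/-2 SD acceptance windows.
PUBLISHED_CALIBRATION: dict[tuple[int, float], dict[str, tuple[float, float]]] = {
    (100, 0.60): {
        "fst": (0.49, 0.01), "rg_Deli": (-0.69, 0.07), "rg_LaMe": (-0.73, 0.04),
        "va_Deli_BN": (1.55, 0.22), "va_Deli_BW": (0.76, 0.15),
        "va_LaMe_BN": (2.00, 0.37), "va_LaMe_BW": (1.16, 0.20),
        "F_Deli": (0.26, 0.00), "F_LaMe": (0.14, 0.01),
    },
    (100, 0.75): {
        "fst": (0.48, 0.03), "rg_Deli": (-0.75, 0.07), "rg_LaMe": (-0.73, 0.10),
        "va_Deli_BN": (1.86, 0.63), "va_Deli_BW": (0.98, 0.38),
        "va_LaMe_BN": (1.82, 0.28), "va_LaMe_BW": (1.04, 0.22),
        "F_Deli": (0.26, 0.00), "F_LaMe": (0.13, 0.01),
    },
    (100, 0.90): {
        "fst": (0.47, 0.02), "rg_Deli": (-0.90, 0.02), "rg_LaMe": (-0.86, 0.03),
        "va_Deli_BN": (1.78, 0.24), "va_Deli_BW": (0.87, 0.15),
        "va_LaMe_BN": (2.12, 0.50), "va_LaMe_BW": (1.06, 0.20),
        "F_Deli": (0.25, 0.01), "F_LaMe": (0.13, 0.00),
    },
    (500, 0.60): {
        "fst": (0.47, 0.03), "rg_Deli": (-0.64, 0.05), "rg_LaMe": (-0.68, 0.03),
        "va_Deli_BN": (1.94, 0.13), "va_Deli_BW": (0.91, 0.16),
        "va_LaMe_BN": (2.27, 0.14), "va_LaMe_BW": (1.21, 0.03),
        "F_Deli": (0.26, 0.01), "F_LaMe": (0.13, 0.01),
    },
    (500, 0.75): {
        "fst": (0.47, 0.01), "rg_Deli": (-0.79, 0.05), "rg_LaMe": (-0.73, 0.03),
        "va_Deli_BN": (1.99, 0.14), "va_Deli_BW": (0.94, 0.08),
        "va_LaMe_BN": (2.27, 0.09), "va_LaMe_BW": (1.11, 0.07),
        "F_Deli": (0.26, 0.01), "F_LaMe": (0.14, 0.01),
    },
    (500, 0.90): {
        "fst": (0.48, 0.02), "rg_Deli": (-0.83, 0.03), "rg_LaMe": (-0.86, 0.04),
        "va_Deli_BN": (2.03, 0.42), "va_Deli_BW": (1.00, 0.21),
        "va_LaMe_BN": (2.27, 0.30), "va_LaMe_BW": (1.15, 0.13),
        "F_Deli": (0.25, 0.00), "F_LaMe": (0.13, 0.00),
    },
    (1000, 0.60): {
        "fst": (0.49, 0.02), "rg_Deli": (-0.64, 0.08), "rg_LaMe": (-0.66, 0.01),
        "va_Deli_BN": (1.94, 0.10), "va_Deli_BW": (0.96, 0.05),
        "va_LaMe_BN": (2.20, 0.06), "va_LaMe_BW": (1.14, 0.08),
        "F_Deli": (0.26, 0.00), "F_LaMe": (0.14, 0.00),
    },
    (1000, 0.75): {
        "fst": (0.48, 0.01), "rg_Deli": (-0.75, 0.07), "rg_LaMe": (-0.71, 0.05),
        "va_Deli_BN": (1.99, 0.13), "va_Deli_BW": (0.99, 0.06),
        "va_LaMe_BN": (2.11, 0.19), "va_LaMe_BW": (1.08, 0.10),
        "F_Deli": (0.25, 0.01), "F_LaMe": (0.14, 0.01),
    },
    (1000, 0.90): {
        "fst": (0.47, 0.03), "rg_Deli": (-0.84, 0.04), "rg_LaMe": (-0.81, 0.03),
        "va_Deli_BN": (1.97, 0.18), "va_Deli_BW": (0.93, 0.05),
        "va_LaMe_BN": (2.36, 0.15), "va_LaMe_BW": (1.16, 0.06),
        "F_Deli": (0.26, 0.01), "F_LaMe": (0.13, 0.01),
    },
}


@dataclass
class CalibrationTargets:
    """Acceptance windows for the replicate filter.

    ``windows`` maps statistic name -> (low, high); ``max_qtl_share`` is the
    single-QTL additive-variance share ceiling; the LD rule requires higher
    short-range LD in Deli than in La Me.
    """

    windows: dict[str, tuple[float, float]]
    max_qtl_share: float = 0.20
    require_ld_shape: bool = True

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.windows.items():
            if hi <= lo:
                raise ValueError(f"empty window for {name}")

    @classmethod
    def from_published(
        cls,
        n_qtl: int,
        p_pleio: float,
        n_sd: float = 2.0,
        sd_floor: float = 0.02,
        statistics: tuple[str, ...] | None = None,
        **kwargs,
    ) -> "CalibrationTargets":
        """Windows of +/- ``n_sd`` (pooled) SD around the published means of
        the matching architecture cell; SDs are floored to keep windows with
        a zero reported SD non-degenerate."""
        key = (int(n_qtl), round(float(p_pleio), 2))
        if key not in PUBLISHED_CALIBRATION:
            raise KeyError(f"no published calibration for cell {key}")
        cell = PUBLISHED_CALIBRATION[key]
        names = statistics or tuple(cell)
        windows = {}
        for name in names:
            mean, sd = cell[name]
            half = n_sd * max(sd, sd_floor)
            windows[name] = (mean - half, mean + half)
        return cls(windows=windows, **kwargs)


def accept_replicate(
    stats: dict, targets: CalibrationTargets
) -> tuple[bool, list[str]]:
    """Check founder statistics against the calibration windows.

    Returns (accepted, reasons); reasons list every violated criterion.
    """
    reasons = []
    if stats.get("max_qtl_share", 0.0) > targets.max_qtl_share:
        reasons.append(
            f"QTL share {stats['max_qtl_share']:.3f} > {targets.max_qtl_share:.2f}"
        )
    for name, (lo, hi) in targets.windows.items():
        v = stats.get(name)
        if v is None or not np.isfinite(v):
            reasons.append(f"{name} missing")
        elif not lo <= v <= hi:
            reasons.append(f"{name} = {v:.3f} outside [{lo:.3f}, {hi:.3f}]")
    if targets.require_ld_shape and "ld_short_r2_Deli" in stats:
        if not stats["ld_short_r2_Deli"] > stats["ld_short_r2_LaMe"]:
            reasons.append("short-range LD not higher in Deli than in La Me")
    return (len(reasons) == 0, reasons)
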