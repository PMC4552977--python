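"""Four-cycle breeding-scheme engine.

Compares conventional reciprocal recurrent selection (RRS) with two
reciprocal recurrent genomic selection strategies over four selection
cycles:

* RRS — progeny test every cycle (pattern GGGG), EBV from a bivariate
  pedigree-based GCA model, candidates limited to the 120 tested parents.
* RRGS_PAR — the same two-kernel GCA model with population-specific genomic
  matrices computed from parental genotypes.
* RRGS_HYB — a single-step model where parents and (partly genotyped)
  hybrids share one breeding-value vector with covariance H, the genomic
  part built from an origin-aware multiallelic G.

Progeny tests (calibration generations, "G") take 20 years; marker-only
generations ("M") reuse the last calibration's phenotype records, extend
the relationship matrices with the new candidates' genotypes, and take 6
years.  Selection picks the parents giving crosses with the highest
expected bunch production.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import DiploidPopulation, GeneticMap, meiose_many
from .history import DELI, LAME, FounderSet
from .mixed_models import (
    BLUPSolution,
    VarComps,
    predict_cross_value,
    solve_gca_bivariate,
    solve_ssgblup_bivariate,
)
from .relationship import (
    PedigreeTable,
    a_inverse,
    h_inverse,
    origin_aware_G,
    pedigree_A,
    vanraden_G,
)
from .stats import GenerationRecord, RunSummary, selection_accuracy, summarize_run
from .traits import TRAITS, additive_variance, residual_and_phenotype

logger = logging.getLogger(__name__)

__all__ = [
    "SchemeConfig",
    "scheme_years",
    "design_progeny_test",
    "select_parents",
    "make_within_pop_matings",
    "select_snp_panel",
    "measure_hybrid_production",
    "run_scheme",
]

STRATEGIES = ("RRS", "RRGS_PAR", "RRGS_HYB")
PATTERNS = ("GGGG", "GMGM", "GMMM")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SchemeConfig:
    """One cell of the scheme grid (defaults = the conventional design)."""

    strategy: str = "RRS"
    pattern: str = "GGGG"
    n_candidates: int = 120
    n_genotyped_hybrids: int = 0
    n_selected: int = 20
    diallel_fraction: float = 0.8
    n_progeny_tested: int = 120
    n_test_crosses: int = 300
    n_offspring_per_cross: int = 45
    panel_size: int = 2500
    panel_maf_min: float = 0.04
    years_progeny_test: float = 20.0
    years_marker_only: float = 6.0
    blend_weight: float = 0.99

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy}")
        if set(self.pattern) - {"G", "M"} or self.pattern[0] != "G":
            raise ValueError("pattern must be G/M letters starting with G")
        if self.strategy == "RRS":
            if self.pattern != "G" * len(self.pattern):
                raise ValueError("RRS requires progeny tests every generation")
            if self.n_candidates != self.n_progeny_tested:
                raise ValueError("RRS candidates are the progeny-tested set")
            if self.n_genotyped_hybrids:
                raise ValueError("RRS does not genotype hybrids")
        if self.strategy == "RRGS_HYB" and self.n_genotyped_hybrids <= 0:
            raise ValueError("RRGS_HYB requires genotyped hybrids")
        if self.n_candidates < self.n_selected:
            raise ValueError("fewer candidates than selected parents")

    @property
    def n_cycles(self) -> int:
        return len(self.pattern)

    def years_per_cycle(self) -> list[float]:
        return [
            self.years_progeny_test if c == "G" else self.years_marker_only
            for c in self.pattern
        ]


def scheme_years(pattern: str, years_g: float = 20.0, years_m: float = 6.0) -> float:
    """Total years for a calibration pattern (GGGG=80, GMGM=52, GMMM=38)."""
    if set(pattern) - {"G", "M"}:
        raise ValueError("pattern must consist of G/M letters")
    return sum(years_g if c == "G" else years_m for c in pattern)


# ---------------------------------------------------------------------------
# Design primitives
# ---------------------------------------------------------------------------

def _balanced_usage(n_items: int, total: int, rng: np.random.Generator) -> np.ndarray:
    """Per-item usage counts differing by at most one, summing to total."""
    base, extra = divmod(total, n_items)
    counts = np.full(n_items, base, dtype=np.int64)
    if extra:
        counts[rng.choice(n_items, size=extra, replace=False)] += 1
    return counts


def design_progeny_test(
    n_parents1: int,
    n_parents2: int,
    n_crosses: int,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> np.ndarray:
    """Incomplete factorial progeny-test design: distinct interpopulation
    pairs with per-parent usage counts as balanced as possible.

    Returns (n_crosses, 2) parent indices.  With 120 + 120 parents and 300
    crosses each parent is used two or three times (2.5 on average).
    """
    if n_crosses > n_parents1 * n_parents2:
        raise ValueError("more crosses than distinct pairs")
    if min(n_parents1, n_parents2) < 1:
        raise ValueError("both parent sets must be non-empty")
    for _ in range(max_tries):
        u1 = np.repeat(np.arange(n_parents1), _balanced_usage(n_parents1, n_crosses, rng))
        u2 = np.repeat(np.arange(n_parents2), _balanced_usage(n_parents2, n_crosses, rng))
        rng.shuffle(u1)
        rng.shuffle(u2)
        pairs = np.stack([u1, u2], axis=1)
        # Repair duplicate pairs by swapping second-population slots.
        for _ in range(50):
            _, first = np.unique(pairs[:, 0] * n_parents2 + pairs[:, 1], return_index=True)
            dup = np.setdiff1d(np.arange(n_crosses), first)
            if dup.size == 0:
                return pairs
            for i in dup:
                j = rng.integers(0, n_crosses)
                pairs[[i, j], 1] = pairs[[j, i], 1]
    raise RuntimeError("could not build a duplicate-free balanced design")


def select_parents(
    gca1: np.ndarray,
    gca2: np.ndarray,
    means: np.ndarray,
    n_selected: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Top candidates per population by expected hybrid bunch production.

    Each candidate is scored by the cross value of its pairing with the
    opposite population's mean candidate (``predict_cross_value``); ties
    are broken by the RNG.  ``gca*`` are (n, 2) per-candidate transmitted
    effects on the (BW, BN) scale.
    """
    gca1 = np.asarray(gca1, dtype=float)
    gca2 = np.asarray(gca2, dtype=float)
    if min(gca1.shape[0], gca2.shape[0]) < n_selected:
        raise ValueError("fewer candidates than n_selected")
    out = []
    for own, other in ((gca1, gca2), (gca2, gca1)):
        opp_mean = other.mean(axis=0)
        scores = predict_cross_value(own, np.tile(opp_mean, (own.shape[0], 1)), means)
        scores = np.atleast_1d(scores)
        order = np.lexsort((rng.random(own.shape[0]), -scores))
        out.append(np.sort(order[:n_selected]))
    return out[0], out[1]


def make_within_pop_matings(
    n_parents: int,
    fraction: float,
    n_offspring_total: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Within-population mating plan from a half diallel with selfing.

    floor(fraction * n(n+1)/2) distinct crosses are retained, dropping
    crosses from over-used parents first so per-parent cross counts stay as
    equal as possible; offspring are spread uniformly (counts differ by at
    most one, 0/1 when offspring are fewer than crosses).

    Returns (n_crosses, 3) rows of (parent_a, parent_b, n_offspring), with
    rows where n_offspring = 0 removed.
    """
    if n_parents < 1 or not 0.0 < fraction <= 1.0:
        raise ValueError("invalid parent count or fraction")
    iu = np.triu_indices(n_parents)
    pairs = np.stack([iu[0], iu[1]], axis=1)
    target = int(np.floor(fraction * pairs.shape[0]))
    order = rng.permutation(pairs.shape[0])
    pairs = pairs[order]
    usage = np.bincount(pairs.ravel(), minlength=n_parents)
    keep = np.ones(pairs.shape[0], dtype=bool)
    for _ in range(pairs.shape[0] - target):
        load = usage[pairs[:, 0]] + usage[pairs[:, 1]]
        load = np.where(keep, load, -1)
        best = np.flatnonzero(load == load.max())
        drop = rng.choice(best)
        keep[drop] = False
        usage[pairs[drop, 0]] -= 1
        usage[pairs[drop, 1]] -= 1
    pairs = pairs[keep]
    n_crosses = pairs.shape[0]
    base, extra = divmod(n_offspring_total, n_crosses)
    n_off = np.full(n_crosses, base, dtype=np.int64)
    if extra:
        # Prefer topping up crosses whose parents currently carry the fewest
        # offspring, with random tie-breaks.
        off_load = np.zeros(n_parents)
        order = rng.permutation(n_crosses)
        chosen = []
        for _ in range(extra):
            load = off_load[pairs[order, 0]] + off_load[pairs[order, 1]]
            load[np.isin(order, chosen)] = np.inf
            k = order[int(np.argmin(load))]
            chosen.append(k)
            n_off[k] += 1
            off_load[pairs[k, 0]] += 1
            off_load[pairs[k, 1]] += 1
    out = np.concatenate([pairs, n_off[:, None]], axis=1)
    return out[out[:, 2] > 0]


def select_snp_panel(
    dosages: np.ndarray,
    maf_min: float,
    n_panel: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random marker panel among loci passing the MAF filter.

    Falls back (with a warning) to all eligible loci when fewer than
    ``n_panel`` pass; raises when no locus is polymorphic enough.
    """
    f = np.asarray(dosages, dtype=float).mean(axis=0) / 2.0
    maf = np.minimum(f, 1.0 - f)
    eligible = np.flatnonzero(maf > maf_min)
    if eligible.size == 0:
        raise ValueError("no locus passes the MAF filter")
    if eligible.size < n_panel:
        logger.warning(
            "only %d loci pass MAF > %.3f (requested %d); using all",
            eligible.size, maf_min, n_panel,
        )
        return np.sort(eligible)
    return np.sort(rng.choice(eligible, size=n_panel, replace=False))


def measure_hybrid_production(
    tbv1: np.ndarray,
    tbv2: np.ndarray,
    means: np.ndarray,
    pairs: np.ndarray | None = None,
) -> float:
    """Mean true expected bunch production over interpopulation crosses.

    Cross (i, j) contributes (m_BW + (t1_BW + t2_BW)/2) * (m_BN + ...);
    ``pairs`` defaults to the full factorial of the two parent sets.
    """
    tbv1 = np.atleast_2d(np.asarray(tbv1, dtype=float))
    tbv2 = np.atleast_2d(np.asarray(tbv2, dtype=float))
    means = np.asarray(means, dtype=float)
    if pairs is None:
        i, j = np.meshgrid(np.arange(tbv1.shape[0]), np.arange(tbv2.shape[0]))
        pairs = np.stack([i.ravel(), j.ravel()], axis=1)
    bw = means[0] + 0.5 * (tbv1[pairs[:, 0], 0] + tbv2[pairs[:, 1], 0])
    bn = means[1] + 0.5 * (tbv1[pairs[:, 0], 1] + tbv2[pairs[:, 1], 1])
    return float(np.mean(bw * bn))


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

class _ModelPedigree:
    """Growing pedigree rooted at the generation-0 retained ancestry.

    The mixed models see only the pedigree retained at generation 0 (four
    ancestor generations in Deli, two in La Me) plus everything bred since.
    """

    def __init__(self, founders: FounderSet) -> None:
        ids, sire, dam = [], [], []
        for pop, depth_key in ((founders.deli, DELI), (founders.lame, LAME)):
            depth = founders.config.pedigree_depth[depth_key]
            t = founders.recorder.trimmed_table(pop.ids, depth)
            ids.extend(t.ids.tolist())
            sire.extend(t.sire.tolist())
            dam.extend(t.dam.tolist())
        self.ids, self.sire, self.dam = ids, sire, dam
        self._known = set(ids)

    def add(self, ids, sire, dam) -> None:
        for i, s, d in zip(np.asarray(ids), np.asarray(sire), np.asarray(dam)):
            self.ids.append(int(i))
            self.sire.append(int(s) if int(s) in self._known else -1)
            self.dam.append(int(d) if int(d) in self._known else -1)
            self._known.add(int(i))

    def table(self) -> PedigreeTable:
        return PedigreeTable(
            np.array(self.ids), np.array(self.sire), np.array(self.dam)
        )

    def subtable(self, needed_ids: np.ndarray) -> PedigreeTable:
        """Ancestor closure of ``needed_ids`` (keeps dense A tractable)."""
        parent = {i: (s, d) for i, s, d in zip(self.ids, self.sire, self.dam)}
        keep: set[int] = set()
        stack = [int(i) for i in np.asarray(needed_ids)]
        while stack:
            i = stack.pop()
            if i in keep:
                continue
            keep.add(i)
            for par in parent.get(i, (-1, -1)):
                if par >= 0:
                    stack.append(par)
        order = [i for i in self.ids if i in keep]
        sire = [parent[i][0] if parent[i][0] in keep else -1 for i in order]
        dam = [parent[i][1] if parent[i][1] in keep else -1 for i in order]
        return PedigreeTable(np.array(order), np.array(sire), np.array(dam))


@dataclass
class _Calibration:
    """State stored at a progeny-test generation and reused in marker-only
    generations."""

    y: np.ndarray  # (n_records, 2) hybrid phenotypes
    deli_link: np.ndarray  # record -> position among calibration Deli candidates
    lame_link: np.ndarray
    varcomps: VarComps
    means: np.ndarray
    panel: np.ndarray  # panel locus indices (genome coordinates)
    deli_panel_dosage: np.ndarray | None = None
    lame_panel_dosage: np.ndarray | None = None
    hybrid_gametotypes: np.ndarray | None = None  # genotyped hybrids, panel loci
    hybrid_ids: np.ndarray | None = None  # all phenotyped hybrid ids
    genotyped_hybrid_ids: np.ndarray | None = None
    deli_ids: np.ndarray | None = None
    lame_ids: np.ndarray | None = None


def _submap(gmap: GeneticMap, loci: np.ndarray) -> GeneticMap:
    return GeneticMap(gmap.chromosome_lengths, gmap.locus_chrom[loci], gmap.locus_pos[loci])


def _gca_varcomps(
    tbv_d: np.ndarray, tbv_l: np.ndarray, Kd: np.ndarray, Kl: np.ndarray,
    resid_var: dict[str, float],
) -> VarComps:
    """True-component mapping for the GCA model: each population transmits
    half its breeding values, so Var(GCA) = 1/4 of the intrapopulation
    additive (co)variance; the untracked Mendelian-sampling half of the
    hybrid genetic variance is folded into the residual."""
    Sd = np.cov(tbv_d.T)
    Sl = np.cov(tbv_l.T)
    terms = {
        DELI: Sd / (4.0 * np.mean(np.diag(Kd))),
        LAME: Sl / (4.0 * np.mean(np.diag(Kl))),
    }
    resid = np.array(
        [
            resid_var[trait] + 0.25 * (Sd[t, t] + Sl[t, t])
            for t, trait in enumerate(TRAITS)
        ]
    )
    return VarComps(terms=terms, resid=resid)


def _ss_varcomps(
    tbv_d: np.ndarray, tbv_l: np.ndarray, resid_var: dict[str, float]
) -> VarComps:
    """Single common additive (co)variance for the single-step model."""
    S = 0.5 * (np.cov(tbv_d.T) + np.cov(tbv_l.T))
    resid = np.array([resid_var[t] for t in TRAITS])
    return VarComps(terms={"additive": S}, resid=resid)


class _SchemeEngine:
    def __init__(self, config: SchemeConfig, founders: FounderSet, rng) -> None:
        self.cfg = config
        self.f = founders
        self.rng = rng
        self.model_ped = _ModelPedigree(founders)
        self.records: list[GenerationRecord] = []
        self.years = 0.0
        self.baseline: float | None = None
        self.calibration: _Calibration | None = None
        self.cand = {DELI: founders.deli, LAME: founders.lame}
        if config.n_candidates < founders.deli.size:
            for pop in (DELI, LAME):
                idx = rng.choice(
                    self.cand[pop].size, config.n_candidates, replace=False
                )
                self.cand[pop] = self.cand[pop].subset(np.sort(idx))
        elif config.n_candidates > founders.deli.size:
            raise ValueError("more candidates requested than founders provide")

    # -- helpers ----------------------------------------------------------

    def tbv(self, pop: DiploidPopulation) -> np.ndarray:
        return self.f.tbv(pop)

    def _record_generation(
        self, gen: int, calibration: bool, accuracy: dict, production: float
    ) -> None:
        rec = GenerationRecord(
            generation=gen,
            calibration=calibration,
            years_elapsed=self.years,
            hybrid_production=production,
            accuracy=accuracy,
        )
        for pop in (DELI, LAME):
            p = self.cand[pop]
            freqs = p.allele_freq()
            tbv = self.tbv(p)
            for t, trait in enumerate(TRAITS):
                rec.additive_variance[(pop, trait)] = additive_variance(
                    freqs, self.f.arch, trait
                )
            if tbv[:, 0].std() > 0 and tbv[:, 1].std() > 0:
                rec.genetic_correlation[pop] = float(
                    np.corrcoef(tbv[:, 0], tbv[:, 1])[0, 1]
                )
            else:
                rec.genetic_correlation[pop] = float("nan")
            rec.mean_inbreeding[pop] = self.f.recorder.mean_inbreeding(p.ids)
        self.records.append(rec)

    def _simulate_progeny_test(self, tested: dict[str, np.ndarray], panel: np.ndarray):
        """Simulate the 300 x 45 interpopulation progeny test.

        Returns (plan, tbv_hyb, pheno, deli_gam, lame_gam, hybrid_ids)
        where gametes are stored at the tracked loci (QTL + panel).
        """
        cfg, rng = self.cfg, self.rng
        arch = self.f.arch
        tracked = np.union1d(arch.all_loci(), panel)
        sub = _submap(self.f.gmap, tracked)
        plan = design_progeny_test(
            tested[DELI].size, tested[LAME].size, cfg.n_test_crosses, rng
        )
        reps = np.repeat(np.arange(plan.shape[0]), cfg.n_offspring_per_cross)
        d_parents = self.cand[DELI].subset(tested[DELI])
        l_parents = self.cand[LAME].subset(tested[LAME])
        d_gam = meiose_many(
            d_parents.haplotypes[:, :, tracked], plan[reps, 0], sub, self.f.meiosis, rng
        )
        l_gam = meiose_many(
            l_parents.haplotypes[:, :, tracked], plan[reps, 1], sub, self.f.meiosis, rng
        )
        # TBV of hybrids at the tracked loci, relative to base frequencies.
        tbv_hyb = np.empty((d_gam.shape[0], 2))
        for t, trait in enumerate(TRAITS):
            qpos = np.searchsorted(tracked, arch.loci(trait))
            d = d_gam[:, qpos].astype(float) + l_gam[:, qpos].astype(float)
            tbv_hyb[:, t] = (d - 2.0 * self.f.base_freqs[arch.loci(trait)]) @ arch.alpha(trait)
        pheno = residual_and_phenotype(tbv_hyb, self.f.trait_params, rng)
        ids = self.f.alloc.take(d_gam.shape[0])
        sire = d_parents.ids[plan[reps, 0]]
        dam = l_parents.ids[plan[reps, 1]]
        self.f.recorder.add(ids, sire, dam, "Hybrid")
        self.model_ped.add(ids, sire, dam)
        panel_pos = np.searchsorted(tracked, panel)
        return plan, reps, tbv_hyb, pheno, d_gam[:, panel_pos], l_gam[:, panel_pos], ids

    # -- model fits -------------------------------------------------------

    def _fit_gca(self, tested, plan, reps, pheno) -> tuple[BLUPSolution, dict]:
        """RRS / RRGS_PAR calibration fit; returns the solution and the
        candidate GCA per population (kernel covers all candidates)."""
        cfg, rng = self.cfg, self.rng
        cand_d, cand_l = self.cand[DELI], self.cand[LAME]
        if cfg.strategy == "RRS":
            ped = self.model_ped.subtable(
                np.concatenate([cand_d.ids, cand_l.ids])
            )
            A, _ = pedigree_A(ped)
            pos_d = ped.positions(cand_d.ids)
            pos_l = ped.positions(cand_l.ids)
            Kd = 0.5 * A[np.ix_(pos_d, pos_d)]
            Kl = 0.5 * A[np.ix_(pos_l, pos_l)]
            panel = None
        else:
            panel = self.calib_panel
            Kd = vanraden_G(cand_d.dosages()[:, panel].astype(float))
            Kl = vanraden_G(cand_l.dosages()[:, panel].astype(float))
            Kd = 0.99 * Kd + 0.01 * np.eye(Kd.shape[0])
            Kl = 0.99 * Kl + 0.01 * np.eye(Kl.shape[0])
        vc = _gca_varcomps(
            self.tbv(cand_d), self.tbv(cand_l), Kd, Kl,
            self.f.trait_params.resid_var,
        )
        sol = solve_gca_bivariate(
            pheno, tested[DELI][plan[reps, 0]], tested[LAME][plan[reps, 1]],
            Kd, Kl, vc, term_names=(DELI, LAME),
        )
        gca = {DELI: sol.effects[DELI], LAME: sol.effects[LAME]}
        store = {
            "varcomps": vc,
            "deli_panel_dosage": None if panel is None else cand_d.dosages()[:, panel],
            "lame_panel_dosage": None if panel is None else cand_l.dosages()[:, panel],
        }
        return sol, gca, store

    def _fit_ssgblup(
        self, tested, plan, reps, pheno, d_gam, l_gam, hybrid_ids
    ):
        """RRGS_HYB calibration fit via the single-step H matrix."""
        cfg, rng = self.cfg, self.rng
        cand_d, cand_l = self.cand[DELI], self.cand[LAME]
        panel = self.calib_panel
        n_hyb = hybrid_ids.size
        # Genotyped hybrids: equal numbers per cross, random within cross.
        per_cross = _balanced_usage(plan.shape[0], cfg.n_genotyped_hybrids, rng)
        sel = []
        for c in range(plan.shape[0]):
            members = np.flatnonzero(reps == c)
            sel.append(rng.choice(members, size=per_cross[c], replace=False))
        geno_hyb = np.sort(np.concatenate(sel))
        gametotypes = np.stack([d_gam[geno_hyb], l_gam[geno_hyb]], axis=1)

        ped = self.model_ped.table()
        genotyped_ids = np.concatenate(
            [cand_d.ids, cand_l.ids, hybrid_ids[geno_hyb]]
        )
        # Ancestor closure of the genotyped set only: hybrids are terminal,
        # so their inbreeding never enters Henderson's rules and A22 needs
        # just the genotyped block.
        sub = self.model_ped.subtable(genotyped_ids)
        A_sub, F_sub = pedigree_A(sub)
        g_pos = sub.positions(genotyped_ids)
        A22 = A_sub[np.ix_(g_pos, g_pos)]
        G = origin_aware_G(
            {DELI: cand_d.dosages()[:, panel].astype(float),
             LAME: cand_l.dosages()[:, panel].astype(float)},
            gametotypes,
        )
        # Sparse A^-1 over the model pedigree, reusing F from the closure.
        F_full = np.zeros(ped.size)
        F_full[ped.positions(sub.ids)] = F_sub
        a_inv = a_inverse(ped, F_full)
        hinv = h_inverse(
            a_inv, A22, G, ped.positions(genotyped_ids), cfg.blend_weight
        )
        vc = _ss_varcomps(
            self.tbv(cand_d), self.tbv(cand_l), self.f.trait_params.resid_var
        )
        rec_idx = ped.positions(hybrid_ids)
        sol = solve_ssgblup_bivariate(pheno, rec_idx, hinv, vc)
        if not sol.converged:
            logger.warning("single-step solver did not fully converge")
        a = sol.effects["additive"]
        gca = {
            DELI: 0.5 * a[ped.positions(cand_d.ids)],
            LAME: 0.5 * a[ped.positions(cand_l.ids)],
        }
        store = {
            "varcomps": vc,
            "deli_panel_dosage": cand_d.dosages()[:, panel],
            "lame_panel_dosage": cand_l.dosages()[:, panel],
            "hybrid_gametotypes": gametotypes,
            "genotyped_hybrid_ids": hybrid_ids[geno_hyb],
        }
        return sol, gca, store

    # -- marker-only prediction -------------------------------------------

    def _predict_from_calibration(self) -> tuple[BLUPSolution, dict]:
        """GEBV of the current (non-progeny-tested) candidates from the
        stored calibration, by extending the relationship machinery with
        their genotypes and re-solving with the stored records."""
        cal = self.calibration
        cfg = self.cfg
        cand_d, cand_l = self.cand[DELI], self.cand[LAME]
        new_d = cand_d.dosages()[:, cal.panel]
        new_l = cand_l.dosages()[:, cal.panel]
        if cfg.strategy == "RRGS_PAR":
            stack_d = np.concatenate([cal.deli_panel_dosage, new_d]).astype(float)
            stack_l = np.concatenate([cal.lame_panel_dosage, new_l]).astype(float)
            Kd = vanraden_G(stack_d)
            Kl = vanraden_G(stack_l)
            Kd = 0.99 * Kd + 0.01 * np.eye(Kd.shape[0])
            Kl = 0.99 * Kl + 0.01 * np.eye(Kl.shape[0])
            sol = solve_gca_bivariate(
                cal.y, cal.deli_link, cal.lame_link, Kd, Kl, cal.varcomps,
                term_names=(DELI, LAME),
            )
            n_old_d = cal.deli_panel_dosage.shape[0]
            n_old_l = cal.lame_panel_dosage.shape[0]
            gca = {
                DELI: sol.effects[DELI][n_old_d:],
                LAME: sol.effects[LAME][n_old_l:],
            }
            return sol, gca
        # RRGS_HYB: extend the genotyped block of H with the new candidates.
        ped = self.model_ped.table()
        # Order must match origin_aware_G rows: all Deli (calibration then
        # new), all La Me, then the genotyped hybrids.
        genotyped_ids = np.concatenate(
            [cal.deli_ids, cand_d.ids, cal.lame_ids, cand_l.ids,
             cal.genotyped_hybrid_ids]
        )
        sub = self.model_ped.subtable(genotyped_ids)
        A_sub, F_sub = pedigree_A(sub)
        g_pos = sub.positions(genotyped_ids)
        A22 = A_sub[np.ix_(g_pos, g_pos)]
        G = origin_aware_G(
            {DELI: np.concatenate([cal.deli_panel_dosage, new_d]).astype(float),
             LAME: np.concatenate([cal.lame_panel_dosage, new_l]).astype(float)},
            cal.hybrid_gametotypes,
        )
        F_full = np.zeros(ped.size)
        F_full[ped.positions(sub.ids)] = F_sub
        a_inv = a_inverse(ped, F_full)
        hinv = h_inverse(a_inv, A22, G, ped.positions(genotyped_ids), cfg.blend_weight)
        rec_idx = ped.positions(cal.hybrid_ids)
        sol = solve_ssgblup_bivariate(cal.y, rec_idx, hinv, cal.varcomps)
        a = sol.effects["additive"]
        gca = {
            DELI: 0.5 * a[ped.positions(cand_d.ids)],
            LAME: 0.5 * a[ped.positions(cand_l.ids)],
        }
        return sol, gca

    # -- cycle ------------------------------------------------------------

    def run(self, n_cycles: int | None = None) -> RunSummary:
        cfg, rng = self.cfg, self.rng
        pattern = cfg.pattern if n_cycles is None else cfg.pattern[:n_cycles]
        self._record_generation(0, False, {}, np.nan)  # production filled below

        for cycle, letter in enumerate(pattern, start=1):
            if letter == "G":
                sol, gca, accuracy = self._calibration_cycle()
                self.years += cfg.years_progeny_test
            else:
                sol, gca = self._predict_from_calibration()
                accuracy = self._accuracy(gca)
                self.years += cfg.years_marker_only

            means = sol.means
            sel_d, sel_l = select_parents(
                gca[DELI], gca[LAME], means, cfg.n_selected, rng
            )
            tbv_sel_d = self.tbv(self.cand[DELI])[sel_d]
            tbv_sel_l = self.tbv(self.cand[LAME])[sel_l]
            production = measure_hybrid_production(
                tbv_sel_d, tbv_sel_l,
                np.array([self.f.trait_params.mean_bw, self.f.trait_params.mean_bn]),
            )
            self._next_generation(sel_d, sel_l)
            self._record_generation(cycle, letter == "G", accuracy, production)

        summary = summarize_run(self.records)
        return summary

    def _accuracy(self, gca: dict) -> dict:
        out = {}
        for pop in (DELI, LAME):
            tbv = self.tbv(self.cand[pop])
            for t, trait in enumerate(TRAITS):
                out[(pop, trait)] = selection_accuracy(gca[pop][:, t], tbv[:, t])
        return out

    def _calibration_cycle(self):
        cfg, rng = self.cfg, self.rng
        tested = {}
        for pop in (DELI, LAME):
            n = self.cand[pop].size
            if n > cfg.n_progeny_tested:
                tested[pop] = np.sort(
                    rng.choice(n, cfg.n_progeny_tested, replace=False)
                )
            else:
                tested[pop] = np.arange(n)
        # Marker panel from the current parental candidates (genomic
        # strategies only; RRS carries no panel).
        if cfg.strategy == "RRS":
            self.calib_panel = None
            panel = np.empty(0, dtype=np.int64)
        else:
            combined = np.concatenate(
                [self.cand[DELI].dosages(), self.cand[LAME].dosages()]
            )
            self.calib_panel = select_snp_panel(
                combined, cfg.panel_maf_min, cfg.panel_size, rng
            )
            panel = self.calib_panel
        plan, reps, tbv_hyb, pheno, d_gam, l_gam, hybrid_ids = (
            self._simulate_progeny_test(tested, panel)
        )
        if self.baseline is None:
            base_prod = measure_hybrid_production(
                self.tbv(self.cand[DELI].subset(tested[DELI])),
                self.tbv(self.cand[LAME].subset(tested[LAME])),
                np.array([self.f.trait_params.mean_bw, self.f.trait_params.mean_bn]),
                pairs=plan,
            )
            self.baseline = base_prod
            self.records[0].hybrid_production = base_prod

        if cfg.strategy == "RRGS_HYB":
            sol, gca, store = self._fit_ssgblup(
                tested, plan, reps, pheno, d_gam, l_gam, hybrid_ids
            )
        else:
            sol, gca, store = self._fit_gca(tested, plan, reps, pheno)

        self.calibration = _Calibration(
            y=pheno,
            deli_link=tested[DELI][plan[reps, 0]],
            lame_link=tested[LAME][plan[reps, 1]],
            varcomps=store["varcomps"],
            means=sol.means,
            panel=panel,
            deli_panel_dosage=store.get("deli_panel_dosage"),
            lame_panel_dosage=store.get("lame_panel_dosage"),
            hybrid_gametotypes=store.get("hybrid_gametotypes"),
            hybrid_ids=hybrid_ids,
            genotyped_hybrid_ids=store.get("genotyped_hybrid_ids"),
            deli_ids=self.cand[DELI].ids.copy(),
            lame_ids=self.cand[LAME].ids.copy(),
        )
        accuracy = self._accuracy(gca)
        return sol, gca, accuracy

    def _next_generation(self, sel_d: np.ndarray, sel_l: np.ndarray) -> None:
        cfg, rng = self.cfg, self.rng
        for pop, sel in ((DELI, sel_d), (LAME, sel_l)):
            selected = self.cand[pop].subset(sel)
            plan = make_within_pop_matings(
                selected.size, cfg.diallel_fraction, cfg.n_candidates, rng
            )
            matings = np.repeat(plan[:, :2], plan[:, 2], axis=0)
            g1 = meiose_many(
                selected.haplotypes, matings[:, 0], self.f.gmap, self.f.meiosis, rng
            )
            g2 = meiose_many(
                selected.haplotypes, matings[:, 1], self.f.gmap, self.f.meiosis, rng
            )
            ids = self.f.alloc.take(matings.shape[0])
            newpop = DiploidPopulation(
                ids,
                selected.ids[matings[:, 0]],
                selected.ids[matings[:, 1]],
                np.stack([g1, g2], axis=1),
                selected.generation + 1,
                pop,
            )
            self.f.recorder.add(newpop.ids, newpop.sire, newpop.dam, pop)
            self.model_ped.add(newpop.ids, newpop.sire, newpop.dam)
            self.cand[pop] = newpop


def run_scheme(
    config: SchemeConfig,
    founders: FounderSet,
    rng: np.random.Generator,
    n_cycles: int | None = None,
) -> RunSummary:
    """Run one breeding scheme on a founder replicate.

    ``n_cycles`` truncates the calibration pattern for reduced runs; the
    default runs all four cycles.
    """
    return _SchemeEngine(config, founders, rng).run(n_cycles)
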