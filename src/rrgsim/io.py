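"""Output writers, genotype export and miniature test fixtures."""

from __future__ import annotations

import dataclasses
import json
import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import StudyConfig, phase_rng
from .genome import DiploidPopulation, GeneticMap, MeiosisParams, run_burnin
from .history import FounderSet, HistoryConfig, build_founders
from .schemes import SchemeConfig
from .stats import RunSummary
from .traits import TraitParams, assign_qtl

__all__ = [
    "write_run_outputs",
    "export_genotypes",
    "save_population",
    "load_population",
    "save_founders",
    "load_founders",
    "make_toy_fixture",
    "ToyFixture",
]


# ---------------------------------------------------------------------------
# Run outputs
# ---------------------------------------------------------------------------

def write_run_outputs(
    summary: RunSummary,
    out_dir: str | Path,
    scheme: SchemeConfig | None = None,
    manifest: dict | None = None,
    prefix: str = "run",
) -> dict[str, Path]:
    """Write per-generation and scheme-level CSV tables plus a manifest.

    The per-generation table is ``summary.table``; the scheme-level table
    carries one row of endpoint summaries.  The manifest records seeds and
    configuration so a run is re-creatable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    gen_path = out_dir / f"{prefix}_generations.csv"
    summary.table.to_csv(gen_path, index=False)
    paths["generations"] = gen_path

    row = {
        "total_years": summary.total_years,
        "cumulative_response_pct": summary.cumulative_response_pct,
        "annual_response_pct": summary.annual_response_pct,
    }
    for pop, v in summary.delta_F_cumulative_pct.items():
        row[f"delta_F_cum_pct_{pop}"] = v
    for pop, v in summary.delta_F_annual_pct.items():
        row[f"delta_F_annual_pct_{pop}"] = v
    for pop, v in summary.delta_F_absolute.items():
        row[f"delta_F_abs_{pop}"] = v
    if scheme is not None:
        row = {**dataclasses.asdict(scheme), **row}
    scheme_path = out_dir / f"{prefix}_summary.csv"
    pd.DataFrame([row]).to_csv(scheme_path, index=False)
    paths["summary"] = scheme_path

    man_path = out_dir / f"{prefix}_manifest.json"
    man_path.write_text(json.dumps(manifest or {}, indent=2, default=str))
    paths["manifest"] = man_path
    return paths


# ---------------------------------------------------------------------------
# Genotype export
# ---------------------------------------------------------------------------

def export_genotypes(
    pop: DiploidPopulation,
    gmap: GeneticMap,
    path: str | Path,
    loci: np.ndarray | None = None,
    fmt: str = "vcf",
    origins: tuple[str, str] | None = None,
) -> Path:
    """Export phased genotypes as VCF (or a transposed text matrix).

    VCF positions are the map positions in Morgans scaled to integer
    base-pair-like coordinates (x 1e6, 1-based).  When ``origins`` names the
    two parental populations of hybrid individuals, a per-individual PO
    (parental origin) FORMAT field tags haplotype 1 / haplotype 2 with them.
    """
    path = Path(path)
    loci = np.arange(gmap.n_loci) if loci is None else np.asarray(loci)
    if loci.size and (loci.min() < 0 or loci.max() >= gmap.n_loci):
        raise ValueError("panel loci outside the map")
    if fmt == "matrix":
        dos = pop.dosages()[:, loci]
        df = pd.DataFrame(
            dos.T,
            index=[f"locus{int(l)}" for l in loci],
            columns=[f"ind{int(i)}" for i in pop.ids],
        )
        df.to_csv(path, sep="\t")
        return path
    if fmt != "vcf":
        raise ValueError(f"unsupported format {fmt!r}")

    lines = [
        "##fileformat=VCFv4.2",
        "##source=rrgsim",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">',
    ]
    if origins is not None:
        lines.append(
            '##FORMAT=<ID=PO,Number=1,Type=String,Description='
            '"Parental origin of haplotype 1|haplotype 2">'
        )
    for c in range(gmap.n_chromosomes):
        length = int(np.ceil(gmap.chromosome_lengths[c] * 1e6)) + 1
        lines.append(f"##contig=<ID=chr{c + 1},length={length}>")
    cols = "\t".join(f"ind{int(i)}" for i in pop.ids)
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}")
    fmt_col = "GT:PO" if origins is not None else "GT"
    po = f"{origins[0]}|{origins[1]}" if origins is not None else None
    h = pop.haplotypes
    for loc in loci:
        loc = int(loc)
        chrom = int(gmap.locus_chrom[loc]) + 1
        pos = int(round(gmap.locus_pos[loc] * 1e6)) + 1
        gts = [
            f"{h[i, 0, loc]}|{h[i, 1, loc]}" + (f":{po}" if po else "")
            for i in range(pop.size)
        ]
        lines.append(
            f"chr{chrom}\t{pos}\tlocus{loc}\tA\tT\t.\tPASS\t.\t{fmt_col}\t"
            + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Snapshots (runtime containers, not part of any text deliverable)
# ---------------------------------------------------------------------------

def save_population(pop: DiploidPopulation, gmap: GeneticMap, path: str | Path) -> None:
    """Snapshot a population (haplotypes bit-packed) plus its map."""
    np.savez_compressed(
        Path(path),
        ids=pop.ids, sire=pop.sire, dam=pop.dam,
        generation=pop.generation, label=pop.label,
        n_loci=pop.n_loci,
        haplo_packed=np.packbits(pop.haplotypes, axis=-1),
        chromosome_lengths=gmap.chromosome_lengths,
        locus_chrom=gmap.locus_chrom, locus_pos=gmap.locus_pos,
    )


def load_population(path: str | Path) -> tuple[DiploidPopulation, GeneticMap]:
    z = np.load(Path(path), allow_pickle=False)
    n_loci = int(z["n_loci"])
    haplo = np.unpackbits(z["haplo_packed"], axis=-1)[..., :n_loci]
    pop = DiploidPopulation(
        z["ids"], z["sire"], z["dam"], haplo,
        int(z["generation"]), str(z["label"]),
    )
    gmap = GeneticMap(z["chromosome_lengths"], z["locus_chrom"], z["locus_pos"])
    return pop, gmap


def save_founders(founders: FounderSet, path: str | Path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(founders, fh)


def load_founders(path: str | Path) -> FounderSet:
    with open(path, "rb") as fh:
        return pickle.load(fh)


# ---------------------------------------------------------------------------
# Toy fixtures
# ---------------------------------------------------------------------------

@dataclass
class ToyFixture:
    """Miniature study inputs runnable in seconds (for tests and demos)."""

    scale: str
    study: StudyConfig
    gmap: GeneticMap
    meiosis: MeiosisParams
    base_pop: DiploidPopulation
    founders: FounderSet

    def scheme(self, **overrides) -> SchemeConfig:
        defaults = dict(
            strategy="RRS", pattern="GGGG",
            n_candidates=12, n_genotyped_hybrids=0, n_selected=5,
            n_progeny_tested=12, n_test_crosses=30, n_offspring_per_cross=5,
            panel_size=60, panel_maf_min=0.04,
        )
        defaults.update(overrides)
        return SchemeConfig(**defaults)


def make_study_base(
    seed: int,
    burnin_size: int = 200,
    burnin_generations: int = 800,
) -> tuple[DiploidPopulation, GeneticMap, MeiosisParams]:
    """Desk-scale base population: the full 16-chromosome / 17 Morgan /
    20000-locus genome burnt in at the published population size with a
    reduced number of generations (about one coalescent time at the
    equal-contribution effective size), which retains a U-shaped frequency
    spectrum with substantial residual polymorphism.  A single base
    population is generated per study and shared by all replicates."""
    gmap = GeneticMap.uniform(16, 17.0, 20000)
    mparams = MeiosisParams(1e-5)
    base = run_burnin(
        burnin_size, burnin_generations, gmap, mparams, phase_rng(seed, 0)
    )
    return base, gmap, mparams


def make_study_replicate(
    base: DiploidPopulation,
    gmap: GeneticMap,
    mparams: MeiosisParams,
    seed: int,
    replicate: int = 0,
    n_qtl: int = 500,
    p_pleio: float = 0.75,
    max_attempts: int = 10,
) -> FounderSet:
    """One study replicate from a shared base population.

    Runs QTL assignment and the full published population history
    (divergence, bottlenecks, mass selection, pseudo progeny tests,
    300-individual generation-0 populations), retrying the replicate while
    a single QTL explains more than 20% of the additive variance in either
    population.
    """
    from .history import founder_statistics

    trait_params = TraitParams()
    founders = None
    for attempt in range(max_attempts):
        rng = phase_rng(seed, 1, replicate, attempt)
        arch = assign_qtl(base, n_qtl, p_pleio, -0.9, (6.0, 12.0), rng, maf_min=0.1)
        founders = build_founders(
            base, arch, trait_params, gmap, mparams, rng, HistoryConfig()
        )
        stats = founder_statistics(founders, ld=False)
        if stats["max_qtl_share"] <= 0.20:
            break
    return founders


_TOY_SCALES = {
    "tiny": dict(
        n_chromosomes=2, total_length=1.0, n_loci=200,
        burnin_size=30, burnin_generations=100,
        n_qtl=20, p_pleio=0.75,
        history=dict(
            divergence_generations=10, divergence_size=15,
            deli_founders=4, deli_random_sizes=(12,),
            deli_expansion_sizes=(16, 20), deli_retain=0.7,
            lame_founders=8, lame_expansion_sizes=(16, 20), lame_retain=0.5,
            pre_rrs_accuracies=(0.8, 0.9), n_selected=6,
            diallel_fraction=0.8, generation0_size=24,
        ),
    ),
    "small": dict(
        n_chromosomes=4, total_length=4.0, n_loci=1000,
        burnin_size=64, burnin_generations=200,
        n_qtl=60, p_pleio=0.75,
        history=dict(
            divergence_generations=25, divergence_size=30,
            deli_founders=4, deli_random_sizes=(15,),
            deli_expansion_sizes=(25, 40), deli_retain=0.7,
            lame_founders=12, lame_expansion_sizes=(25, 40), lame_retain=0.4,
            pre_rrs_accuracies=(0.8, 0.9), n_selected=8,
            diallel_fraction=0.8, generation0_size=40,
        ),
    ),
}


def make_toy_fixture(scale: str = "tiny", seed: int = 0) -> ToyFixture:
    """Build a miniature, fully deterministic study (burn-in + founders)."""
    if scale not in _TOY_SCALES:
        raise ValueError(f"scale must be one of {sorted(_TOY_SCALES)}")
    spec = _TOY_SCALES[scale]
    gmap = GeneticMap.uniform(
        spec["n_chromosomes"], spec["total_length"], spec["n_loci"]
    )
    mparams = MeiosisParams(mutation_rate=1e-4)
    rng = phase_rng(seed, 0)
    base = run_burnin(
        spec["burnin_size"], spec["burnin_generations"], gmap, mparams, rng
    )
    trait_params = TraitParams()
    arch = assign_qtl(
        base, spec["n_qtl"], spec["p_pleio"], -0.9, (6.0, 12.0),
        phase_rng(seed, 1), maf_min=0.1,
    )
    hist = HistoryConfig(**spec["history"])
    founders = build_founders(
        base, arch, trait_params, gmap, mparams, phase_rng(seed, 2), hist
    )
    study = StudyConfig(allow_custom=True)
    study.genome.n_chromosomes = spec["n_chromosomes"]
    study.genome.total_length_morgans = spec["total_length"]
    study.genome.n_loci = spec["n_loci"]
    study.genome.burnin_size = spec["burnin_size"]
    study.genome.burnin_generations = spec["burnin_generations"]
    study.traits.n_qtl = spec["n_qtl"]
    study.traits.p_pleio = spec["p_pleio"]
    study.history = hist
    study.master_seed = seed
    return ToyFixture(scale, study, gmap, mparams, base, founders)
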