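"""Study configuration: YAML loading, validation, defaults and seeding.

An empty configuration file yields the full default study (17 Morgan / 16
chromosome genome, 20000 loci, 2400-generation burn-in of 200 individuals,
base additive variances 6 and 12, heritability 0.8, the published
population-history schedule and scheme grid).  Values outside the
documented grids are rejected unless ``allow_custom`` is set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .history import HistoryConfig

__all__ = ["StudyConfig", "load_config", "dump_config", "phase_rng", "derive_seed"]

N_QTL_GRID = (100, 500, 1000)
P_PLEIO_GRID = (0.60, 0.75, 0.90)
CANDIDATE_GRID = (120, 300)
GENOTYPED_GRID = (0, 300, 1000, 1700)


@dataclass
class GenomeBlock:
    n_chromosomes: int = 16
    total_length_morgans: float = 17.0
    n_loci: int = 20000
    mutation_rate: float = 1e-5
    burnin_size: int = 200
    burnin_generations: int = 2400


@dataclass
class TraitBlock:
    n_qtl: int = 500
    p_pleio: float = 0.75
    rho: float = -0.9
    base_var_bw: float = 6.0
    base_var_bn: float = 12.0
    h2_base: float = 0.8
    mean_bw: float = 15.0
    mean_bn: float = 15.0
    qtl_maf_min: float = 0.1


@dataclass
class SchemeBlock:
    strategy: str = "RRS"
    pattern: str = "GGGG"
    n_candidates: int = 120
    n_genotyped_hybrids: int = 0


@dataclass
class StudyConfig:
    genome: GenomeBlock = field(default_factory=GenomeBlock)
    traits: TraitBlock = field(default_factory=TraitBlock)
    history: HistoryConfig = field(default_factory=HistoryConfig)
    schemes: list[SchemeBlock] = field(default_factory=lambda: [SchemeBlock()])
    replicates: int = 5
    master_seed: int = 1
    allow_custom: bool = False

    def validate(self) -> None:
        g, t = self.genome, self.traits
        if not 0.0 <= g.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if min(g.n_chromosomes, g.n_loci, g.burnin_size) < 1 or g.burnin_generations < 0:
            raise ValueError("genome block values must be positive")
        if not -1.0 <= t.rho <= 1.0:
            raise ValueError("rho must be in [-1, 1]")
        if not 0.0 < t.h2_base <= 1.0:
            raise ValueError("h2_base must be in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.allow_custom:
            if t.n_qtl not in N_QTL_GRID:
                raise ValueError(
                    f"n_qtl {t.n_qtl} outside the documented grid {N_QTL_GRID}; "
                    "set allow_custom to override"
                )
            if round(t.p_pleio, 2) not in P_PLEIO_GRID:
                raise ValueError(
                    f"p_pleio {t.p_pleio} outside the documented grid {P_PLEIO_GRID}; "
                    "set allow_custom to override"
                )
            for s in self.schemes:
                if s.n_candidates not in CANDIDATE_GRID:
                    raise ValueError(
                        f"n_candidates {s.n_candidates} outside {CANDIDATE_GRID}; "
                        "set allow_custom to override"
                    )
                if s.n_genotyped_hybrids not in GENOTYPED_GRID:
                    raise ValueError(
                        f"n_genotyped_hybrids {s.n_genotyped_hybrids} outside "
                        f"{GENOTYPED_GRID}; set allow_custom to override"
                    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["history"]["pedigree_depth"] = dict(self.history.pedigree_depth)
        return d


def _from_mapping(cls, data: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None = None, text: str | None = None) -> StudyConfig:
    """Load and validate a YAML study configuration.

    Missing blocks and keys fall back to the study defaults; unknown keys
    and out-of-range values are rejected with explicit messages.
    """
    if text is None:
        if path is None:
            raise ValueError("either path or text is required")
        text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a YAML mapping")
    known_top = {"genome", "traits", "history", "schemes", "replicates",
                 "master_seed", "allow_custom"}
    unknown = set(raw) - known_top
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    genome = _from_mapping(GenomeBlock, raw.get("genome", {}), "genome")
    traits = _from_mapping(TraitBlock, raw.get("traits", {}), "traits")
    hist_raw = dict(raw.get("history", {}))
    for key in ("deli_random_sizes", "deli_expansion_sizes",
                "lame_expansion_sizes", "pre_rrs_accuracies"):
        if key in hist_raw:
            hist_raw[key] = tuple(hist_raw[key])
    history = _from_mapping(HistoryConfig, hist_raw, "history")
    schemes_raw = raw.get("schemes", [{}]) or [{}]
    schemes = [
        _from_mapping(SchemeBlock, s, f"schemes[{k}]")
        for k, s in enumerate(schemes_raw)
    ]
    cfg = StudyConfig(
        genome=genome, traits=traits, history=history, schemes=schemes,
        replicates=int(raw.get("replicates", 5)),
        master_seed=int(raw.get("master_seed", 1)),
        allow_custom=bool(raw.get("allow_custom", False)),
    )
    cfg.validate()
    return cfg


def dump_config(cfg: StudyConfig) -> str:
    """YAML text that round-trips through :func:`load_config`."""
    d = cfg.to_dict()
    for key in ("deli_random_sizes", "deli_expansion_sizes",
                "lame_expansion_sizes", "pre_rrs_accuracies"):
        d["history"][key] = list(d["history"][key])
    return yaml.safe_dump(d, sort_keys=False)


def derive_seed(master_seed: int, *keys: int) -> np.random.SeedSequence:
    """Hierarchical seed: master -> replicate -> phase, so any phase can be
    re-run in isolation."""
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in keys))


def phase_rng(master_seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, *keys))
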