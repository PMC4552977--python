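"""Bivariate QTL architecture, breeding values and phenotypes.

Two additive component traits — bunch weight (BW) and bunch number (BN) —
are controlled by biallelic QTL, a configurable fraction of which are
pleiotropic with substitution effects drawn from a bivariate normal with
correlation rho (default -0.9).  Bunch production, the selection objective,
is the BW x BN product; its heterosis arises purely from the multiplicative
interaction of the negatively correlated components, without dominance.

Breeding values follow the classical biallelic parameterisation: at a QTL
with allele-1 frequency p and substitution effect alpha, genotypes 00/01/11
contribute -2p*alpha, (1-2p)*alpha and 2(1-p)*alpha, i.e. (d - 2p)*alpha for
dosage d.  The intrapopulation additive variance is sum(2p(1-p)alpha^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import DiploidPopulation

__all__ = [
    "QTLArchitecture",
    "TraitParams",
    "TRAITS",
    "assign_qtl",
    "true_breeding_values",
    "additive_variance",
    "qtl_variance_shares",
    "residual_and_phenotype",
]

TRAITS = ("BW", "BN")


@dataclass(frozen=True)
class QTLArchitecture:
    """Trait-specific and pleiotropic QTL with their substitution effects.

    ``loci_bw``/``loci_bn`` are locus indices (each trait sees exactly
    ``n_qtl`` loci); pleiotropic loci appear in both lists with effects drawn
    jointly.
    """

    loci_bw: np.ndarray
    alpha_bw: np.ndarray
    loci_bn: np.ndarray
    alpha_bn: np.ndarray
    pleiotropic: np.ndarray  # locus indices carried by both traits

    def __post_init__(self) -> None:
        for name in ("loci_bw", "loci_bn", "pleiotropic"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        for name in ("alpha_bw", "alpha_bn"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.loci_bw.size != self.alpha_bw.size or self.loci_bn.size != self.alpha_bn.size:
            raise ValueError("loci and effects must align")

    @property
    def n_qtl(self) -> int:
        return int(self.loci_bw.size)

    def loci(self, trait: str) -> np.ndarray:
        return self.loci_bw if trait == "BW" else self.loci_bn

    def alpha(self, trait: str) -> np.ndarray:
        return self.alpha_bw if trait == "BW" else self.alpha_bn

    def all_loci(self) -> np.ndarray:
        """Distinct QTL loci across both traits."""
        return np.unique(np.concatenate([self.loci_bw, self.loci_bn]))

    def to_table(self):
        """Tab-separated-friendly table of the architecture."""
        import pandas as pd

        rows = []
        pleio = set(self.pleiotropic.tolist())
        for trait in TRAITS:
            for loc, a in zip(self.loci(trait), self.alpha(trait)):
                rows.append(
                    {"locus": int(loc), "trait": trait, "effect": float(a),
                     "pleiotropic": int(loc) in pleio}
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TraitParams:
    """Trait means, base-population heritability and residual variances.

    Residual variances are fixed once from the configured base additive
    variances via sigma2_e = sigma2_a * (1 - h2) / h2 and never updated.
    """

    mean_bw: float = 15.0
    mean_bn: float = 15.0
    h2_base: float = 0.8
    base_var_bw: float = 6.0
    base_var_bn: float = 12.0

    def __post_init__(self) -> None:
        if not 0.0 < self.h2_base <= 1.0:
            raise ValueError("h2_base must be in (0, 1]")
        if self.base_var_bw < 0 or self.base_var_bn < 0:
            raise ValueError("base variances must be non-negative")

    @property
    def resid_var(self) -> dict[str, float]:
        f = (1.0 - self.h2_base) / self.h2_base
        return {"BW": self.base_var_bw * f, "BN": self.base_var_bn * f}

    @property
    def means(self) -> dict[str, float]:
        return {"BW": self.mean_bw, "BN": self.mean_bn}


def assign_qtl(
    base_pop: DiploidPopulation,
    n_qtl: int,
    p_pleio: float,
    rho: float,
    base_variances: tuple[float, float],
    rng: np.random.Generator,
    maf_min: float = 0.1,
) -> QTLArchitecture:
    """Assign QTL among segregating loci with MAF > ``maf_min``.

    round(p_pleio * n_qtl) loci are pleiotropic (shared by BW and BN, effects
    from a bivariate normal with correlation ``rho``); the remaining QTL are
    trait-private with univariate normal effects.  Per-trait effect variance
    is base variance / n_qtl.
    """
    if not 0.0 <= p_pleio <= 1.0:
        raise ValueError("p_pleio must be in [0, 1]")
    f = base_pop.allele_freq()
    maf = np.minimum(f, 1.0 - f)
    eligible = np.flatnonzero(maf > maf_min)
    n_pleio = int(round(p_pleio * n_qtl))
    n_priv = n_qtl - n_pleio
    n_needed = n_pleio + 2 * n_priv
    if eligible.size < n_needed:
        raise ValueError(
            f"only {eligible.size} loci with MAF > {maf_min}, need {n_needed}"
        )
    chosen = rng.choice(eligible, size=n_needed, replace=False)
    pleio = np.sort(chosen[:n_pleio])
    priv_bw = np.sort(chosen[n_pleio : n_pleio + n_priv])
    priv_bn = np.sort(chosen[n_pleio + n_priv :])

    var_bw = base_variances[0] / n_qtl
    var_bn = base_variances[1] / n_qtl
    cov = rho * np.sqrt(var_bw * var_bn)
    if n_pleio:
        eff = rng.multivariate_normal(
            [0.0, 0.0], [[var_bw, cov], [cov, var_bn]], size=n_pleio
        )
    else:
        eff = np.empty((0, 2))
    a_bw = np.concatenate([eff[:, 0], rng.normal(0.0, np.sqrt(var_bw), n_priv)])
    a_bn = np.concatenate([eff[:, 1], rng.normal(0.0, np.sqrt(var_bn), n_priv)])
    loci_bw = np.concatenate([pleio, priv_bw])
    loci_bn = np.concatenate([pleio, priv_bn])
    return QTLArchitecture(loci_bw, a_bw, loci_bn, a_bn, pleio)


def true_breeding_values(
    haplotypes: np.ndarray,
    arch: QTLArchitecture,
    allele_freqs: np.ndarray,
) -> np.ndarray:
    """True breeding values, (n, 2) array ordered (BW, BN).

    ``allele_freqs`` are the allele-1 frequencies of the reference population
    in which breeding values are expressed; when they are the frequencies of
    the scored population itself the per-QTL mean contribution is exactly 0.
    """
    allele_freqs = np.asarray(allele_freqs, dtype=float)
    if np.any(allele_freqs < 0) or np.any(allele_freqs > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    out = np.empty((haplotypes.shape[0], 2))
    for t, trait in enumerate(TRAITS):
        loci = arch.loci(trait)
        d = haplotypes[:, :, loci].sum(axis=1)
        p = allele_freqs[loci]
        out[:, t] = (d - 2.0 * p) @ arch.alpha(trait)
    return out


def additive_variance(
    allele_freqs: np.ndarray, arch: QTLArchitecture, trait: str
) -> float:
    """Intrapopulation additive variance sum(2 p (1-p) alpha^2)."""
    return float(qtl_variance_shares(allele_freqs, arch, trait).sum())


def qtl_variance_shares(
    allele_freqs: np.ndarray, arch: QTLArchitecture, trait: str
) -> np.ndarray:
    """Per-QTL additive-variance contributions 2 p (1-p) alpha^2."""
    p = np.asarray(allele_freqs, dtype=float)[arch.loci(trait)]
    return 2.0 * p * (1.0 - p) * arch.alpha(trait) ** 2


def residual_and_phenotype(
    tbv: np.ndarray,
    params: TraitParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Phenotypes (n, 2): mean + TBV + independent normal residuals."""
    tbv = np.asarray(tbv, dtype=float)
    resid = params.resid_var
    out = np.empty_like(tbv)
    for t, trait in enumerate(TRAITS):
        noise = rng.normal(0.0, np.sqrt(resid[trait]), size=tbv.shape[0])
        out[:, t] = params.means[trait] + tbv[:, t] + noise
    return out
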