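"""Calibration and outcome statistics.

Weir-Cockerham Fst between the two parental populations, linkage
disequilibrium decay against genetic distance, selection accuracy, and the
per-run summaries (selection response, annual response, inbreeding rates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneticMap

__all__ = [
    "wc_fst",
    "ld_r2_curve",
    "ld_decay_distance",
    "selection_accuracy",
    "GenerationRecord",
    "RunSummary",
    "summarize_run",
]


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst (two populations, multilocus ratio of averages)
# ---------------------------------------------------------------------------

def wc_fst(dosages1: np.ndarray, dosages2: np.ndarray) -> float:
    """Weir & Cockerham (1984) theta for two samples of diploid genotypes.

    ``dosages*`` are (n_i, m) 0/1/2 matrices over shared loci.  Returns the
    multilocus ratio-of-averages estimate; NaN when no locus is polymorphic.
    Individuals are treated as random-union-of-gametes (heterozygote
    frequencies enter the c component).
    """
    D1 = np.asarray(dosages1)
    D2 = np.asarray(dosages2)
    if D1.size == 0 or D2.size == 0:
        raise ValueError("both samples must be non-empty")
    if D1.shape[1] != D2.shape[1]:
        raise ValueError("populations must share loci")
    r = 2.0  # number of populations
    n1, n2 = D1.shape[0], D2.shape[0]
    n_bar = (n1 + n2) / r
    n_c = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1.0)

    p1 = D1.mean(axis=0) / 2.0
    p2 = D2.mean(axis=0) / 2.0
    h1 = (D1 == 1).mean(axis=0)
    h2 = (D2 == 1).mean(axis=0)
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (n1 + n2)

    a = (n_bar / n_c) * (
        s2
        - (p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - h_bar / 4.0) / (n_bar - 1.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1 - p_bar)
        - (r - 1.0) / r * s2
        - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    poly = (p_bar > 0) & (p_bar < 1)
    denom = (a + b + c)[poly].sum()
    if not poly.any() or denom == 0:
        return float("nan")
    return float(a[poly].sum() / denom)


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def _pair_r2(h: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """r^2 = D^2 / (p1 q1 p2 q2) between locus pairs from phased haplotypes
    ``h`` (n_hap, m)."""
    pa = h[:, i].mean(axis=0)
    pb = h[:, j].mean(axis=0)
    pab = (h[:, i] * h[:, j]).mean(axis=0)
    D = pab - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, D * D / denom, np.nan)


def ld_r2_curve(
    haplotypes: np.ndarray,
    gmap: GeneticMap,
    max_cm: float = 30.0,
    bin_cm: float = 1.0,
    max_pairs: int = 200_000,
    maf_min: float = 0.05,
    rng: np.random.Generator | None = None,
    smooth: int = 3,
) -> pd.DataFrame:
    """Binned mean r^2 against genetic distance (cM).

    Pairs of polymorphic loci on the same chromosome within ``max_cm`` are
    sampled (at most ``max_pairs``), r^2 binned by distance, and the binned
    means smoothed with a centered moving average of ``smooth`` bins.
    Returns a DataFrame with columns distance_cm, r2, r2_smooth, n_pairs.
    """
    rng = rng or np.random.default_rng(0)
    h = haplotypes.reshape(-1, haplotypes.shape[-1]) if haplotypes.ndim == 3 else haplotypes
    f = h.mean(axis=0)
    keep = np.minimum(f, 1 - f) >= maf_min
    pos_cm = gmap.cumulative_pos() * 100.0
    chrom = gmap.locus_chrom
    loci = np.flatnonzero(keep)
    if loci.size < 2:
        raise ValueError("fewer than two polymorphic loci")
    # Sample locus pairs: anchor loci, partner within window on same chromosome.
    anchors, anchor_counts = np.unique(
        rng.choice(loci, size=max_pairs, replace=True), return_counts=True
    )
    pairs_i, pairs_j = [], []
    pos_keep = pos_cm[loci]
    for a, count in zip(anchors, anchor_counts):
        count = int(count)
        lo = np.searchsorted(pos_keep, pos_cm[a] + 1e-12)
        hi = np.searchsorted(pos_keep, pos_cm[a] + max_cm)
        cand = loci[lo:hi]
        cand = cand[chrom[cand] == chrom[a]]
        if cand.size == 0:
            continue
        pick = cand if cand.size <= count else rng.choice(cand, size=count, replace=False)
        pairs_i.append(np.full(pick.size, a))
        pairs_j.append(pick)
    i = np.concatenate(pairs_i)
    j = np.concatenate(pairs_j)
    r2 = _pair_r2(h.astype(np.float64), i, j)
    dist = pos_cm[j] - pos_cm[i]
    ok = ~np.isnan(r2)
    df = pd.DataFrame({"distance_cm": dist[ok], "r2": r2[ok]})
    df["bin"] = (df["distance_cm"] // bin_cm).astype(int)
    g = df.groupby("bin").agg(r2=("r2", "mean"), n_pairs=("r2", "size")).reset_index()
    g["distance_cm"] = (g["bin"] + 0.5) * bin_cm
    g = g.sort_values("distance_cm").reset_index(drop=True)
    g["r2_smooth"] = (
        g["r2"].rolling(smooth, center=True, min_periods=1).mean()
    )
    return g[["distance_cm", "r2", "r2_smooth", "n_pairs"]]


def ld_decay_distance(
    haplotypes: np.ndarray,
    gmap: GeneticMap,
    target_r2: float = 0.1,
    **curve_kwargs,
) -> tuple[float, pd.DataFrame]:
    """Distance (cM) where the smoothed LD curve decays to ``target_r2``.

    Linear interpolation between the bins flanking the first crossing from
    above; NaN (with the curve attached) when the curve never crosses.
    """
    curve = ld_r2_curve(haplotypes, gmap, **curve_kwargs)
    r2 = curve["r2_smooth"].to_numpy()
    d = curve["distance_cm"].to_numpy()
    below = r2 <= target_r2
    if r2.size == 0 or below.all():
        return 0.0, curve
    if not below.any():
        return float("nan"), curve
    k = int(np.argmax(below))  # first bin at/below target
    if k == 0:
        return float(d[0]), curve
    x0, x1 = d[k - 1], d[k]
    y0, y1 = r2[k - 1], r2[k]
    frac = (y0 - target_r2) / (y0 - y1) if y0 != y1 else 0.5
    return float(x0 + frac * (x1 - x0)), curve


# ---------------------------------------------------------------------------
# Accuracy
# ---------------------------------------------------------------------------

def selection_accuracy(ebv: np.ndarray, tbv: np.ndarray) -> float:
    """Pearson correlation between estimated and true breeding values;
    NaN when either vector is (near) constant or fewer than 3 individuals."""
    ebv = np.asarray(ebv, dtype=float).ravel()
    tbv = np.asarray(tbv, dtype=float).ravel()
    if ebv.size != tbv.size:
        raise ValueError("ebv and tbv must align")
    if ebv.size < 3 or np.std(ebv) == 0 or np.std(tbv) == 0:
        return float("nan")
    return float(np.corrcoef(ebv, tbv)[0, 1])


# ---------------------------------------------------------------------------
# Run summaries
# ---------------------------------------------------------------------------

@dataclass
class GenerationRecord:
    """Per-generation state of one breeding-scheme run."""

    generation: int
    calibration: bool
    years_elapsed: float
    hybrid_production: float
    accuracy: dict = field(default_factory=dict)  # (pop, trait) -> r
    additive_variance: dict = field(default_factory=dict)  # (pop, trait) -> var
    genetic_correlation: dict = field(default_factory=dict)  # pop -> r(BW, BN)
    mean_inbreeding: dict = field(default_factory=dict)  # pop -> F


@dataclass
class RunSummary:
    """Trajectories and endpoint summaries of a four-cycle run."""

    records: list[GenerationRecord]
    total_years: float
    cumulative_response_pct: float
    annual_response_pct: float
    delta_F_cumulative_pct: dict  # pop -> 100*(F4-F0)/F0 (relative scale)
    delta_F_annual_pct: dict  # pop -> above / total years
    delta_F_absolute: dict  # pop -> F4 - F0 (absolute alternative)
    table: pd.DataFrame = field(default=None, repr=False)


def summarize_run(records: list[GenerationRecord]) -> RunSummary:
    """Fold per-generation records into response and inbreeding summaries.

    Cumulative response = 100 * (production_4 - production_0)/production_0;
    annual response divides by total years.  Inbreeding rates are reported
    relative to generation-0 inbreeding (with an absolute-scale alternative,
    flagged when F_0 = 0).
    """
    if not records:
        raise ValueError("no generation records")
    recs = sorted(records, key=lambda r: r.generation)
    base = recs[0]
    last = recs[-1]
    years = last.years_elapsed
    if years <= 0:
        raise ValueError("total years must be positive")
    p0, p4 = base.hybrid_production, last.hybrid_production
    cum = 100.0 * (p4 - p0) / p0
    annual = cum / years

    dFc, dFy, dFa = {}, {}, {}
    for pop in base.mean_inbreeding:
        f0 = base.mean_inbreeding[pop]
        f4 = last.mean_inbreeding.get(pop, np.nan)
        dFa[pop] = f4 - f0
        if f0 > 0:
            dFc[pop] = 100.0 * (f4 - f0) / f0
            dFy[pop] = dFc[pop] / years
        else:  # flagged: relative scale undefined
            dFc[pop] = float("nan")
            dFy[pop] = float("nan")

    rows = []
    for r in recs:
        row = {
            "generation": r.generation,
            "calibration": r.calibration,
            "years": r.years_elapsed,
            "hybrid_production": r.hybrid_production,
            "response_pct": 100.0 * (r.hybrid_production - p0) / p0,
        }
        for (pop, trait), v in r.accuracy.items():
            row[f"accuracy_{pop}_{trait}"] = v
        for (pop, trait), v in r.additive_variance.items():
            row[f"addvar_{pop}_{trait}"] = v
        for pop, v in r.genetic_correlation.items():
            row[f"rg_{pop}"] = v
        for pop, v in r.mean_inbreeding.items():
            row[f"F_{pop}"] = v
        rows.append(row)
    return RunSummary(
        records=recs,
        total_years=years,
        cumulative_response_pct=cum,
        annual_response_pct=annual,
        delta_F_cumulative_pct=dFc,
        delta_F_annual_pct=dFy,
        delta_F_absolute=dFa,
        table=pd.DataFrame(rows),
    )
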