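# Methods

`rrgsim` is a forward-in-time stochastic simulator of reciprocal recurrent
selection (RRS) and reciprocal recurrent genomic selection (RRGS) for a
hybrid crop whose target trait is the product of two negatively correlated
additive components. The motivating system is oil palm, where bunch
production = bunch weight (BW) × bunch number (BN) and heterosis between
the Deli and La Mé breeding populations arises multiplicatively, without
dominance at the QTL level. This note documents the model, the defaults,
the numerical choices, and what the reduced-scale runs do and do not show.

## 1. Genome and meiosis

The genome is 16 linear chromosomes totalling 17 Morgans carrying 20000
equally spaced biallelic loci. Meiosis follows the Haldane model: per
chromosome a Poisson number of crossovers with mean equal to its length in
Morgans, crossover positions uniform, no interference, random start
haplotype per chromosome. Mutation is a symmetric per-locus allele flip
with probability 10⁻⁵ per meiosis (the rate is nominally "per bp", but the
simulation operates on discrete loci, so it is applied per locus).

Haplotypes are unpacked `uint8` arrays; at the study's largest transient
(13 500 hybrids tracked at QTL + panel loci) peak memory stays near
100 MB. Hybrids never reproduce, so their gametes are simulated only at
the tracked loci using a sub-map — the crossover process restricted to a
subset of loci has exactly the right joint law.

## 2. Base population

A single base population of 200 individuals mates at random (selfing
excluded) with **equal contributions** — every individual leaves exactly
two gametes — starting from exactly equifrequent alleles. Equal
contributions roughly double the effective size (Nₑ ≈ 2N), so
heterozygosity decays at ≈ 1/(4N) per generation; the unit tests check
this against an independent single-locus simulation of the same scheme.

With the nominal 2400 burn-in generations and μ = 10⁻⁵, mutation input
(4Nₑμ ≈ 0.016 per locus) cannot sustain appreciable polymorphism: the
equilibrium state is almost fully fixed. Desk-scale runs therefore default
to a **reduced burn-in of 800 generations** (about one coalescent time at
Nₑ ≈ 400), which leaves roughly half the loci segregating with a partially
drifted, edge-heavy spectrum — a state that matches the downstream
calibration statistics well (see §6). The 2400-generation configuration
remains available through the configuration file.

## 3. Trait architecture

Each trait has n_QTL ∈ {100, 500, 1000} QTL drawn among loci segregating
with MAF > 0.1 in the base population. A fraction p_QTL ∈ {0.60, 0.75,
0.90} of them (rounded) is pleiotropic: shared by both traits with effects
drawn from a bivariate normal with correlation ρ = −0.9. Trait-private
effects are univariate normal. Per-QTL effect variance is (base additive
variance)/n_QTL with base variances σ²ₐ(BW) = 6 and σ²ₐ(BN) = 12 — the BW
variance feeds BW effects and the BN variance BN effects (the source text
swaps the two labels in one sentence; the swap is treated as
typographical, which reproduces the published generation-0 variance
magnitudes).

Breeding values use the classical biallelic parameterisation: a genotype
with dosage d at a QTL of frequency p and substitution effect α
contributes (d − 2p)α; additive variance is Σ 2p(1−p)α². Phenotype =
15 + TBV + residual, with residual variances fixed once at
σ²ₑ = σ²ₐ,BP(1 − h²)/h² (h² = 0.8 ⇒ 1.5 for BW, 3 for BN), independent
across traits, constant across populations and generations. TBVs used for
phenotypes and selection are expressed against the *base-population*
frequencies, so population means carry the divergence signal; variances
and correlations are invariant to the frequency reference.

The published generation-0 h² values (~0.55–0.68) are mutually
inconsistent with the same tables' additive variances under these fixed
residuals (they imply ~0.35–0.45); we report realized
h² = σ²ₐ/(σ²ₐ + σ²ₑ) and calibrate on variances, not h².

## 4. Population history

From the base population: (i) random split into populations A and B of 100,
which evolve 100 generations under fitness-proportional selection
(sampling probability ∝ max(phenotype, 0)) on BW in A and BN in B; (ii) a
4-founder bottleneck from A ("Deli"), three generations of 25 random
mating, then expansion 50-50-60-75-100-150 with mass selection retaining
the top 70 % on the BW×BN phenotype product; (iii) a 19-founder bottleneck
from B ("La Mé") expanding 75-150 with 30 % retained; (iv) two
pedigree-era RRS cycles in which EBV are pseudo progeny tests — TBV mixed
with noise to a target accuracy of 0.8, then 0.9 — the top 20 per
population are chosen by expected cross value, and an 80 % half diallel
with selfing (168 crosses) produces 300 offspring per population
(generation 0).

Pedigree recording starts at the bottleneck founders; reported inbreeding
is diag(A) − 1 against that base, which reproduces the published
generation-0 levels (Deli ≈ 0.26, La Mé ≈ 0.13–0.14). The mixed models
see a shallower pedigree: four ancestor generations retained in Deli, two
in La Mé, as at generation 0 of the published design.

Replicates are filtered: runs are accepted only if Fst (Weir–Cockerham),
the TBV correlations, the additive variances and mean inbreeding fall
within ±2 SD windows around the published per-cell calibration values
(SDs floored at 0.02 because several are reported as 0.00), short-range LD
is higher in Deli than in La Mé, and no single QTL explains > 20 % of
additive variance. Window widths are configurable because the original
calibration tolerances were not published.

## 5. Breeding schemes and models

A scheme is strategy × calibration pattern × candidates × genotyped
hybrids. Every cycle with a progeny test ("G", 20 years): 120 parents per
population (random among the candidates when there are 300) are crossed in
an incomplete factorial of 300 interpopulation crosses (per-parent usage 2
or 3) with 45 offspring each — 13 500 phenotyped hybrids. Marker-only
cycles ("M", 6 years) select on GEBV predicted from the stored calibration.

* **RRS** — bivariate two-kernel GCA model: hybrid records carry one Deli
  and one La Mé parental effect with covariance (2×2 trait matrix) ⊗ 0.5·A
  per population; fixed effects are per-trait means only.
* **RRGS_PAR** — same model with population-specific VanRaden G matrices
  (observed allele frequencies, mean diagonal normalized to 1) on a
  2500-SNP panel drawn among loci with MAF > 4 % in the current parents.
  The panel is redrawn at every calibration.
* **RRGS_HYB** — single breeding-value vector for parents and hybrids with
  covariance Σ ⊗ H. The genomic block uses an origin-aware multiallelic G:
  each SNP becomes four allele classes (0/1 × Deli/La Mé origin), purebreds
  carry two copies of own-origin classes, hybrids one allele per origin
  (gametotypes are taken from simulation truth); centered class dosages are
  cross-multiplied, scaled by Σ p_c(1−p_c) and normalized to mean diagonal
  1. The exact multiallelic centering of the original is unpublished; this
  natural class-dosage extension is isolated in one function so it can be
  swapped. H⁻¹ = A⁻¹_all + [0 0; 0 G*⁻¹ − A22⁻¹] with unweighted blocks
  and G* = 0.99 G + 0.01 A22 (blending guarantees invertibility; the
  weight is configurable). Non-genotyped hybrids enter through A_all.

Variance components are the true simulated ones mapped to model scale (the
models predict, they do not estimate): GCA covariance = ¼ of the empirical
TBV covariance of the candidates, rescaled by the kernel's mean diagonal;
the untracked Mendelian-sampling half of the hybrid genetic variance is
folded into the residual (σ²ₑ + ¼(σ²ₐ,Deli + σ²ₐ,LaMé) per trait). The
single-step model uses the across-population mean TBV covariance with
residual σ²ₑ. An optional dense bivariate EM-REML (`estimate_varcomps_em`)
is provided and validated by parameter recovery, but is off by default.

Marker-only prediction extends the relationship machinery with the new
candidates' genotypes (G recomputed on the combined genotyped set; H
rebuilt over the grown pedigree) and re-solves against the stored
phenotype records.

Selection ranks each candidate by the expected bunch production of its
cross with the opposite population's mean candidate:
(μ̂_BW + g_BW + ḡ_BW)(μ̂_BN + g_BN + ḡ_BN), fitted means included (a
deviation-only product is sign-unstable; the greedy joint-cross
alternative the wording could also support is not implemented). The top 20
mate in the 80 % half diallel with selfing; 120 candidates means one
offspring for 120 of the 168 crosses, 300 means one or two per cross (so
most candidates have exactly one full sib). Response is measured as the
mean true cross value over the selected 20×20 factorial,
(15 + ½TBV_Deli + ½TBV_LaMé) per trait multiplied across traits, relative
to the unselected cycle-1 progeny-test crosses (generation 0); inbreeding
rates are reported relative to generation-0 inbreeding (ΔF_c, ΔF_y), with
the absolute increment as an alternative since the published wording
admits both.

## 6. Solvers and numerics

The GCA mixed-model equations are assembled dense (≤ ~1200 unknowns) and
solved directly. The single-step system (~29 000 unknowns bivariate) is
solved matrix-free by Jacobi-preconditioned conjugate gradients at
relative tolerance 10⁻⁸; H⁻¹ is held as sparse Henderson A⁻¹ plus a dense
correction on the genotyped block (≤ 2540²). A_all⁻¹ needs inbreeding only
for individuals that are parents, so F is computed on the purebred
ancestor closure; hybrids are terminal. Ties in every selection and
sampling step break by the run's seeded generator; all phases derive their
generators hierarchically from one master seed (master → phase →
replicate), so any phase is re-runnable in isolation and a (config, seed)
pair reproduces outputs byte-for-byte.

## 7. Reduced scales, and what the tests show

The published grid (25 schemes × 9 architectures × 5 replicates at 2400
burn-in generations) is a cluster-scale computation. The packaged runs use
three tiers, chosen once:

* **tiny/small fixtures** (`make_toy_fixture`) — minutes-per-suite CI
  scale: 200–1000 loci, scaled-down history with the same phase structure,
  and a mutation rate of 10⁻⁴ so toy genomes stay polymorphic. These
  exercise contracts and invariants, not published values.
* **desk-scale study** (`make_study_base` / `make_study_replicate`) — full
  genome, full history, full design sizes (300×45 progeny tests, 2500-SNP
  panels, 1700 genotyped hybrids), burn-in reduced to 800 generations; a
  replicate runs in ~1 minute after the shared ~90 s burn-in. At this
  scale the generation-0 calibration statistics land close to the
  published ones (Fst ≈ 0.47–0.55, r_g ≈ −0.7…−0.8, additive variances ≈
  1.0/2.2, inbreeding ≈ 0.28/0.14), and the accuracy structure reproduces:
  progeny-tested RRS parents ≈ 0.93–0.96 (published 0.967), single-step
  calibration ≈ 0.94 (0.934), marker-only candidates ≈ 0.73–0.77 for
  RRGS_HYB1700 (0.748 ± 0.058) and ≈ 0.63 for RRGS_PAR (0.615 ± 0.101).
* what reduced runs do **not** show: grid-mean response contrasts (e.g.
  0.45 vs 0.26 %/yr) carry replicate CVs near 0.27 and need ≥ 5 replicates
  per cell; single desk-scale runs only support the directional ranking.

The synthetic generator emulates neutral biallelic loci on a uniform map
with a stylized two-population history. It does not emulate sequence
context, variable recombination or mutation landscapes, dominance or
epistasis, genotyping error, or the real pedigree of any breeding program
— conclusions about those features cannot be drawn from passing tests.

## 8. Known limitations

* Pedigree–genomic compatibility in H is taken as published (no τ/ω
  weighting, no metafounders); with few markers the gametic relationships
  of hybrids can be biased, which is visible as the weaker performance of
  RRGS_HYB with only 300 genotyped hybrids.
* The LD decay summary is a binned, moving-average curve with a linear
  interpolation at r² = 0.1; absolute values depend on bin width (1 cM
  default).
* Dense pedigree blocks (tabular A) are O(n²); fine up to a few thousand
  ancestors, which the ancestor-closure trimming guarantees here.
* ANOVA/Tukey comparisons across the scheme grid are out of scope; the
  per-replicate CSV exports are the hand-off point.
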