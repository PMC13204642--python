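# Methods

## The model

`condfdr` implements pleiotropy-informed discovery from GWAS summary
statistics. Given two genetically correlated traits — a *primary* trait whose
risk loci are sought and a *conditioning* trait whose association p-values
carry shared signal — the conditional false discovery rate of SNP *i* is
estimated as

    condFDR(p1 | p2) = p1 / F̂(p1 | P2 ≤ p2),    capped at 1,

where `F̂` is the empirical conditional cumulative distribution function of
primary p-values among SNPs whose conditioning p-value is at most `p2`. If
SNPs with small `p2` are enriched for true primary associations, `F̂` rises
faster than the uniform cdf in those strata and the same nominal `p1` earns a
smaller condFDR — the re-ranking that buys power over an unconditional FDR at
identical sample size. The null proportion π₀ is fixed at 1, which can only
make the estimate conservative. The method is model-free: no specific
pleiotropic mechanism is assumed.

The estimator is deliberately an *empirical-Bayes tail FDR*: with all
conditioning p-values equal it reduces exactly to the unconditional empirical
FDR `p1 · n / rank(p1)`, and `condFDR ≥ p1` always holds because `F̂ ≤ 1`.

## Two scoring paths

**Exact mode** evaluates the definition for every SNP by two-dimensional
dominance counting with inclusive ties on both axes: `n2 = #{j ∈ S : p2_j ≤
p2_i}`, `n12 = #{j ∈ S : p1_j ≤ p1_i, p2_j ≤ p2_i}` over the fitting set `S`,
computed in O(n log n) with an offline sweep over p2 and a Fenwick tree over
p1 ranks. A literal O(n²) double loop is retained (`brute_force_condfdr`) and
the two are asserted identical in the test suite. A SNP whose conditioning
stratum is empty (possible only for masked SNPs) falls back to the
unconditional empirical FDR.

**Lookup mode** (the default) fits `F̂` once on a grid: nested conditioning
thresholds −log₁₀ p2 ∈ {0, 1, 2, 3, 4, 5} crossed with 301 points on
−log₁₀ p1 ∈ [0, 30]. The resolution is enough to place the condFDR < 0.01
decision boundary while keeping strata populated at desk-scale SNP counts.
An empty stratum inherits the next-coarser stratum's cdf; the code never
extrapolates to a tighter stratum.

Numerical choices in lookup scoring, each made for calibration rather than
convenience:

* **Log-scale interpolation.** Per-SNP scores come from bilinear
  interpolation of the monotonized −log₁₀ FDR surface in (−log₁₀ p1,
  −log₁₀ p2). The surface spans many orders of magnitude; interpolating on
  the raw scale systematically overestimates the conditional cdf in sparse
  tail cells and understates the FDR. In simulation, raw-scale interpolation
  produced a measurable excess of borderline null calls that the log-scale
  rule eliminates.
* **No support, no discovery.** Grid cells at p-values smaller than anything
  observed in their stratum carry no empirical mass. Queries that land there
  score condFDR 1 rather than an extrapolated value.
* **Monotonization.** Within each stratum the FDR surface is made
  non-decreasing in p1 by raising larger-p1 cells (the conservative
  direction), restricted to the empirically supported cells. The final score
  is floored at p1 and capped at 1.
* **Agreement across modes.** On well-populated inputs (20,000 SNPs) lookup
  scores match exact scores within 10 % relative for ≈99 % of SNPs. On small
  inputs (≈2,000 SNPs) agreement drops because the exact estimator conditions
  at each SNP's own p2 and therefore tracks realization-level fluctuations
  that a six-threshold stratum grid intentionally smooths; this is a
  variance/approximation trade-off, not an implementation gap.

An optional random LD-pruning average (off by default) refits the surface on
r² < 0.1 subsets over several seeded iterations and averages the cdf grids,
de-weighting LD clusters; every seed is recorded in the lookup metadata.

## Region masking

SNPs inside the extended HLA region (chr6:25,000,000–34,000,000) and the
8p23.1 inversion polymorphism (chr8:6,300,001–12,800,000; GRCh37 cytoband,
configurable) are excluded from cdf fitting — their extreme long-range LD
would inflate apparent enrichment — but they are still scored, so loci there
remain discoverable. Masking is implemented so that the fitted surface and
all unmasked scores are exactly invariant to the masked SNPs' statistics
(verified by a permutation test).

## Intergenic inflation control

Genomic-control λ is the median squared z score over intergenic SNPs divided
by 0.4549364 (the χ²₁ median); intergenic SNPs are presumed depleted of true
signal, so λ measures technical/polygenic inflation. The primary trait is
rescaled as z₁/√λ with p₁ recomputed before cdf fitting. When fewer than
1,000 intergenic SNPs are available the estimate falls back to all SNPs (or
raises, if the fallback is disabled). Adjusting the conditioning trait is
supported but off by default. Injected inflation λ* ∈ {1.1, 1.3, 2.0} is
recovered within ±0.03 at 50,000 SNPs, and re-estimating λ after adjustment
returns 1.00 ± 0.02.

## Loci

Significance is condFDR strictly below 0.01 (a deliberately conservative
threshold). Significant SNPs are clumped greedily: repeatedly promote the
unassigned SNP with the smallest condFDR (ties: p, chromosome, position) to
lead and absorb unassigned SNPs within ±10,000 kb with r² ≥ 0.1 to the lead.
Unknown LD lookups count as r² = 0 — quasi-independence is the conservative
assumption for clumping. Locus spans are then merged transitively when their
closest edges lie within 250 kb (span distance, the stricter reading of the
merge rule); the merged lead is the member with the smallest condFDR.

Runs against several conditioning datasets are combined by the same
span-merge rule; the reported lead and condFDR come from the dataset
achieving the lowest condFDR and the provenance lists every contributor.
Leads are expanded with LD proxies (r² strictly > 0.8) for gene mapping.
Novelty flags are a configurable positional rule (no known locus within
250 kb of the span) against a user-supplied table — a proxy for the
literature review an actual study performs, and reported as such.

## Positional gene mapping

Lead and proxy SNPs outside the extended HLA region map to protein-coding
genes containing them (distance 0) and to genes within a 10 kb flanking
window (configurable; containing genes are reported regardless of the
window). Gene models are read from BED (0-based half-open, converted) or a
minimal GFF3 subset (`gene` features; Name/gene_name and biotype/gene_biotype
attributes). eQTL and chromatin-interaction (functional) mapping are out of
scope: they require external expression and Hi-C resources.

## Synthetic data

The generator works at the z-score level. SNPs are laid out over 22
chromosomes and partitioned into LD blocks with AR(1) correlation `R`
(ρ = 0.9, block size 50 by default; blocks never straddle chromosomes).
Within a block,

    z_t = R (√n_t · β_t) + η_t,    η_t ~ N(0, R),   t ∈ {1, 2},

the standard single-trait summary-statistic model with standardized effects
β. Effects follow a four-component mixture: null / trait-1-only (π₁₀ = 0.002)
/ trait-2-only (π₀₁ = 0.002) / shared (π₁₁ = 0.001, bivariate normal with
correlation 0.5). Effect scale 0.05 at n = 10,000 samples makes a typical
causal |z| ≈ 5 — the borderline-significance regime the method is designed to
mine; the trait-specific fractions are set at twice the shared fraction so
that conditioning is informative but most conditioning signal is irrelevant
to the primary trait, the realistic hard case. Multiplicative χ² inflation
(λ ≥ 1) can be injected into trait 1 to exercise the genomic-control
machinery; the emitted LD source reports R² entries. Everything is
reproducible from a single seed.

What the generator does **not** emulate: minor-allele-frequency-dependent
architectures, population stratification (inflation is injected as a scalar,
not generated by structure), sample overlap between conditioning datasets
(the real use case has shared controls), imputation noise, or strand/allele
errors beyond what the harmonization tests construct directly. Passing tests
therefore demonstrate the statistical machinery under an idealized z-model,
not robustness to those artifacts.

## Problem sizes and study conditions used by the checks

Error control: 100 replicates of 20,000 independent pure-null SNPs; the
default scorer's mean false-discovery proportion at condFDR < 0.01 is 0.00
(a call-free run counts as 0; with π₀ = 1 every call is false). Power: 100
replicates of 20,000 independent SNPs with the default mixture; conditional
true discoveries are compared against the unconditional empirical FDR —
both evaluated in exact mode, the unconditional arm being the all-equal-p2
reduction of the same counting definition, so the two arms differ only in
conditioning. Oracle equivalence uses 2,000-SNP pairs (exact vs double loop)
and 50-SNP clumping instances (greedy vs an independently coded reference).
These sizes keep the full suite under a minute of estimator time while
leaving the Monte-Carlo margins comfortably wider than the asserted bounds.

## Known limitations

* The exact (per-SNP) estimator is slightly anti-conservative in the extreme
  tail of a pure-null pair: the SNPs with the very smallest conditioning
  p-values sit in tiny strata where `F̂` is estimated from a handful of
  points, and a harmonic-sum argument (confirmed by simulation) puts its
  expected spurious borderline calls near 0.1 per 20,000-SNP null pair. The
  stratified lookup is the default precisely because its coarse, nested
  strata do not form per-SNP micro-strata; use exact mode for oracle-style
  comparisons, lookup mode for discovery.
* condFDR assumes exchangeability across SNPs; LD makes neighbouring
  statistics dependent, which the optional pruning average mitigates but
  does not remove.
* Conjunctional FDR (discovery in both traits jointly), local fdr variants
  and covariate-adjusted FDR are out of scope.
* Liftover is out of scope: all inputs must share one declared genome build.
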