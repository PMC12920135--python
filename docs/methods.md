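# Methods

This note documents the statistical machinery in `admixfreq`: the models,
their assumptions, the defaults and why, the numerical conventions, and
what the synthetic-data experiments do and do not establish.

## Ancestry masking and asF

Local-ancestry calls assign every (haplotype, position) an ancestry code;
masking for ancestry *x* keeps an allele iff its haplotype carries *x* at
that site, setting everything else to missing. The ancestry-specific
frequency is the plain allele frequency of the masked matrix,
asF_x = p/(p+q) over called alleles.

Conventions that matter:

- **Undefined ≠ zero.** A (variant, stratum, ancestry) cell with zero
  called alleles is reported as NaN with `called_count = 0`. With a
  minor-ancestry genome fraction of a few percent, empty cells are routine
  and folding them into 0 would fabricate fixed-reference sites.
- **Coordinates.** VCF positions are 1-based; MSP intervals are half-open
  `[spos, epos)` on the same axis, so a site at one window's `epos` belongs
  to the next window. Tests assert this convention.
- **Uncovered sites** (no tract for a haplotype) are masked under *every*
  ancestry — conservative, and logged. The same applies to segments of the
  minor East Asian component if the caller never assigns it.
- **Phase is required.** Local ancestry is a per-haplotype quantity;
  unphased heterozygotes are a hard error by default (a permissive mode
  sets them missing).
- **Conservation.** Because every called allele lies on exactly one
  ancestry, per-site alt and called counts across the K masks partition the
  unmasked counts exactly. This is the core correctness invariant and is
  tested exhaustively (property-based and on 1,000-site fixtures).

Carrier summaries (carrier % = ≥1 effect allele, homozygote % = 2) exclude
individuals with any missing allele at the site from the denominator; the
convention is a package choice, documented rather than inherited.

## Weir–Cockerham Fst and asFst

Between-stratum differentiation uses the Weir & Cockerham (1984)
variance-component estimator. Two reductions are exposed:

- **Haploid path** (masked data): masking breaks the pairing of an
  individual's two alleles, so called alleles are treated as haploid
  observations. Components come from the two-level nested ANOVA moment
  estimators, a = (MSA − MSW)/n_c, b = MSW, θ̂ = a/(a+b).
- **Diploid path** (unmasked genotypes): the full three-component
  estimator with the heterozygosity term c.

Sites where some population has fewer than 2 called alleles, or where
a+b+c = 0 (no variation), are excluded and counted. Negative per-site θ̂
are retained — clipping would bias multi-site summaries. The headline
multi-site summary is the ratio-of-sums Σa/Σ(a+b+c) ("weighted"), with the
mean of per-site ratios reported alongside; the two can differ materially
when per-site sample sizes vary, which masked data guarantee.

Correctness is established against an *independently coded* implementation:
a literal per-observation nested-ANOVA (sums of squares over 0/1
indicators, three-level for the diploid case) agrees with the production
vectorized estimator to 1e-12 on 1,000 random instances, and fixed
differences return θ̂ = 1 exactly.

The asFst contrast between two ancestries (per-variant θ̂ vectors from the
Indigenous and European masks) uses Welch's unequal-variance two-sided t
test by default, with the 95% CI reported on mean(EUR) − mean(IND). A
paired mode exists; independent is the default because per-variant pairing
is broken wherever a variant is defined in only one mask.

## The GLM scan

Per variant, the response is the individual's alternate-allele count
(0/1/2) modelled as binomial with 2 trials and a logit link, fit by IRLS
(statsmodels). Predictors, all z-scored: Indigenous ancestry fraction,
African ancestry fraction, latitude, longitude. European ancestry is
excluded: with four fractions summing to one and East Asian near zero, it
is nearly the mirror of the Indigenous fraction and would make the design
singular. Ancestry fractions are tract-length fractions from the
local-ancestry calls themselves, not a separate clustering run.

The binomial-on-counts choice (over Gaussian-on-dosage, which is available
as `family="gaussian"`) keeps fitted frequencies in [0,1] and makes
coefficients log-odds of allele frequency per SD of predictor.
Standardization does not change Wald p-values (affine invariance — tested
to 1e-8); it is kept for comparability of effect sizes across terms.

A variant's *category* is the exact subset of terms with Wald p < α = 0.05
— deliberately uncorrected, since the classification is descriptive; a
Benjamini–Hochberg mode (`correction="bh"`) is available. Monomorphic
variants, fits with < 5 callable individuals, and non-converged or
separated fits (detected by exploding standard errors, > 1e3 on the logit
scale) are excluded with recorded reasons, so category counts sum to the
number of *converged* variants.

Calibration and recovery, verified by simulation in the test suite: with
10,000 null variants (no predictor dependence, n = 400) each term's type-I
rate lies in [0.04, 0.06]; a logit-scale ancestry effect of 0.5 at
n = 2,000 is recovered with |bias| below 3 Monte-Carlo SEs.

## The synthetic cohort generator

The generator is a single-pulse admixture approximation, not a coalescent:

- **Tracts.** For each haplotype and chromosome of genetic length L,
  breakpoints are a Poisson process of rate g per Morgan (default g = 16
  generations, matching post-colonial admixture depth of roughly five
  centuries at ~30 years/generation), and segment ancestries are i.i.d.
  draws from the stratum's proportion vector. Expected genome-wide ancestry
  fractions equal that vector; tract lengths are exponential with mean
  1/g Morgans. Real tract-length distributions from continuous or multi-wave
  admixture, and correlations between neighbouring segments, are not
  modelled.
- **Defaults.** 6,011 diploid individuals (a biobank-scale default) and
  nationwide proportions (AFR, EUR, EAS, IND) = (0.04, 0.30, 0.01, 0.65).
  Geographic structure is a linear interpolation of proportion vectors
  between a southern (Indigenous-rich) and a northern (European-rich)
  anchor along latitude; longitude is placed non-monotonically so the two
  geographic predictors are not collinear by construction.
- **Alleles.** Bernoulli(f_k) given the covering tract's ancestry k, with
  per-site, per-ancestry frequencies; one ancestry's frequencies can vary
  by stratum (`regional_ancestry`/`regional_freqs`) to emulate
  subcontinental substructure within a source population. No LD, no
  selection, no genotyping error.
- **Coordinates.** A constant 1 cM/Mb map (1 Morgan = 1e8 bp); all
  breakpoints and sites sit on the 1 bp lattice so Morgan and bp
  representations convert exactly and file round-trips are lossless.
- **Caller noise.** A row-stochastic K×K confusion matrix C (rows = true
  ancestry, columns = assigned). The genome is cut into fixed windows
  (default 0.2 cM, the granularity of window-based callers), additionally
  split at true tract boundaries so each window has one true ancestry; each
  window's assigned ancestry is drawn independently from C's row. Window
  width and the independence assumption are package choices — callers'
  errors are in reality autocorrelated along the genome, which would
  *increase* the variance (not the mean) of downstream asF errors. Under
  this model the expected estimated asF has the closed form
  E[asF_x] = Σ_y π_y C[y,x] f_y / Σ_y π_y C[y,x] (a convex combination of
  the true per-ancestry frequencies), which the error experiment verifies
  to within 3 Monte-Carlo SEs across a 5-point MAF grid; with an identity
  matrix the estimator is unbiased at every grid point.

Because the generator produces exactly the model the estimators assume,
passing tests establish *internal* correctness (the statistics compute what
they claim on data satisfying their assumptions) — not robustness to LD,
phasing error, platform artifacts, or realistic recombination maps, none of
which are simulated.

## Variant curation

Variant identity is rsid first, falling back to `chrom:pos:ref:alt`; an
rsid mapping to several loci triggers a warning and the positional key.
Records shared by several source databases collapse to one row carrying the
sorted union of source labels, the strongest PharmGKB level, and the union
of drug associations. PharmGKB evidence is the total order
1A > 1B > 2A > 2B > 3 > 4; `top_drug` picks the maximal-evidence drug with
lexicographic tie-break (documented, deterministic). "Without conflicting
interpretations" is operationalized as: the significance string neither
contains "conflicting" nor asserts benign and pathogenic simultaneously.
The actionable flags apply no frequency threshold; the ≥ 5% MAF filter
(boundary retained at exactly 0.05) applies only to the frequency analyses,
computed on the ALL-ancestry national frequency.

Input dialects are simplified TSV schemas defined by this package (headers
in `catalog.py`); live database exports are out of scope.

## Pipeline and determinism

One seed governs a run; per-stage seeds derive from it deterministically.
Every output file is hashed (SHA-256) into `manifest.json`; a stage whose
outputs exist with matching hashes is skipped, so deleting an intermediate
re-executes only that stage and its downstream. Fixed seed ⇒ byte-identical
manifests, verified end-to-end in the tests.

## Problem sizes used in the validation suite

Simulation checks are sized for a laptop-class run: the tract-proportion
check uses 1,000 haplotypes on ≥ 30 Morgans; the asF recovery check uses
6,011 diploid individuals × 50 replicate sites; the confusion-bias
experiment uses 1,000 individuals × 20 replicates per 5-point MAF grid; GLM
calibration uses 10,000 null variants at n = 400 and recovery uses 120
variants at n = 2,000. All stochastic comparisons use 3 Monte-Carlo
standard-error bands computed from the replicates themselves.

## Known limitations

- No coalescent history, LD, selection, realistic recombination maps,
  phasing or genotyping error in the generator.
- No confidence intervals on asF; no bootstrap or jackknife CIs on Fst;
  no hierarchical (AMOVA-style) Fst.
- No mixed models or kinship correction in the GLM scan (the response is
  allele count, not a phenotype).
- Curation operates on the package's own TSV dialects; star-allele calling
  and live database queries are out of scope.
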