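# Methods

## Model and assumptions

`mrkit` implements two-sample Mendelian randomization on GWAS summary
statistics. The structural model is the standard linear
instrumental-variable one: for SNP j with true exposure effect γ_j, the
true outcome effect on the log-odds scale is

    Γ_j = θ·γ_j + α_j,

where θ is the causal effect of one unit of exposure and α_j is a
horizontal-pleiotropy effect (zero for a valid instrument). The three
IV assumptions are relevance (γ_j ≠ 0, enforced by the significance
filter), independence from confounders (approximated by an offline
exclusion list of known-confounder SNPs) and exclusion restriction
(α_j = 0, probed by the Egger intercept, MR-PRESSO and Steiger
filtering rather than assumed). The two samples are assumed
non-overlapping, so exposure and outcome sampling errors are
independent.

Estimators and their validity conditions:

- **Fixed-effect IVW** assumes all instruments valid and a single θ;
  it is the efficient weighted mean of the Wald ratios.
- **Multiplicative random-effects IVW** keeps the same point estimate
  and rescales the SE by √(Q/(k−1)). The scale is *not* floored at 1:
  under-dispersed instrument sets yield a smaller SE than the fixed
  model. This matches the behaviour of the widely used R
  implementation, and is visible in published analyses where
  random-effects p-values are smaller than fixed-effect ones; flooring
  is available via `floor_dispersion=True`.
- **Weighted median** is consistent when instruments carrying more than
  half the total weight are valid. The estimate interpolates the
  ordered ratios at standardized cumulative weight 0.5 with
  s_j = (cum_j − w_j/2)/Σw; the SE is a parametric bootstrap
  (default 1000 draws, seed 0) that redraws both exposure and outcome
  effects and re-evaluates the weighted median with the original
  weights.
- **MR-Egger** relies on the InSIDE condition (instrument strength
  independent of direct effects). Instruments are oriented so every
  exposure effect is positive before fitting — the intercept is
  meaningless without a sign convention. Inference uses t(k−2) with the
  residual variance unfloored; IVW inference uses normal quantiles.
- **MR-PRESSO** simulates the null distribution of the leave-one-out
  weighted residual sum of squares (weights 1/σ_Yj²). Defaults:
  1000 replicates, empirical p-values with the (1+#)/(n_sim+1)
  correction (never zero), per-SNP p-values Bonferroni-multiplied by k,
  outliers flagged below 0.05 adjusted. The corrected estimate is fixed
  IVW on the unflagged SNPs; the distortion test compares the observed
  raw-vs-corrected change against removal of random subsets of the same
  size, and is only reported when outliers exist. Instruments are
  processed in sorted-id order so the report is invariant to input
  ordering and bit-reproducible given a seed.

## Harmonization conventions

Alleles are compared case-insensitively; indels and multi-allelic rows
are rejected at parse time. Outcome records reporting the swapped
allele pair have their effect sign flipped and frequency complemented.
Palindromic (A/T, C/G) pairs carry no strand information in their
letters, so they are oriented by allele-frequency agreement — both
sides' minor-allele frequencies must be ≤ 0.42 (configurable), else the
SNP is excluded. No reference-panel strand inference and no proxy
lookup are attempted.

## Instrument selection

The QC pipeline applies, in order: p < 5×10⁻⁸ significance filter;
greedy LD clumping (r² > 0.1 within 10,000 kb discarded, best p kept,
ties broken by base-pair position then SNP id); MAF > 0.01 screen;
harmonization; Steiger directionality filter; optional exclusion list.
The clump consumes a user-supplied LD r² matrix — computing LD from
genotype panels is out of scope. For the Steiger test the outcome-side
variance explained of a binary trait uses the observed-scale
approximation r² = z²/(z²+N); note the exposure-side formula
2·EAF(1−EAF)β² / (2·EAF(1−EAF)(β²+se²N)) algebraically reduces to the
same z²/(z²+N), the EAF factor cancelling, so the two conventions
coincide and the binary/continuous switch is documentation only.

The printed form of the R² formula in the literature this package
mirrors contains a typographical mis-parenthesization; the implemented
denominator is the standard 2·EAF·(1−EAF)·(β² + se²·N).

## Power calculations

The binary-outcome power model is the mRnd non-centrality
approximation. An odds ratio OR at case fraction K is first attenuated
to the observed-scale coefficient b = K(OR/(1+K(OR−1)) − 1); the
instrumented association has NCP = N·R²·b²/(K(1−K) − b²) and two-sided
power Φ(√NCP − z_{1−α/2}). `detectable_or` inverts this in closed form,
returning the harmful and protective ORs at the target power; the two
are exact inverses of `power_at_or` (round-trip to 10⁻¹⁰). The
attenuation step is essential: with total R² = 12.8% the four reference
cohorts give detectable ORs 1.039/1.043/1.052/1.065, reproducing the
published values to three decimals, whereas treating the detectable
effect directly as a log-OR would give 1.040 and 1.067 for the extreme
cohorts. Solved on the protective side the formula gives
0.962/0.958/0.949/0.936, one unit in the third decimal above the
published companion values, which appear to be truncated rather than
rounded; the package reports the exact solutions. The
continuous-outcome branch is a stub.

## Synthetic data generator

The generator emulates the regime of a protein-exposure MR study:
7 SNPs, exposure GWAS of n = 997 with total variance explained 12.8%,
binary outcome cohorts of 184,305–260,405 with case fractions
0.066–0.33, true θ = −0.03 by default. Frequencies are uniform on
(0.1, 0.9); true exposure effects are positive (the effect allele is
labelled as the exposure-increasing one), drawn uniform on (0.5, 1.5)
and rescaled so Σ 2p(1−p)γ² equals the R² target exactly — bounding
effects away from zero keeps every instrument relevant, which matters
because ratio estimators degenerate as γ→0. Standard errors follow the
standard GWAS approximations se_X ≈ (2p(1−p)n_X)^(−1/2) and
se_Y ≈ (2p(1−p)n_Y K(1−K))^(−1/2). Pleiotropy α_j is drawn
independently of γ_j (InSIDE holds by construction); outliers are
injected by shifting the first `n_outliers` observed outcome effects by
a stated number of outcome SEs. An optional fraction of SNPs is made
palindromic to exercise harmonization, and a block-constant LD matrix
can be emitted for clump testing.

What the generator does *not* emulate: LD between instruments, sample
overlap, non-collapsibility of the odds ratio (outcome effects are
generated directly on the log-odds scale, so the binary-trait
attenuation present in real logistic-regression GWAS is absent), allele
frequency differences between cohorts, and winner's-curse bias from
selecting instruments in the same sample. Passing recovery tests on
this generator therefore demonstrates correctness of the estimators
under their stated assumptions, not robustness to those additional
real-data features.

### Simulation scenarios used by the test suite

Scenario parameters not pinned down elsewhere were fixed once, on the
following reasoning:

- *Type-I error and parameter recovery* run at the default 7-SNP
  preset (1000 and 500 replicates). The balanced-pleiotropy recovery
  scenario uses pleiotropy SD 0.01, comparable to the per-SNP outcome
  sampling SE (≈ 0.007) — large enough to matter, small enough to be
  realistic for a set of QC-surviving instruments. At this regime the
  mean per-SNP F statistic is ≈ 18, so first-order Wald ratios carry a
  known ≈ 5% weak-instrument attenuation toward zero; the recovery
  check (within 3 Monte-Carlo SEs of θ) accommodates this but the bias
  is real and documented.
- *Egger intercept recovery* (mean pleiotropy 0.05, SD 0.02, 100 SNPs,
  200 replicates) uses a consortium-scale exposure GWAS
  (n = 50,000, per-SNP F ≈ 64). A 100-SNP panel sharing R² = 12.8% at
  n = 997 would have per-SNP F ≈ 1.3; such SNPs are not valid
  instruments (they would fail the relevance filter), and their
  frequent sign errors interact with the positive-orientation
  convention to attenuate the intercept — an instructive failure mode,
  but not a test of a correctly specified analysis.
- *MR-PRESSO rates* use 20 SNPs with one 10-SE outlier (flag rate) and
  the clean 20-SNP null (false-flag rate), 200 replicates at
  n_sim = 1000.

These sizes keep the full suite under ten seconds on one CPU while
leaving Monte-Carlo error well below the margins being asserted.

## Pipeline conventions

The end-to-end driver records every threshold, seed and method default
in a JSON manifest; the manifest hash certifies bit-identical reruns.
Estimates crossing the Bonferroni level 0.0125 (four primary tests:
two outcomes × two cohorts) are flagged; ORs are formatted to two
decimals and p-values to three significant digits in the formatted
columns, alongside full-precision numeric columns. When the input is
simulated, the instruments emulate an already-selected panel, so the
discovery-stage significance filter defaults to pass-through (an
explicit `selection.p_threshold` overrides this); MAF, harmonization
and Steiger stages still run. Meta-analysis combines the primary
estimator across cohorts sharing an outcome label, with the two-cohort
Cochran's Q reported descriptively.

## Degenerate inputs and tie-breaks

Single-instrument IVW degenerates to the Wald ratio; a zero exposure
effect is an error (undefined ratio); zero spread in exposure effects
makes the Egger design singular (error); weighted-median and Egger
require ≥ 3 and MR-PRESSO ≥ 4 instruments. Q = 0 yields I² = 0.
`power_at_or(OR = 1)` returns α/2 with a warning. Clumping ties on
p-value break by position then id; all orderings in the package are
deterministic given seeds.

## Known limitations

First-order Wald SEs ignore exposure-side uncertainty (NOME); no SIMEX
correction for Egger, no mode-based or multivariable estimators, no
correlated-instrument IVW; LD must be supplied, not computed; the
confounder screen is a static exclusion list rather than a phenome
lookup.
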