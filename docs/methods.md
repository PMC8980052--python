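# Methods

`tbimine` implements a matched-cohort diagnosis-code mining procedure for
traumatic brain injury (TBI) and the synthetic cohorts used to validate
it.  This note records the statistical model, the defaults and why they
were chosen, and the known limits of what the synthetic validation shows.

## Study design being modelled

The analysis targets 1:1 matched case-control data from hospital visit
records: each TBI case is matched to one reference patient on sex, age,
residence (urban/rural) and income quintile, and every visit carries a
list of ICD-10 diagnosis codes.  Two phases are defined per patient
relative to an index date — the case's first TBI-coded visit, or the
reference's rank-midpoint visit:

* **event window** — `[index − 30 d, index + 30 d]`, inclusive on both
  ends, i.e. 61 calendar days;
* **pre-injury phase** — `[index − 5 y, index − 31 d]`, calendar-year
  arithmetic.

Codes are truncated to their first three characters (one letter, two
digits) and binarised per patient per phase; the provisional codes U98
and U99 are dropped.  Pairs are split 50/25/25 into train/validation/test
at the pair level, so matching is never broken by splitting.

Where the "midpoint" of an even visit count is ambiguous we take the
earlier of the two middle visits; ties for the earliest TBI-coded visit
break on stable input order after sorting by date.  Both rules are
deterministic and configurable.

## Screening stage

Each code is tested for case/reference imbalance with the matched McNemar
test, which depends only on the discordant pair counts `b` (case-only
exposed) and `c` (reference-only exposed):

* `b + c ≥ 25`: continuity-corrected chi-square `(|b−c|−1)² / (b+c)`,
  one degree of freedom;
* `b + c < 25`: exact two-sided binomial test with `b ~ Bin(b+c, ½)`.

The hybrid threshold of 25 is the standard exact-vs-asymptotic rule;
the statistic is always reported in the chi-square form with a branch
flag.  P-values over all codes are adjusted with the Benjamini-Yekutieli
step-up (chosen over Benjamini-Hochberg because binarised diagnosis codes
are arbitrarily dependent), and a code is retained when its q-value is
below 0.05 **and** its odds ratio exceeds 1.  The default odds ratio is
the conditional (discordant-ratio) estimate `b/c`, which respects the
matching; the marginal 2×2 estimate is also emitted because published
frequency tables are marginal.  A Haldane-Anscombe +0.5 handles zero
cells.  Codes retained in the training split must replicate in the
validation split before entering the factor stage.

The index-event code family (S02/S04/S06/S07 truncations) is excluded
from the factor stage by default: those codes are present in every case
by construction, so any factor containing them is constant within the
case cohort and its transition correlations are undefined.  This mirrors
published factor tables, which contain external-cause codes but not the
cohort-defining codes themselves.  The toggle is
`exclude_index_codes_from_factors`.

## Factor stage

Principal-components factor analysis is run on the phi (Pearson-on-
binary) correlation matrix of the retained codes: loadings are
eigenvectors scaled by the square root of their eigenvalues.  Varimax
rotation is on by default — a flat loading cutoff applied to named,
interpretable factors presupposes a rotated solution — and each factor is
sign-flipped so its largest-magnitude loading is positive, making the
solution deterministic across eigensolvers.  A tetrachoric correlation
option was considered and left out (phi on binary indicators is the
field's standard for this design and keeps the spectrum interpretable as
variance of observed indicators).

The number of factors `k` is chosen by fitting candidate values and
keeping the one whose binary factor scores give the largest AUC in a
conditional-logistic model of case status (ties break toward smaller
`k`).  Three companion diagnostics are reported, not used for the choice:
the scree breakpoint (position of the maximum second difference of the
eigenvalue sequence), the Kaiser count (eigenvalues > 1) and the
cumulative-variance curve.  The AUC is computed on the fitting split;
this mirrors a training-set selection procedure and is documented as
optimistic.

A factor's definition is the set of codes with `|loading| ≥ 0.2`
(inclusive); codes may belong to several factors, and codes qualifying
nowhere are reported separately.  Patients score 1 on a factor if they
carry any member code.  Factors with fewer than 6 positive reference
patients are excluded as too rare to estimate.

## Association stage

For 1:1 matched pairs the conditional-logistic likelihood reduces to a
no-intercept logistic model on within-pair covariate differences with all
outcomes equal to 1.  It is maximised by Newton iterations (convergence
at gradient infinity-norm < 1e-8, at most 100 steps, damped steps capped
at 5 per coordinate).  Covariates that are constant within every pair
(exactly matched sex/age/rurality/income) difference out to zero columns
and are reported inert rather than dropped silently — on coarsely matched
real data they become active automatically.  Complete separation is
detected either by a diverging estimate or by gradient underflow at
`|β| > 15`, flagged, and (for a single exposure) replaced by the +0.5
discordant-cell estimate.  Confidence intervals are Wald,
`exp(β ± 1.96·se)`; profile likelihood is out of scope.

## Transition maps

Binary pre-injury factor scores are correlated with event-phase factor
scores (or with one-hot severity and non-exclusive external-cause
indicators) across the case cohort of each split; on binaries the Pearson
correlation is the phi coefficient.  Each cell's significance comes from
the Fisher transformation `z = atanh(r)` with standard error
`1/√(n−3)`, two-sided normal p-value, with `n` the number of patients in
the analysed cohort.  P-values are FDR-adjusted **jointly over all cells
of one map** (per-heatmap family; BY by default for consistency with the
screening stage) and cells with `q > 0.05` are set to 0.  Cells involving
a constant score vector are flagged undefined, excluded from the FDR
family, and masked.

Rows and columns are ordered by agglomerative Ward clustering on
correlation distance (`1 − r` between profiles of the masked matrix);
constant profiles default to distance 1.  Heatmaps render positive
correlations magenta and negative green with masked cells white, using a
signed rank-binned colour scale; the exact masked values are always
written as TSV so that images never carry information the text outputs
lack.  Cross-split concordance is summarised by per-cell sign agreement,
the Jaccard index of significant cell sets, and the adjusted Rand index
of row cluster assignments.

## Synthetic cohorts

The generator emulates the structure the analysis consumes, with known
ground truth:

* **Matching** — covariates are drawn once per pair and shared exactly,
  so they difference out in conditional models exactly as intended.
* **Planted factors** — a patient carries a factor with reference
  prevalence `p`; case carrier odds are multiplied by the planted odds
  ratio.  Carriers emit each member code at each visit of the factor's
  phase with an emission probability (default 0.7–0.8 in shipped
  configurations); background codes are emitted independently per visit
  (default 1–2%).  This is the simplest mechanism that produces the
  block-correlation structure PCA can recover.
* **Transitions** — carrier indicators are thresholded latent standard
  normals; a planted link sets the latent correlation between two
  dimensions to `rho`.  The implied phi correlation is computed
  numerically from the bivariate-normal rectangle probability
  (`target_phi`); note phi magnitudes are not mirror-symmetric in `rho`
  unless both margins are 50%.
* **Labels** — severity is one category per case (base rates 43/35/4/18%
  for unspecified/mild/moderate/severe), causes are non-exclusive
  indicators (falls 45%, struck 36%, sports 25%, other 12%, MVC 10%,
  assault 7%); linked categories ride the same copula, so pre-injury
  carriers shift their rates.  The injury visit emits a severity-specific
  S06.x code and one external-cause code per active indicator, which the
  labelling stage recovers through the editable mapping stubs.
* **Visit streams** — visit counts are `1 + NegBin` (mean 8 per decade,
  dispersion 2 — a stated assumption; reference visit-count distributions
  are not otherwise constrained), placed so the rank-midpoint visit of a
  reference falls on its pseudo-index date.  That guarantees planted
  event-phase structure is visible inside the downstream 61-day window.

Default size is 2,000 pairs over 200 codes, which keeps a full pipeline
run in seconds and the 200-replicate null calibration in minutes on one
core.  Simulations used by the validation suite are sized accordingly:
block recovery uses 10 cohorts of 2,000 pairs, CI coverage 100 replicates
of 5,000 pairs, and transition-link survival 10 replicates of 10,000
pairs.

What the generator does **not** emulate: realistic marginal prevalences
of specific ICD chapters, seasonality or clustering of visits, code
co-occurrence beyond the planted blocks, informative loss to follow-up,
or miscoding.  Passing recovery tests therefore demonstrates the
correctness of the pipeline's statistics under its stated model, not
robustness to the messiness of real administrative data.

## Numerical and degenerate-input choices

* BY/BH adjustments delegate to `statsmodels.multipletests`; varimax to
  `statsmodels` factor rotation; Ward linkage to
  `scipy.cluster.hierarchy` (validated against a brute-force
  Lance-Williams reference on small fixtures).
* `b + c = 0` discordant tables return p = 1 with a flag; zero cells in
  odds ratios get +0.5; constant code columns are dropped from factor
  analysis with a warning; factors whose codes are absent from a matrix
  warn (partial) or error (total).
* All randomness flows from one root seed (`numpy` `default_rng` /
  `SeedSequence`); a fixed seed reproduces every numeric output file
  bit-identically.

## Known limitations

* The AUC-based choice of `k` is computed in-sample; with strongly
  separating codes it can plateau and the smaller-`k` tie-break then
  governs.
* Wald intervals undercover slightly at small discordant counts; the
  exact-binomial branch protects the test but not the interval.
* The severity/cause mapping tables are editable stubs keyed to code
  prefixes, not the full published external-cause groupings; pipeline
  correctness is tested against the stub semantics.
* The 43 pre-injury factor definitions shipped under `data/` are a
  synthetic stand-in illustrating the input format; real analyses must
  supply their own definitions file.
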