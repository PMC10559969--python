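# Methods

`herdhealth` implements a genetic analysis of producer-recorded health
treatment costs in dairy cows: rule-based cleaning and costing of dated
treatment records, construction of per-cow-per-parity cost phenotypes,
a sire–maternal-grandsire (MGS) numerator relationship matrix, and REML
animal models yielding heritabilities, genetic/phenotypic correlations,
least squares means and BLUP breeding values.  Because the herd data the
design is modelled on are not public, the package ships a first-class
synthetic herd generator with known ground truth; every downstream stage is
validated by parameter recovery against that truth and by independent
oracles.

## The statistical model

For each trait the observation model is

    y_ijk = mu + H_i + C_j + e_ijk

with `H_i` the fixed effect of herd *i*, `C_j` the additive genetic effect
of cow *j* with `C ~ N(0, A sigma_a^2)`, and i.i.d. residuals.  `A` is the
numerator relationship matrix built from sire and MGS links only (dams are
not tracked as individuals).  Heritability is `h^2 = sigma_a^2 /
(sigma_a^2 + sigma_e^2)`; in multivariate fits the cow effect has
covariance `A ⊗ G` and residuals covariance `I ⊗ R`, giving the genetic
correlation `G_12 / sqrt(G_11 G_22)` and the phenotypic correlation
`(G_12 + R_12) / sqrt((G_11 + R_11)(G_22 + R_22))`.  Three configurations
are used: univariate (LSMs and heritabilities), pairwise bivariate
(correlations — an all-traits multivariate model is not attempted), and an
across-parity multitrait model in which parities 1–3 of one trait are three
distinct, correlated traits with trait-specific designs for cows culled or
censored before later parities.

With one record per cow per trait, `sigma_a^2` is identified purely through
the covariance among relatives encoded in `A`; at the default population
structure (2,214 cows from 260 sires in 8 herds) the delta-method SE of a
heritability near 0.25 is about 0.06, in line with field studies of this
design.

### Sire–MGS relationship matrix

Additive effects follow `u_x = 1/2 u_sire + 1/4 u_mgs + phi_x`, so

* `a(x, y) = 1/2 a(s, y) + 1/4 a(m, y)` for any earlier animal *y*,
* `a(x, x) = 1 + 1/4 a(s, m)`,
* Mendelian variance `d_x = 1 − 1/4 a(s,s) − 1/16 a(m,m)` (terms dropped
  for unknown parents: an unknown MGS contributes 0 and inflates `d_x`).

`build_A` applies the tabular recursion; `build_A_inverse` assembles the
sparse inverse from per-animal rank-one updates `(e_x − k)(e_x − k)'/d_x`
with `k` holding 1/2 on the sire and 1/4 on the MGS — the sire–MGS analogue
of Henderson's rules — and also yields `log|A| = Σ log d_x`, which the REML
likelihood needs.  Equality of the two routes (product with the dense
matrix equal to identity to 1e-8 on pedigrees up to 500 animals) is a test
invariant.  Animals appearing only as ancestors stay in `A` and receive
breeding values.

### REML estimation

The restricted log-likelihood is maximized directly over a log-Cholesky
parameterization of `(G, R)` (diagonal of the Cholesky factor on the log
scale), which keeps both matrices positive definite without constraints.
Two exact evaluation routes serve different data shapes:

* **Rotated route** (all traits observed on every cow).  With `K = A_cc`
  the cow block of `A` and eigendecomposition `K = U D U'`, rotating
  records by `U'` decouples them into independent t×t blocks with
  covariance `d_i G + R`.  One likelihood evaluation is then O(n), and the
  eigendecomposition depends only on the pedigree and cow list, so a single
  decomposition serves every replicate of a recovery study.  Optimization
  is quasi-Newton (L-BFGS-B) with finite-difference gradients (step 1e-5,
  chosen against the ~1e-10 relative evaluation noise), followed by a
  bounded Nelder–Mead polish that guards against premature termination on
  gradient noise near the optimum.
* **Mixed-model-equations route** (missing traits allowed; used by the
  across-parity model).  The likelihood is evaluated through the dense
  Cholesky factor of the MME coefficient matrix with the sparse `A⁻¹` and
  per-missing-pattern residual precisions, via the standard identity
  `-2 logL_R = log|R| + t log|A| + q log|G| + log|C| + y'Py` (constants
  included, so the two routes agree exactly — a test checks this against a
  from-first-principles dense-V implementation).  Here the optimizer uses
  the analytic restricted-likelihood score (for `G`:
  `q G⁻¹ − G⁻¹(U'A⁻¹U + T)G⁻¹` with `T_kl = tr(A⁻¹ C^{uu}_{kl})`; for `R`:
  per-pattern residual outer products plus the prediction-variance
  correction from `C⁻¹`), verified against finite differences to 1e-8.
  Starting values come from per-trait univariate fits on each trait's
  observed subset plus herd-centered phenotypic covariances.

Responses are standardized per trait before fitting and the reported
likelihood is corrected back to the natural scale by the exact Jacobian
term.  Convergence: L-BFGS-B defaults with at most 200 iterations;
boundary estimates are flagged when a genetic variance falls below 1e-8 of
the phenotypic variance (heritability then reported as 0), degenerate
constant responses short-circuit to a flagged boundary fit, and a
non-estimable genetic correlation (zero genetic variance in either trait)
is reported as missing rather than failing the batch — mirroring how field
analyses report non-converged pairs.  Accepted iterates are recorded; the
trace is non-increasing in −2 logL.

Standard errors of heritabilities and correlations are delta-method values
from the inverse observed information, computed by central finite
differences on the `(G, R)` scale at the optimum (with step-halving retries
when a perturbation leaves the positive-definite cone; if all retries fail
the SE is reported as unavailable).  Least squares means are unweighted
means of the herd-cell GLS solutions with SEs from the fixed-effect
covariance; EBVs are BLUP solutions at the converged components, computed
in the rotated basis (complete data) or read off the MME solutions.

## The synthetic herd generator

The generator emulates the study population the analysis is designed for:
8 herds with first-parity cow counts (394, 227, 427, 402, 179, 152, 250,
183) totalling 2,214; 260 AI sires with Dirichlet-skewed usage (a few
heavily used bulls, a long tail) and 420 MGS, all founders; survival to
parities 2 and 3 calibrated so the parity distribution lands near 49/33/18
percent of lactations.  Breeding values follow the sire–MGS recursion with
Mendelian covariance `d_x G_true`; phenotypes add herd effects and
residuals from `R_true`.  The default three-trait structure (total health
cost, 305-d milk, somatic cell score) uses first-parity heritabilities
0.25/0.23/0.18, genetic correlations THC–milk 0.44, THC–SCS 0.93,
milk–SCS 0.13, and phenotypic correlations THC–milk −0.07, THC–SCS 0.14;
trait means per parity follow the published multivariate LSMs (e.g. milk
10,943 / 12,628 / 13,018 kg).

Health events use a liability threshold: category liability is
`lambda * u_THC / sd(u_THC) + N(0, 1)` with `lambda = 0.5`, thresholded so
the fraction of first lactations with at least one treated case matches the
incidence targets (MAST 26.5, REPRO 13.3, LAME 26.7, META 7.7, MISC 14.1
percent — interpreted as *percent of cows with ≥1 case*, since "frequency
of treatment" is ambiguous between that and cases per 100 lactations).
Affected lactations draw a zero-truncated Poisson number of illness
episodes whose mean (1.1–1.5 by category; the Poisson rate is solved
numerically from the truncated mean) and per-treatment costs were
calibrated once so category cost means land near the published first-parity
LSMs ($10.88/15.28/12.89/8.02/8.13).  The raw log deliberately contains
within-window duplicate records, same-day repeats and sparse dry-period
treatments, so the cleaning rules have real work to do.  The cost table
itself is synthetic (per-treatment veterinary, pharmaceutical and
labor-hour components are not published); the $18/h labor wage is the only
externally fixed constant.

What the generator does **not** emulate: the Gaussian trait module emits
normal phenotypes, whereas real lactational cost is zero-inflated and
right-skewed (the event-derived THC from the full pipeline *is*
zero-inflated — about 40% zero-cost first lactations — and is what the
analysis drivers fit); no selection feedback across generations; no
test-day lactation-curve modelling (305-d values are emitted directly); no
genotype-by-herd interaction.  Recovery tests therefore demonstrate
correctness of the estimation machinery under the model's assumptions, not
robustness to every feature of field data.

## Record cleaning and costing rules

* Deduplication windows: a record is a new billable event only if ≥3 days
  elapsed since the previous hoof record, ≥5 days for digestive, ketosis,
  mastitis, metritis, milk fever and respiratory, ≥7 days for cystic ovary.
  The elapsed-day anchor is the most recent *record* of the same type,
  kept or not: closely spaced records mark one continuing illness episode,
  so e.g. mastitis records on days 1, 3 and 6 are a single event.  The
  operation is idempotent.
* Displaced abomasum, retained placenta and miscellaneous reproduction:
  once per lactation.  Mastitis diagnostic test, injury, other: one per
  calendar day, no other restriction.  A mastitis test on the same day as a
  mastitis treatment is two billable records (distinct codes).
* Record edits: abortion-initiated lactations removed; lactations calving
  within 30 days of study end removed; cows whose sire or MGS has fewer
  than 2 descendants (daughters + granddaughters) among the remaining cows
  removed, in a single pass over post-edit counts (the edit is not iterated
  to a fixed point; a bull whose count drops to 1 because another bull's
  daughters were removed is not re-examined).
* Aggregation: events dated in [calving of parity p, calving of p+1)
  accrue to parity p — including the dry period; disposed or in-progress
  lactations sum whatever accrued with no days-in-milk adjustment; cows
  with no events get explicit zero-cost rows; events before first calving
  are rejected with a report line; parity >3 records are dropped with a
  report line.  Currency is held in integer cents so THC equals the
  category sum exactly.
* Test-day edits: DIM ≥ 4, milk > 2.27 kg (strict), fat in [1.0, 9.9]%,
  protein in [1.0, 6.0]% (closed intervals).

## Reporting conventions

Percent columns round half-away-from-zero to integers (unrounded values are
retained); currency prints to 2 decimals.  Treatment frequency is percent
of cows at risk with ≥1 deduplicated event in the category during the
parity.  Significance flags mark `|estimate| > 1.96 SE` (95% CI excluding
zero).  The sire regression includes sires with ≥10 recorded daughters
(default) and reports the OLS slope of per-sire daughter means on sire
EBVs, in raw and herd-adjusted variants, plus the EBV spread.

## Problem sizes and test design

Recovery studies hold the pedigree and herd assignment fixed and redraw
breeding values, herd effects and residuals each replicate; this isolates
sampling variation of the genetic parameters and lets one eigendecomposition
serve all 30 replicates.  The headline recoveries (univariate h² = 0.25 and
bivariate r_g = 0.93 with h² 0.25/0.18) run at the full study structure.
The across-parity multitrait checks run on reduced herds (240 cows, 25–30
sires) where a single fit carries a heritability sampling SD near 0.15–0.2;
the culling-ordering test therefore uses a wider true per-parity contrast
(0.35 vs 0.12) than a field study would show and asserts the ordering of
replicate means — the property under test is that phenotypic culling plus
the multitrait machinery recovers the first-parity > later-parity ordering,
at a signal size the reduced scale can resolve.  The analysis driver fits
the across-parity model on a seeded 400-cow subsample with the pedigree
pruned to the subsample's ancestors, keeping the dense MME factorizations
small.

## Known limitations

* Costs are Gaussian-modelled in the REML stage even though lactational
  cost data are zero-inflated; the study design shares this property, and
  the recovery tests show the machinery is unbiased under the Gaussian
  generator, not under strong skew.
* The dense MME route scales as O((q·t)³) per factorization and is meant
  for datasets up to a few thousand animal-trait effects; larger problems
  would need sparse factorizations.
* Standard errors may be reported as unavailable when the observed
  information cannot be evaluated stably near a variance boundary.
* The two-descendant edit is single-pass by design (documented above).
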