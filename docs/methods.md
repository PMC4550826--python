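# Methods

## Setting and assumptions

The package estimates the effect of telomere length (TL, in kb) on disease
risk (log odds) from two independent sets of GWAS summary statistics: per-
allele SNP→TL effects for a panel of instrument SNPs, and per-allele
SNP→disease log odds ratios from a case-control consortium. The causal
interpretation rests on the standard instrumental-variable assumptions:
(1) each SNP is truly associated with TL, (2) SNPs are independent of
confounders of the TL-disease relationship, and (3) SNPs affect disease
only through TL (no pleiotropy). The dose-response is assumed log-linear in
TL; U-shaped or threshold effects are outside the model. All multi-SNP
statistics additionally assume the instruments are mutually uncorrelated
(no LD), which is why the packaged instrument table marks two tag SNPs in
LD with stronger instruments as excluded.

## Data model and harmonization

Exposure effects are reported per copy of the "long-TL" allele and are
positive by construction. Outcome effects are oriented to that allele at
join time: if the outcome's effect allele equals the long allele the effect
is kept, if its other allele does the sign is flipped, and anything else is
an error — no strand complementing is ever attempted. Palindromic A/T and
C/G pairs are refused by default because their orientation is undecidable
without strand or frequency information; an explicit opt-in accepts them as
stated, with a logged warning. Instruments missing from an outcome table
are dropped with an audit reason rather than failing the run, optionally
after substituting a user-supplied proxy (tag) SNP, which keeps its
instrument's exposure effect. Every exclusion (LD mark, user exclusion,
missing-in-outcome, strict, goodness-of-fit) is carried through to the run
report.

When an exposure table reports β and P but no SE (the packaged instrument
table does), the SE is recovered by inverting the two-sided Wald test,
`se = |β| / Φ⁻¹(1 − p/2)`. P-values below 1e-300 are rejected rather than
clamped; the smallest P in the packaged table is 2.5e-31, far from the
floor. Whether the original instrument GWASs' reported SEs differ slightly
from this inversion is unknowable from the table itself; the derivation is
used uniformly and round-trips to the input P within 1e-10 relative.

## Estimators

**IVW.** The inverse-variance weighted estimate is the weighted
least-squares slope of outcome on exposure effects through the origin with
weights σ_Y⁻², with the fixed-effect (first-order) standard error
(Σ X²σ_Y⁻²)^(−1/2). It treats exposure effects as fixed; with
instrument-grade exposure precision the resulting weak-instrument dilution
is below a percent and is visible in the generator's parameter-recovery
tests only as a sub-MC-error bias.

**Likelihood method.** Each pair (X_k, Y_k) is modelled bivariate-normal
with means (ξ_k, βξ_k), the reported SEs, and within-SNP correlation ρ.
In a two-sample design the exposure and outcome estimates come from
disjoint samples, so ρ defaults to 0; the parameter is exposed for
sensitivity analysis. The nuisance effects ξ_k maximise a quadratic and
have a closed form at fixed β, so the fit profiles them out and optimises
β alone by BFGS, warm-started at the IVW solution with up to three
jittered restarts (gradient tolerance 1e-8, relative step 1e-10). The
convergence flag is part of the reported fit because strongly significant
heterogeneity is known to degrade this optimisation. The Wald SE comes
from the numerical curvature of the profile log-likelihood at the optimum
(central differences, step max(1e-5, 1e-4·|β|)), whose observed
information equals the β block of the full information's inverse. The
default 95% interval is the profile interval, bracketing the deviance
cutoff 3.841 by geometric expansion and solving with Brent's method
(xtol 1e-10); Wald intervals are available for speed. All 95% intervals
use z = 1.959964.

Both estimators follow the scikit-learn contract (`fit(X, y, …)`, fitted
attributes with trailing underscores, `get_params`/`clone`, `predict`
returning βx), so they compose with sklearn tooling; `ivw_estimate` and
`likelihood_estimate` wrap them for harmonized instrument sets and attach
OR-scale reporting.

## Heterogeneity test and pruning

Q_rs = Σ (Y_k/σ_Yk)² − (β̂_IVW/SE)² is χ²_{K−1} under proportionality.
The stepwise procedure, triggered while its P < α (default 0.05), removes
the SNP whose leave-one-out subset has the smallest resulting Q — which is
exactly the removal achieving the greatest reduction of Q — and re-tests.
Ties (which the source procedure does not address) are broken by the
smaller resulting Q, then lexicographically by rsID, making traces
deterministic. Pruning never goes below a configurable floor of 3
instruments; hitting the floor while still significant flags the history
and logs a warning instead of raising, since a sensitivity analysis that
dies half-way is less useful than a flagged one. Leave-one-out always
weakly reduces Q (the full-set residual sum of squares bounds any subset's
minimum), so traces are monotone.

The pipeline reports three analysis variants per outcome: "all" (every
instrument), "strict" (dropping rs6772228, whose TL association is
inconsistent across cohorts), and "goodness-of-fit based" (the pruned set),
each with both estimators.

## Quartile rescaling and power

`quartile_shift` draws n = 1e6 values from Normal(mean 6000 bp, SD
400-700 bp — the range reported for leukocyte TL), splits at the empirical
quartiles and differences the tail means; for a normal this converges to
2φ(z₀.₇₅)/0.25 ≈ 2.5422 SDs, and the simulation agrees with that
quadrature value within Monte-Carlo error (~0.6 bp SE at SD 400).
`rescale_or` then maps a per-1000 bp OR to the quartile contrast by
exponent Δbp/1000 under log-linearity.

`min_detectable_or` inverts the asymptotic IV power calculation for a
binary outcome: the detectable per-SD-of-TL log-OR satisfies
|β| = (z_{1−α/2} + z_{power})·SE with SE = 1/sqrt(N·R²·φ(1−φ)), φ the case
fraction and R² the TL variance explained by the instruments (1-2% for
this panel). A case-control simulation oracle in the test suite confirms
the formula's 80% rejection rate. Converting the per-SD OR to per-1000 bp
raises it to a power: the conventional exponent is 0.5 (treating 1 SD as
roughly 500 bp), which is dimensionally inconsistent — SD ≈ 500 bp implies
exponent 1000/500 = 2. Both are implemented behind `exponent_mode`;
`"paper"` (0.5) is the default for comparability with published power
tables, `"consistent"` computes 1000/sd_bp.

## Synthetic data

The generator draws summary statistics directly from the sampling
distributions the estimators assume — x̂_k ~ N(ξ_k, σ_xk²) independent of
ŷ_k ~ N(βξ_k + α_k, σ_yk²) — rather than simulating genotypes; this is
orders of magnitude faster and makes calibration statements exact. SEs
derive from sample sizes: σ_xk = sd_TL/√(2m(1−m)·n_exp) and the per-allele
logistic approximation σ_yk = 1/√(2m(1−m)·n_cases·n_controls/N).

Defaults define the reference conditions: the nine packaged instrument
effects (0.057-0.120 kb/allele), sd_TL = 0.5 kb, allele frequency m = 0.3
for every SNP (instrument frequencies are not part of the packaged table),
adenocarcinoma-scale outcome counts (3718 / 15 871), and n_exp = 37 000 —
the size of the largest TL GWAS behind the instrument panel. With the
global m and sd_TL defaults this yields σ_x ≈ 0.004, somewhat tighter than
the ≈0.010 implied by inverting the packaged P-values (whose studies
differ per SNP in frequency and TL variance); n_exp is a config field for
anyone wanting to study the weak-instrument regime. Half the outcome rows
are written oriented to the short allele so harmonization is exercised on
every dataset; allele pairs are a deterministic function of the rsID
(packaged long alleles where applicable), keeping tables from different
seeds joinable. Pleiotropy is injected as additive offsets α_k on the
outcome means, and the stored truth includes the implied Q_rs
noncentrality Σα²w − (Σξαw)²/Σξ²w.

What the generator does not emulate — and what green tests therefore do
not certify about real data: LD between instruments, allele-frequency and
per-study heterogeneity in instrument precision, non-normal finite-sample
behaviour of logistic estimates, sample overlap (ρ ≠ 0), population
stratification, and selection effects in the source GWASs.

## Test problem sizes

Calibration tests use 5000 replicates for the null rejection rate of Q_rs
(binomial SE 0.003), 1000 replicates for parameter recovery and CI
coverage of both estimators at consortium scale, and 500 replicates for
pleiotropy-detection rates; the detection scenario places a 6σ_y direct
effect on the weakest instrument, where the analytic noncentral-χ² trigger
power is ≈0.997. Quartile simulations use n = 1e6 draws. These sizes make
the whole suite run in well under a minute while keeping Monte-Carlo error
far below every asserted tolerance.

## Known limitations

* Fixed-effect IVW only; no MR-Egger, weighted-median or mode-based
  estimators, and no random-effects heterogeneity summaries (I²).
* No LD modelling anywhere: correlated instruments must be pruned upstream,
  as the packaged table does via its exclusion marks.
* The likelihood model takes the reported SEs as known constants.
* Power calculations use the asymptotic normal approximation; rare-disease
  and extreme case:control imbalance regimes are untested.
* The quartile rescaling assumes normally distributed TL and log-linearity
  of risk in TL across the whole distribution.
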