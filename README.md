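# telomr

Two-sample Mendelian randomization (MR) of telomere length (TL) and cancer
risk from GWAS summary statistics.

Observational associations between leukocyte telomere length and cancer are
plagued by reverse causation (diagnosis and treatment shorten telomeres) and
confounding. MR sidesteps both by using germline variants as instruments:
SNPs robustly associated with TL are combined into a genetic score, and the
score's association with disease — taken from an independent case-control
GWAS — estimates the effect of TL itself on risk, under the usual
instrumental-variable assumptions. This package implements that analysis for
epidemiologists working from summary-level data: per-SNP association tables
in, causal odds ratios with sensitivity analyses out.

## The model

For instrument SNP *k*, let *X<sub>k</sub>* be its per-allele effect on TL
(kb per copy of the "long-TL" allele, with standard error
σ<sub>Xk</sub>) and *Y<sub>k</sub>* its per-allele log odds ratio for the
outcome (SE σ<sub>Yk</sub>), oriented to the same allele. Two estimators of
the causal log-odds β per 1 kb of TL are provided:

* **Inverse-variance weighted (IVW)**

  β̂ = Σ<sub>k</sub> X<sub>k</sub>Y<sub>k</sub>σ<sub>Yk</sub>⁻² / Σ<sub>k</sub> X<sub>k</sub>²σ<sub>Yk</sub>⁻²,  SE(β̂) = (Σ<sub>k</sub> X<sub>k</sub>²σ<sub>Yk</sub>⁻²)<sup>−1/2</sup>

  — weighted least squares of *Y* on *X* through the origin.

* **Likelihood method** — each (*X<sub>k</sub>*, *Y<sub>k</sub>*) is
  bivariate normal around (ξ<sub>k</sub>, βξ<sub>k</sub>) with known SEs and
  within-SNP correlation ρ (0 in the two-sample design); β and the nuisance
  instrument effects ξ<sub>k</sub> are estimated by maximum likelihood, with
  profile-likelihood confidence intervals.

Instrument validity is probed by the goodness-of-fit statistic
Q<sub>rs</sub> = X²<sub>k-df</sub> − X²<sub>rs</sub> (the unconstrained K-df
chi-square of the outcome associations minus the 1-df risk-score
chi-square), distributed χ²<sub>K−1</sub> when all SNP-outcome effects are
proportional to the SNP-TL effects. When Q<sub>rs</sub> is significant, the
SNP whose removal most reduces it is excluded, repeatedly, until the test is
non-significant ("goodness-of-fit based" analysis). A "strict" analysis
drops the PXK-region SNP rs6772228, whose TL association is itself
questioned. A quartile-rescaling simulation converts per-kb ORs to
top-vs-bottom-quartile contrasts, and a power module reports minimum
detectable ORs given case/control counts and instrument strength R².

The nine-SNP TL instrument table (TERC, TERT, NAF1, OBFC1, PXK, ZNF208,
RTEL1, CTC1, ACYP2 loci, plus two LD-excluded tags) ships with the package;
`telomr.synthetic_data` generates outcome tables with known causal truth at
consortium-scale sample sizes, so the whole pipeline is testable without
any data access.

## Worked example

```python
import numpy as np
from telomr import (SyntheticConfig, generate_instrument_set,
                    ivw_estimate, likelihood_estimate, gof_statistic)

cfg = SyntheticConfig(true_beta=np.log(2.87), seed=11)   # OR 2.87 per kb
instruments, truth = generate_instrument_set(cfg)

ivw = ivw_estimate(instruments)
lik = likelihood_estimate(instruments)
gof = gof_statistic(instruments)

print(f"IVW:        OR {ivw.or_point:.2f} (95% CI {ivw.ci_low:.2f}, "
      f"{ivw.ci_high:.2f}), P = {ivw.p_value:.1e}")
print(f"likelihood: OR {lik.or_point:.2f} (95% CI {lik.ci_low:.2f}, "
      f"{lik.ci_high:.2f}), P = {lik.p_value:.1e}")
print(f"GOF: Q = {gof.q_stat:.2f} on {gof.df} df, P = {gof.p_value:.2f}")
```

prints

```
IVW:        OR 2.85 (95% CI 2.31, 3.50), P = 5.6e-23
likelihood: OR 2.85 (95% CI 2.31, 3.52), P = 1.5e-22
GOF: Q = 6.97 on 8 df, P = 0.54
```

One synthetic adenocarcinoma-scale dataset (3718 cases / 15 871 controls,
true OR 2.87 per kb): both estimators recover the truth within sampling
error, agree closely with each other, and the non-significant Q on 8 df
shows no evidence of pleiotropy — as it should, since none was injected.

The same analysis runs from the shell on TSV tables
(`telomr run -c config.yaml`), and

```sh
telomr power --n-cases 3718 --n-controls 15871
```

```
r2      or_per_sd       or_per_kb
0.01    1.666   1.291
0.02    1.435   1.198
```

reads: with instruments explaining 1% of TL variance at these sample sizes,
only ORs of at least 1.67 per SD of TL (≈1.29 per kb under the package's
default conversion) are detectable with 80% power at α = 0.05.

Other subcommands: `telomr simulate` (synthetic dataset + truth JSON),
`telomr gof` (heterogeneity test and pruning trace), `telomr scale`
(per-quartile rescaling).

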