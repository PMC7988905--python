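# ruralgap

Analysis toolkit for rural/non-rural inequality in a binary child-health
outcome across grouped, weighted survey microdata. It implements, as a
tested reusable package:

- **synthetic data** — a multi-country, cluster-structured survey
  generator with known logistic data-generating parameters (structural
  rural effect, compositional covariate shifts, cluster random
  intercepts, log-normal sampling weights), plus a Monte-Carlo
  `expected_prevalence` oracle;
- **ses** — a neighbourhood socioeconomic index: the first principal
  component of each cluster's weighted proportions of uneducated,
  poor-household and unemployed mothers, oriented so higher = more
  disadvantaged, quintiled by child count;
- **inequality** — weighted prevalences, rural-minus-non-rural risk
  differences per 1000 with Wald CIs, two-proportion z-tests, chi-square
  association tests, and fixed-/random-effects (DerSimonian–Laird)
  pooling of per-country risk differences with forest-plot tables;
- **pooled_or** — per-country logistic odds ratios, the Mantel–Haenszel
  pooled OR with Robins–Breslow–Greenland SE, Cochran's Q, I², and
  homogeneity tests on country subsets;
- **fairlie** — nonlinear decomposition of the rural/non-rural gap in
  mean outcome into per-covariate-block "explained" contributions and an
  "unexplained" remainder: pooled-logit reference coefficients,
  rank-matching on predicted probabilities after random subsampling of
  the larger group, sequential block switching with per-replication
  order randomization, and replication-based standard errors;
- **cli/pipeline** — a one-command pipeline chaining
  simulate → SES → inequality → pooled OR → decomposition of the
  countries classified significantly pro-rural by the OR test.

## Data format

Comma-delimited text with a header, one row per child:

| column     | meaning                                   |
|------------|-------------------------------------------|
| country    | country name                              |
| cluster_id | primary sampling unit, nested in country  |
| rural      | 1 = rural (group A), 0 = non-rural        |
| weight     | positive sampling weight                  |
| outcome    | 1 = outcome event within recall window    |
| *other*    | any additional numeric column is a covariate |

The SES stage expects covariates named `no_education`, `unemployed` and
either `wealth` (quintile 1–5, 1 = poorest) or a binary `poor_household`.

## CLI

```bash
ruralgap simulate  -c examples/pipeline.yaml -o data.csv   # (simulation section)
ruralgap ses       -i data.csv -o ses.csv
ruralgap inequality -i data.csv -o out/
ruralgap pooled-or -i data.csv -o out/
ruralgap decompose -i data.csv --country Alpha -o dec.json -R 1000 --seed 1
ruralgap run-all   -c examples/pipeline.yaml
```

`run-all` writes prevalence, risk-difference forest, meta-analysis,
odds-ratio, heterogeneity and decomposition reports (CSV + JSON) plus a
`manifest.json` recording seeds and every analysis convention in effect.
Outputs are byte-identical for identical config + seed.

## Python API sketch

```python
from ruralgap import (
    SimulationConfig, CountryConfig, generate_survey,
    DecompositionConfig, run_fairlie, contribution_table,
)
from ruralgap.fairlie import group_samples_from_frame

cfg = SimulationConfig(countries=[CountryConfig(
    name="K", n_clusters=200, children_per_cluster=100,
    rural_cluster_fraction=0.65, intercept=-2.0,
    covariate_effects={"no_education": 1.2},
    covariate_rural_shift={"no_education": 0.3},
    covariate_base={"no_education": 0.25},
)], seed=1)
data = generate_survey(cfg)
A, B = group_samples_from_frame(data.frame, data.covariate_names)
result, model = run_fairlie(A, B, DecompositionConfig(replications=1000, seed=1))
print(contribution_table(result))
```

## Analysis conventions

Point estimates use sampling weights; test variances use unweighted group
sizes (a Kish effective-sample-size option exists). Chi-square tests use
unweighted counts. All tests are two-sided at α = 0.05 with no
multiple-testing adjustment. Random-effects pooling is DerSimonian–Laird.
Mantel–Haenszel uses unweighted counts; a 0.5 continuity correction is
applied per stratum only inside Q when a cell is zero. Decomposition
defaults: pooled coefficients without a group dummy, 1000 replications,
randomized block order per replication, SEs as SDs over replications.
All of these are echoed into the pipeline manifest.
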