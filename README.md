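# ripetime

Timing analysis of climacteric tomato fruit ripening from interval-censored
colour-stage scores, with the supporting qPCR relative quantification and
ethylene-emission computations of a typical ripening phenotyping study.

## The problem

In a greenhouse trial, fruits of several genotypes (e.g. a wild type and
ripening mutants such as *rin* or *acs4* alleles) are scored on the ordinal
colour scale **MG < T < O < LR < R** (mature green, turning, orange, light
red, red) at scheduled visits.  Two quantities per genotype are of
interest: the number of days from anthesis (flower opening) to the first
ripening sign (entry into T), and the length of the climacteric phase
(days from first sign to red).  Neither time is observed directly — each is
*interval censored* between consecutive visits — and fruits of one plant
are correlated.

`ripetime` models the latent event-time pair per fruit as

```
(Y1, Y2)' = μ + α_m(p) + β_b + γ_f + Z_p + U,
Z_p ~ N₂(0, Σ₀),   U ~ N₂(0, Σ),
```

with genotype (α), truss (β) and fruit-position (γ) effects under
treatment coding, a per-plant bivariate random effect `Z_p` and residual
`U`.  With censoring rectangle `[L⁽¹⁾,R⁽¹⁾] × [L⁽²⁾,R⁽²⁾]` per fruit, the
log-likelihood is

```
Σ_p log E_{Σ₀} [ Π_{b,f} P_Σ( μ + α + β + γ + Z + U ∈ [L,R]×[L,R] ) ],
```

evaluated with machine-precision bivariate-normal rectangle probabilities
(Owen's T) and product Gauss–Hermite quadrature over `Z_p`, and maximised
by quasi-Newton optimisation.  Covariates are kept or dropped by asymptotic
χ² likelihood-ratio tests; genotype summaries carry delta-method standard
errors and LRT significance stars.

Around the core model the package provides, as first-class tested code:

- **`ripetime.simulate`** — seeded generators for whole ripening
  experiments (with ground-truth sidecars), qPCR plates and ethylene
  traces, so every stage is testable without external data;
- **`ripetime.qpcr`** — window-of-linearity amplification efficiency,
  plate-mean efficiency, normalised relative quantities against reference
  genes, geNORM stability (M values, V ladder), mean-centred run merging,
  and one-way ANOVA with Fisher's protected LSD;
- **`ripetime.ethylene`** — cuvette emission rates corrected for flow,
  fresh weight and background, and per-stage genotype comparisons;
- **`ripetime.cli` / `ripetime.io`** — CSV/YAML/JSON formats and a
  `ripetime` command with `simulate`, `censor`, `fit`, `lrt`, `summarize`,
  `qpcr`, `ethylene` and `run` subcommands plus a manifest-writing
  pipeline.

## Worked example

Simulate the built-in design (wild type + three mutants, 17 plants, six
fruits each, twice-weekly scoring for four weeks from day 30), derive the
censoring intervals and fit the model:

```python
from ripetime import (default_design, default_params,
                      simulate_ripening_experiment, derive_censoring_intervals,
                      ModelSpec, RipeningModel, QuadratureSpec)
from ripetime.model import censored_to_frame

series, truth = simulate_ripening_experiment(default_design(), default_params(), seed=1)
data = censored_to_frame([derive_censoring_intervals(s) for s in series])
spec = ModelSpec.infer(data, reference="WT", include_truss=False,
                       include_fruit="linear", quad=QuadratureSpec(15))
result = RipeningModel(data, spec).fit(restarts=2, seed=1)
print(result.summary())
print(result.genotype_summary().to_string(index=False))
```

prints

```
Bivariate interval-censored ripening model
====================================================
observations (fruits):   102    plants: 17
log-likelihood: -161.4443    free parameters: 16
converged: True    quadrature: 15 nodes/dim
----------------------------------------------------
parameter             estimate     std err
mu(1)                  41.9321      0.6928
mu(2)                  52.2585      0.5883
alpha[acs4-1](1)        4.8192      0.9406
alpha[acs4-1](2)        2.6967      0.7802
alpha[rin-2](1)         5.4815      0.9428
alpha[rin-2](2)         6.1897      0.8165
alpha[rin-3](1)         4.8178      1.2872
alpha[rin-3](2)         4.5687      1.0630
gamma_lin(1)            0.5786      0.2156
gamma_lin(2)            0.5584      0.2322
----------------------------------------------------
Sigma  (residual): [[2.067, 0.181], [0.181, 2.278]]
Sigma0 (plant):    [[1.759, 0.671], [0.671, 0.992]]

genotype  first_sign_days  first_sign_se  ripening_length_days  ripening_length_se  p_vs_reference significance
      WT        41.932058       0.692750             10.326429            0.758435             NaN
  acs4-1        46.751304       0.705429              8.203871            0.757839    1.172413e-03           **
   rin-2        47.413523       0.709696             11.034621            0.801602    9.649339e-08          ***
   rin-3        46.749829       1.127603             10.077395            1.161681    2.418814e-03           **
```

Reading the table: the wild type shows its first ripening sign an estimated
41.9 days after anthesis (truth: 42) and takes 10.3 days to reach red;
`alpha[rin-2] = (5.5, 6.2)` recovers the simulated onset/red delays of
(5, 6) days, and `gamma_lin ≈ 0.58` the simulated half-day-per-position
effect.  Stars are 2-df likelihood-ratio tests of each genotype against the
wild type.  (`rin-3` has only two plants in this design, so its estimate
tracks the realised draw of those plants rather than the nominal (2, 4).)

The same analysis from the shell:

```sh
ripetime simulate ripening --seed 1 --out data/
ripetime censor --data data/observations.csv --out data/censored.csv
ripetime fit --data data/censored.csv --seed 1 --out data/fit.json
ripetime summarize --fit data/fit.json --data data/censored.csv --out data/summary.csv
```

or in one configured, manifest-tracked step: `ripetime run --config
config.yaml --out results/`.

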