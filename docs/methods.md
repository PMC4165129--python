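# Methods

## The ripening-time model

Tomato fruits are scored repeatedly on the ordinal colour scale
MG < T < O < LR < R (mature green, turning, orange, light red, red).  Two
event times per fruit are of interest: `Y1`, days from anthesis to the first
ripening sign (entry into T), and `Y2`, days to fully red (entry into R).
Because fruits are only visited on scheduled days, both times are interval
censored: each is known only to lie between the last visit before and the
first visit at-or-after the transition.  A fruit already past a stage at its
first visit gets lower bound 0 (anthesis — no fruit ripens before its flower
opens); a fruit never seen at a stage is right-censored at its last visit.
Observations at the intermediate O and LR stages sharpen the lower bound for
the red transition only; the model itself concerns just the two events.

The latent pair is modelled as a bivariate Gaussian linear mixed model

    (Y1, Y2)' = mu + alpha_{m(p)} + beta_b + gamma_f + Z_p + U,

with genotype effect `alpha`, truss effect `beta`, fruit-position effect
`gamma` (all length-2 vectors under reference/treatment coding: wild type,
first truss and first position are exactly zero), a per-plant random effect
`Z_p ~ N2(0, Sigma0)` shared by all fruits of a plant, and residual
`U ~ N2(0, Sigma)`.  The model is strictly additive — no interactions.  The
fruit-position effect can alternatively be taken linear in position
(`gamma_lin * (f - 1)`).  We do not constrain `Y1 <= Y2`; the probability
mass the fitted model places on inverted orderings is negligible at
realistic parameter values.

Each fruit contributes the probability that the latent pair falls in its
censoring rectangle; fruits of one plant are dependent through `Z_p`, so the
per-plant likelihood marginalises it:

    l_p = log E_{Z ~ N2(0, Sigma0)} [ prod_fruits P_Sigma( Y in rect - m - Z ) ],

and the total log-likelihood is the sum over plants.

### Rectangle probabilities

The bivariate normal CDF is evaluated through Owen's T function
(`scipy.special.owens_t`), which is deterministic and accurate to machine
precision; rectangle probabilities follow by inclusion–exclusion over the
four corners, clipped to [0, 1] to absorb round-off.  Closed-form cases
(orthants, independence) are reproduced to ~1e-12, which matters because a
quasi-Newton optimiser differentiates this surface numerically.  The branch
constant of Owen's decomposition is computed from argument signs rather than
the product `h*k`, which can underflow for corner arguments near zero.

### Quadrature

The expectation over `Z` uses a fixed product Gauss–Hermite rule after
whitening `Z` along the eigenvectors of `Sigma0` (rank-adaptive: a singular
or zero `Sigma0` degenerates to a 1-D rule or a point mass).  Products over
fruits are accumulated in log space with a log-sum-exp over nodes, so plants
with many fruits cannot underflow; a plant whose likelihood is exactly zero
yields `-inf` with a warning naming the plant.  The default is 15 nodes per
dimension.  Convergence is exponential in the node count but depends on how
concentrated the integrand is relative to the Gaussian weight: with
unit-scale plant variances 15 vs 25 nodes agree below 1e-6, while plant
variances of ~3 days² give agreement of ~1e-3 at 15 nodes — still far below
Monte-Carlo oracle noise at 1e5 draws, and without practical effect on the
optimum.  Censoring bounds snap to the observation schedule, so distinct
fruits often share an identical shifted rectangle; the evaluator
deduplicates rectangles before the quadrature sweep (an ~20x speedup on
realistic designs).

### Estimation

`RipeningModel.fit()` maximises the marginal likelihood with L-BFGS-B on an
unconstrained vector: fixed effects untransformed, `Sigma` and `Sigma0` via
log-Cholesky factors (guaranteeing positive (semi)definiteness, with the PSD
boundary reachable in the limit).  Starting values come from interval
midpoints (right-censored fruits: lower bound plus half the median finite
width): the baseline from the reference genotype's midpoint mean, each fixed
effect from the corresponding group-mean contrast, and the midpoint
covariance split equally between `Sigma0` and `Sigma`.  By default 3 starts
are used (the midpoint start plus seeded jittered copies; 0.75 days SD on
fixed effects, 0.15 on the covariance factors) and the best optimum kept;
everything is deterministic given the seed.  Relative function tolerance is
1e-11 with a 1e-6 finite-difference step, appropriate for a likelihood
computed to near machine precision.

Standard errors come from the observed information: a central-difference
Hessian at the optimum (step `1e-4 * max(1, |theta|)` per coordinate),
inverted; a singular information matrix falls back to a pseudo-inverse and
flags the results object.  Genotype summaries (days to first sign
`mu1 + alpha1`; phase length `(mu2 + alpha2) - (mu1 + alpha1)`) propagate
uncertainty by the delta method — these are linear transforms, so the delta
method is exact given the Hessian.  We report standard errors of the
estimates; a per-fruit SD would be a different (larger) quantity.

Nested comparisons use the asymptotic chi-squared likelihood-ratio test,
with the degrees of freedom equal to the difference in free-parameter
counts (each dropped effect level frees 2 parameters, one per event).  Two
identical specifications give statistic 0, df 0, p 1.  Nested fits are
warm-started from the enclosing optimum projected onto the reduced space;
if the reduced optimum nevertheless exceeds the full one, the full model is
refitted from the reduced optimum and the better fit kept.  This makes the
monotone-likelihood property structurally reliable — cold refits of richer
models occasionally stall in local optima on small datasets.  Covariate
selection drops truss and fruit terms in turn at alpha = 0.05; the plant
random effect is structural and never dropped, and no test is performed for
`Sigma0` at its boundary.  Per-genotype significance stars come from the
2-df test that fixes that genotype's `alpha` at zero.

## Synthetic experiments

The ripening generator draws from exactly the model above and discretises
through the observation schedule.  Intermediate stages carry no latent
structure: `[Y1, Y2)` is split into three equal thirds labelled T, O, LR.
A draw with `Y2 < Y1` (possible under an unconstrained bivariate Gaussian)
has its residual redrawn once, then `Y2` clamped to `Y1`; clamps are counted
in the ground-truth sidecar.  The default design mirrors a greenhouse
ripening trial: genotypes WT, rin-2, rin-3, acs4-1 with 5/5/2/5 plants,
2 trusses x 3 fruits per plant, scored twice weekly for four weeks from
day 30 (days 30, 33, 37, 40, 44, 47, 51, 54, 58).  Default truth: wild type
turning at day 42 and red at 52; onset/length delays of (5,6), (2,4), (4,3)
days for rin-2, rin-3, acs4-1; half a day per fruit position;
`Sigma0 = [[3,1],[1,3]]`, `Sigma = [[2,0.5],[0.5,2]]` days².  These are
plausible greenhouse scales, chosen once; the observation window
deliberately right-censors part of the slow mutants, as a real four-week
trial would.

What the generator does *not* emulate: scorer error (mislabelled stages),
missed visits, fruit abortion/drop-out, or non-Gaussian tails.  Passing
recovery tests therefore demonstrates correctness of the estimator under
the model's own assumptions, not robustness to misscoring.

The qPCR generator produces Cq values (`Cq = C0 - x * ln2 / lnE` for log2
expression `x`, plus Gaussian Cq noise) and logistic-plateau amplification
curves whose exponential phase has the gene's base `E`, anchored so the 10%
of-plateau crossing reproduces the well's Cq; reference genes are constant
across samples up to noise.  The ethylene generator writes steady-state
cuvette traces: concentration = background + rate x weight / flow (nL/L for
rate in nL h⁻¹ g⁻¹, weight in g, flow in L/h), with optional Gaussian
noise, sampled every 5 s.

## qPCR quantification

Amplification efficiency per reaction comes from the window of linearity of
the log-linear phase: baseline (mean of cycles 1–5) subtracted, candidate
cycles above 10x baseline noise and below 90% of the observed plateau, and
the contiguous window of 4–6 cycles with the highest R² selected (ties to
the lowest-fluorescence window, where growth is purest; windows must reach
R² >= 0.995 or the curve is rejected as lacking an exponential phase).  The
fluorescence is linearised as `log10(F / (1 - F/P))` with `P` the observed
plateau — a plain log fit of a saturating curve is biased low by several
percent because the top of the window already bends; this first-order
correction removes that bias while leaving truly exponential curves
untouched.  Efficiencies are averaged per plate and the plate mean applied
to every gene on the plate.

Relative quantities use the across-sample mean Cq of each gene as
calibrator, `RQ = E^(meanCq - Cq)` (technical replicates first averaged on
the Cq scale); the normalisation factor of a sample is the geometric mean
of its reference-gene RQs and `NRQ = RQ / NF`.  Between-sample NRQ ratios
are invariant to the calibrator choice; for display one may rescale any
condition to 1.

geNORM stability: `M_g` is the mean over other genes of the SD across
samples of the pairwise log2 ratio; ranking by iterative exclusion of the
highest-M gene; `V_{n/n+1}` is the SD across samples of
`log2(NF_n / NF_{n+1})` with `NF_k` the geometric mean of the k most stable
genes.  Group comparisons use one-way ANOVA on log-scale quantities with
Fisher's protected LSD (pairwise t on the pooled MSE, df = N - k, declared
only when the omnibus F is significant) and an insert-and-absorb compact
letter display.

## Ethylene emission

A fruit in a flow-through cuvette at steady state satisfies
`rate = (mean excess concentration) * flow / weight`.  The trace is
summarised by the mean over its final five minutes (a fixed rule standing
in for manual selection of a representative measurement).  Rates below zero
(background above the measurement, which happens only at the noise floor of
pre-climacteric fruit) are flagged, and floored at half the smallest
positive rate before the log-transformed ANOVA/LSD comparison within a
stage.  Units are standardised to nL h⁻¹ g⁻¹ (numerically identical to
computing in ppbv, since ppbv = nL/L).

## Verification strategy and problem sizes

The acceptance script and test suite recompute, at fixed scaled sizes
chosen to keep a laptop run comfortable:

- quadrature likelihood vs a Monte-Carlo oracle (exact rectangle
  probabilities, 1e5 draws of each plant effect) on 20 random small
  instances, agreement within 3 MC standard errors;
- fixed-effect recovery on 20 simulated experiments of 30 plants/genotype x
  6 fruits (twice-weekly, four weeks), mean absolute error and the sign of
  a 4-day onset delay;
- type-I error of the truss LRT over 200 null replicates of 10 plants x 4
  fruits at 9 quadrature nodes, checked against the exact central 95%
  binomial interval for rate 0.05;
- the qPCR chain (efficiency 1.9 recovery as a plate mean of 24 wells; the
  18-fold NRQ change as the mean over 12 simulated datasets at Cq noise
  0.15, n=4 per group — a single dataset carries ~6% sampling error by
  design, so the average measures estimator accuracy; geNORM offender
  detection over 20 seeds; the V ladder against its definition);
- ethylene round-trip and linearity identities;
- byte-identical pipeline reruns, with estimated genotype contrasts
  required to match the sign of the *realized* simulated contrasts wherever
  those exceed 1 day — below the twice-weekly scoring resolution a sign is
  not identifiable by any correct estimator.

## Known limitations

- The likelihood treats the observation schedule as fixed and
  non-informative; informative inspection times are not modelled.
- The likelihood-ratio test uses the asymptotic chi-squared reference, as is
  standard for this model.  Our own calibration simulations show it is
  anti-conservative at very small designs: with 10 plants x 4 fruits the
  null rejection rate at nominal 5% is about 8–9% (the mean statistic is
  ~2.3 against a chi-squared-2 mean of 2), while 25 plants are already well
  calibrated (~4–5%).  We verified the inflation is not an optimisation or
  quadrature artifact.  Conclusions from designs with ten or fewer plants
  should treat p-values near the threshold with caution; no small-sample
  (Bartlett/Kenward-Roger-type) correction is applied.
- Standard errors are asymptotic (observed information); no profile or
  bootstrap intervals.
- Gauss–Hermite accuracy degrades for very diffuse plant effects relative
  to the censoring interval width; raise `nodes_per_dim` when `Sigma0`
  entries exceed ~5 days².
- The Cq-calling convention for simulated curves (10% of plateau, linear
  interpolation) is one documented choice among several used by real
  cyclers.
- The LSD letter display is greedy insert-and-absorb; with many groups the
  display is correct but not guaranteed minimal in letter count.
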