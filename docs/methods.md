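# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `quantal`, together with what the simulation-based
tests do and do not demonstrate.

## Model

Each record is a batch of `total` organisms of one population exposed to
`dose` units of a stimulus, of which `dead` responded. Batches are
assumed independent; within a batch, responses are exchangeable
(binomial), except where beta-binomial overdispersion is simulated
explicitly. The mean model per population is the classical probit line

    Φ⁻¹( E[dead/total] ) = a + b · log₁₀(dose),

with Φ the standard normal CDF. Base 10 is used throughout so that
lethal doses back-compute as `LD_π = 10^((Φ⁻¹(π) − a)/b)` in input dose
units; slopes are in probits per decade of dose.

### Control-mortality (Abbott) correction

Dose-0 batches measure experiment-induced mortality. For each population
a single control mortality `c` is estimated by maximising the product of
binomial likelihoods across its control replicates (numerically, L-BFGS-B
on [1e-9, 1−1e-9]; for this likelihood the optimum coincides with the
pooled proportion Σdead/Σtotal, which the unit tests exploit as a
closed-form oracle). Heterogeneity between control replicates is
quantified by a χ² homogeneity test and triggers a warning below p = 0.05
rather than altering the estimate: a shared-`c` model is still the only
estimand the correction needs, but the user should know the controls
disagree.

If `c` exceeds the threshold (default 0.05, configurable, including 0 to
force correction), treatment mortalities are rescaled by Abbott's
survival-ratio formula `1 − (1−raw)/(1−c)`, clamped to [0, 1]: values
below 0 (treatment killing less than control) carry no information a
probit fit can use. All-dead controls are an error — stimulus-free
mortality of 1 leaves nothing to correct against.

### Fitting

The GLM is fitted by iteratively reweighted least squares on the
(possibly corrected, hence non-integer) mortality proportions with batch
totals as binomial weights — never on probit-transformed proportions,
which cannot represent 0% or 100% batches. Start values are a flat line
at the overall mean mortality; convergence is declared when the largest
relative coefficient change drops below 1e-10, with a 100-iteration cap;
fitted means are clipped to [1e-10, 1−1e-10]. Complete separation,
all-0/all-1 responses, or a singular weighted design raise explicit
errors rather than returning garbage coefficients.

Replicate rows enter as separate binomial observations by default (the
design matrix contains only intercept and log-dose). A `pooling="pooled"`
option sums counts per dose first; with homogeneous replicates both give
identical coefficients (binomial additivity), and keeping rows separate
lets replicate disagreement inflate the dispersion, which is the point.

### Overdispersion and the heterogeneity factor

Dispersion is estimated as Pearson χ²/df. Coefficient covariance is the
inverse weighted information times the dispersion **floored at 1**: real
assays are often noisier than binomial but rarely genuinely cleaner, and
shrinking standard errors below binomial on the strength of a small-df
dispersion estimate is not defensible. The floored dispersion is the
heterogeneity factor `h` reported with every fit; `h` therefore enters
the covariance exactly once (Finney's `h × binomial covariance` — a
quasi-binomial covariance with φ > 1 *is* that product, so no further
inflation is applied downstream).

The confidence-limit multiplier is the normal quantile unless
heterogeneity is *established*, i.e. the fit's Pearson χ² is significant
at 0.05 (`het_p < 0.05`), in which case Student-t with the residual df
is used. Gating on significance rather than on `h > 1` matters: with
pure binomial data the dispersion ratio exceeds 1 about 40% of the time
by chance, and switching to t with 3 residual df on those fits pushes
empirical 95% LD₅₀ coverage to ~0.975; with the significance gate,
measured coverage over 500 simulated assays is ~0.95–0.97.

### Linearity screen

Observed and predicted dead counts are pooled per dose point and
compared by χ² = Σ(O−E)²/E with df = (#dose points − 2); a predicted
count of zero is floored at 0.5 and flagged. Populations failing the
screen (p < α, default 0.05) keep their LD/RR rows but are flagged
not-recommended, are excluded from the multi-population comparison, and
are drawn as segments without a regression line.

### Fieller limits, g, resistance ratios

With `m = (Φ⁻¹(π) − a)/b` and V the (h-inflated) coefficient covariance,
the confidence limits for log₁₀ LD are the Fieller roots

    [ m + g·v_ab/v_bb ± (t/b)·√( v_aa + 2m·v_ab + m²·v_bb − g·(v_aa − v_ab²/v_bb) ) ] / (1 − g),

with `g = t²·v_bb/b²`. As g → 0 these collapse to the delta-method
interval; at g ≥ 1 the slope is indistinguishable from 0 at the chosen
confidence and the fiducial region is unbounded — reported as an error
(or NaN limits in bulk tables), never as a fake finite interval. The
`use_h_in_g` switch (default on, Finney's convention) lets users divide
the heterogeneity back out of g and the limits.

Resistance ratios divide a population's LD by the reference's (lowest
LD, ties broken lexicographically). Their CIs use the delta method on
log₁₀ LD — `Var(log₁₀ LD) = (v_aa + 2m·v_ab + m²·v_bb)/b²` summed over
the two independent fits — with a normal multiplier; symmetric on the
log scale, per Robertson & Preisler. A population against itself is
exactly 1 by construction.

### Population comparison

Quasi-binomial models have no true likelihood, so the "likelihood ratio
test" is realised as the scaled deviance-difference F statistic,
`F = (D_null − D_full)/(Δdf·φ_full)`, with φ_full the full model's
Pearson dispersion and the full design containing dose, population and
their interaction. Pairwise post hoc tests refit each pair on its own
data (keeping dispersion pair-local) and are Holm–Bonferroni adjusted.
Populations failing the linearity screen are rejected with an explicit
error naming them, not silently dropped.

## Synthetic data

The generator draws `dead ~ Binomial(n, p*(d))` with
`p*(d) = c + (1−c)·Φ(b·(log₁₀ d − log₁₀ LD₅₀))` — the exact generative
inverse of Abbott's formula, so the correction module can be validated
for exact recovery. Beta-binomial replicates (intra-class correlation ρ,
shape `s = (1−ρ)/ρ`) provide the overdispersion mechanism matching the
quasi-binomial variance form. Control batches are drawn at dose 0 with
mortality `c`. Identical seeds give bit-identical tables.

Default validation conditions used in tests and the acceptance script:
slope 4 probits/decade, LD₅₀ 0.05, five doses log-symmetric around the
LD₅₀ (0.0125–0.2, consecutive ratio 2), 100 organisms per dose — a
typical larval-bioassay design; 200–500 replicate experiments for
Monte-Carlo summaries, 400 seeds for null rejection rates. The
Fieller-vs-bootstrap check uses fixtures with h = 1 only, because the
Gaussian-resampling oracle is exact there while heterogeneous fits
legitimately use the heavier Student-t multiplier that no Gaussian
bootstrap reproduces.

What the simulator does *not* emulate: dose-measurement error, serial
correlation between replicates run on different days, finite mixtures of
susceptible/resistant genotypes (the main real-world cause of linearity
failure — the tests emulate it with a plateau-shaped response instead),
or knockdown/time-to-event endpoints. Passing simulation tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to every field artefact.

## Numerical and degenerate-input choices

- Probit is defined on the open interval only; 0/1 mortalities are
  excluded from transformed displays but retained in count-based fits.
- Corrected mortalities are clamped to [0, 1]; doses are never
  converted between units.
- Fits with ≤ 0 residual df get h = 1 and no dispersion scaling (nothing
  to estimate it from); `heterogeneity_factor` raises on such designs.
- Dose points far below the LD₅₀ combined with an Abbott correction can
  leave tiny positive corrected mortalities where the model predicts
  ~0; the Pearson dispersion (hence h) then explodes and the Fieller
  limits degenerate to unbounded. This is faithful quasi-binomial
  behaviour, and a signal the dose design is carrying uninformative
  tail points — not a numerical bug.
- The control-mortality optimiser reports an exact 0 at the lower
  boundary instead of the 1e-9 box constraint.

## Known limitations

- Single stimulus per fit; joint modelling of several insecticides is
  out of scope (one plot per stimulus is produced).
- No logit/complementary-log-log links and no 4/5-parameter log-logistic
  curves; tools dedicated to flexible curve families cover those.
- The global F-test's type-I error degrades when the dose design leaves
  many fully saturated (0%/100%) cells, which deflate the pooled
  dispersion estimate; keep at least a few informative doses per
  population.
- Henderson–Tilton / Schneider–Orelli corrections for unequal control
  exposure are not implemented.
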