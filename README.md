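# quantal

Probit analysis of quantal-response bioassays.

Bioassays expose batches of organisms (mosquito larvae, cell lines,
parasite cultures, ...) to graded doses of a stimulus — typically an
insecticide or another xenobiotic — and record a binary outcome per
batch: how many of the `Total` exposed were `Dead`. `quantal` turns
tables of such records into dose–response estimates and population
comparisons, the bread-and-butter statistics of insecticide-resistance
monitoring:

- **Abbott's correction** for baseline mortality: the control (dose 0)
  mortality `c` of each population is estimated by shared-parameter
  binomial maximum likelihood across control replicates, and when
  `c` exceeds a threshold (default 5%) treatment mortalities are
  rescaled as `corrected = 1 − s_T / s_C` (survival ratio), with a
  χ² homogeneity warning when control replicates disagree.
- **Probit regression**: per population, a binomial GLM with probit link
  fitted by IRLS, `Φ⁻¹(E[Y]) = a + b·log₁₀(dose)`, weighted by batch
  totals, with quasi-binomial (Pearson) dispersion. A χ² homogeneity
  test of observed vs predicted dead counts per dose screens for
  departures from log-dose linearity (mixed populations, threshold
  effects).
- **Lethal doses with fiducial limits**: `LD_π = 10^((Φ⁻¹(π) − a)/b)`
  at 25/50/95% by default, with Fieller/Finney confidence limits that
  inflate the coefficient covariance by the heterogeneity factor
  `h = max(1, χ²_Pearson/df)` and report Finney's
  `g = t²·Var(b)/b²` (limits do not exist once `g ≥ 1`).
- **Resistance ratios**: `RR = LD(population)/LD(reference)` against the
  most susceptible population, with delta-method CIs on the log scale
  (Robertson & Preisler).
- **Population comparison**: a quasi-binomial deviance F-test of the
  pooled-dose null model against the full `dose × population` model,
  followed (for >2 populations) by pairwise refits with Holm–Bonferroni
  adjustment.
- **Probit graphs**: probit-transformed corrected mortality against
  log₁₀ dose, regression lines with confidence bands for populations
  passing the linearity screen, point-to-point segments for those that
  fail it.
- **A synthetic-assay simulator** with known ground truth
  (`p*(d) = c + (1−c)·Φ(b·(log₁₀ d − log₁₀ LD₅₀))`, binomial or
  beta-binomial counts) for power exploration and validation.

## Input format

Delimited text (CSV, or TSV by extension) with mandatory columns
`Strain` (or `Population`), `Dose`, `Total`, `Dead` — case-insensitive,
any order. `Dose` 0 marks control batches. Optional columns:
`Replicate` (default `"1"`), `Date`, `Insecticide`. Doses are never
converted; every result is reported in input units.

## Worked example

Simulate a susceptible and a 10×-resistant strain (true slopes 4, true
LD₅₀ 0.05 and 0.5, 12% baseline mortality), then run the full analysis:

```sh
quantal simulate --populations SUS:4:0.05 --populations RES:4:0.5 \
    --doses 0.0125,0.04,0.125,0.4,1.25,4.0 --n-per-dose 150 \
    --control-mortality 0.12 --control-n 100 --seed 11 --out assay.csv
quantal analyze --input assay.csv --output-dir report
```

which prints (and writes to `report/fits.csv`, `report/ld_rr.csv`,
`report/comparison.csv`, `report/probit_assay.png`, `report/manifest.json`):

```
population    slope  slope_se  intercept  intercept_se   chi2_p        h  n_points  abbott_applied
       SUS 3.474202  0.386519   4.661117      0.530624 0.213056 2.307257         6            True
       RES 4.420799  0.357622   1.119409      0.128472 0.986874 1.000000         6            True
population  level       ld   ci_low  ci_high        g        h reference        rr    rr_low   rr_high
       SUS   0.50 0.045537 0.038701 0.053514 0.047548 2.307257       SUS  1.000000  1.000000  1.000000
       RES   0.50 0.558195 0.508694 0.612744 0.025139 1.000000       SUS 12.258080 10.209257 14.718068
...
global comparison: F = 300.181 (2, 8), p = 2.99e-08
```

Reading it: control mortality exceeded the 5% threshold, so Abbott's
correction was applied (`abbott_applied`). Both strains pass the
linearity screen (`chi2_p` ≥ 0.05). The susceptible LD₅₀ is estimated at
0.046 (truth 0.05) and the resistant at 0.56 (truth 0.5), giving a
resistance ratio of ~12 (truth 10). The F-test confirms the two strains
respond differently. A population failing the linearity screen would be
excluded from the comparison and drawn as dashed segments, with no
regression line, in `probit_assay.png`.

The same pipeline is available programmatically:

```python
import quantal as q

table = q.read_assay_table("assay.csv")
bundle = q.analyze_table(table)
bundle.fit_table        # slope/intercept/SE/h per population
bundle.ld_rr_table      # LD and RR with confidence limits
bundle.comparison       # global + pairwise tests
```

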