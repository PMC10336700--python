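# bivoi

Closed-form evaluation of the unit normal loss integral (UNLI) in one and two
dimensions, with a value-of-information toolkit built on top of it for
3-strategy decision problems.

The 2-D UNLI is `E(max(Y1, Y2, 0))` for a bivariate normal `(Y1, Y2)`,
evaluated exactly from univariate normal functions plus the bivariate normal
CDF — no Monte-Carlo error. For a decision among three strategies, with `Y1`
and `Y2` the incremental net benefits of the two non-reference strategies,
the expected value of perfect information (EVPI) is
`E(max(Y1, Y2, 0)) - max(mu1, mu2, 0)`.

Components:

- `bivoi.core_unli` — closed-form 1-D/2-D UNLI, per-pair term decomposition,
  bivariate normal CDF (Owen's T reduction), EVPI from bivariate-normal
  parameters.
- `bivoi.mc_oracle` — seeded Monte-Carlo estimator of `E(max(Y1, Y2, 0))`,
  the independent verification oracle.
- `bivoi.simulation_grid` — 252-setting factorial verification study
  (closed form vs MC, z-score report).
- `bivoi.trial_evpi` — patient-level pipeline for a parallel 3-arm trial:
  net benefits, incremental-NB bivariate-normal parameterisation, closed-form
  and stratified-bootstrap EVPI, Rubin pooling of per-imputation estimates,
  WTP sweeps and curve plotting.
- `bivoi.synthetic_trial` — synthetic 3-arm trial generator (log-normal
  costs, clipped-normal QALYs, Gaussian copula, MCAR missingness) with
  controllable ground truth.
- `bivoi.cli` — `bivoi` command-line interface.

## Library quick start

```python
from bivoi import BVNParams, evpi_from_bvn, unli_2d

p = BVNParams(mu1=-4734, mu2=-2668, sigma1=4678, sigma2=4645, rho=0.50)
evpi_from_bvn(p)   # ~1019 (currency units)
unli_2d(p)         # E(max(Y1, Y2, 0))
```

```python
from bivoi import case_study_like, generate, wtp_sweep

trial = generate(case_study_like(seed=1))
curve = wtp_sweep(trial, [25_000, 50_000, 75_000, 100_000], B=1000, seed=0)
print(curve.points)
```

## CLI

```sh
# closed-form 2-D UNLI / EVPI with term decomposition and an MC check
bivoi unli --mu1 -4734 --mu2 -2668 --sigma1 4678 --sigma2 4645 --rho 0.5 \
      --mc-check 100000 --seed 1

# 1-D mode
bivoi unli --mu 0 --sigma 1

# 252-setting factorial verification study (CSV report + pass/fail summary)
bivoi verify --n 100000 --seed 0 --out verify.csv

# synthetic 3-arm trial dataset
bivoi synth --preset case-study --seed 1 --out trial.csv

# EVPI from patient-level data, both methods, with a curve plot
bivoi evpi trial.csv --arms single,double,triple --reference single \
      --wtp 25000 --wtp 50000 --wtp 75000 --wtp 100000 \
      -B 1000 --seed 0 --out evpi.json --plot curve.png
```

Trial CSVs have the header `patient_id,arm,cost,qaly`; an empty cell is a
missing value. Analyses refuse missing data unless `--missing complete-case`
or `--missing mean-impute` is selected (externally imputed datasets can be
pooled with `bivoi.trial_evpi.rubin_pool`). Exit codes: 0 success,
2 validation error, 1 runtime error.

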