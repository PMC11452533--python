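# riclpm

Random-intercept cross-lagged panel models (RI-CLPM) for multi-construct
longitudinal cohorts, with full-information maximum likelihood (FIML) under
missing data, nested model comparison, and a synthetic cohort generator with
saved ground truth.

The package is built around a four-construct, four-wave perinatal panel:
maternal relationship satisfaction, positive affect, and depressive and
anxiety symptoms measured in late pregnancy and at 6, 18 and 36 months
postpartum, with a wellbeing-spectrum polygenic index (PGI) predicting the
stable between-person components. Cohort data of this kind are
access-restricted, so the package ships a calibrated generator that
reproduces the statistical structure of such a cohort — trait-like
between-person variance, wave-varying within-person dynamics, published
attrition rates, item-level reliabilities — and every estimator is validated
against that known ground truth.

## The model

For constructs k = 1..K observed at waves t = 1..T:

```
x_kt = mu_kt + RI_k + w_kt                    (observed composite)
RI_k = b_k (g - mu_g) + u_k,   u ~ MVN(0, Psi)    (between person)
w_.1 ~ MVN(0, Sigma_w1)
w_.t = B_t w_.(t-1) + eps_t,   eps_t ~ MVN(0, Theta_t)   (within person)
```

The random intercept `RI_k` carries each person's time-invariant standing on
construct k; the VAR(1) part carries within-person dynamics, with the
diagonal of `B_t` the autoregressive paths and the off-diagonal the
cross-lagged paths. The covariate `g` (here a polygenic index, observed with
missingness) predicts the random intercepts inside the joint likelihood.
Three nested constraint schemes tie the transition matrices over time:
model 1 (`constrained`, one shared B), model 2 (`first_free`, the
pregnancy-to-postpartum transition free, later ones shared) and model 3
(`free`). Fits are compared with likelihood-ratio chi-square tests and
CFI / TLI / RMSEA / AIC / BIC.

Estimation maximizes the casewise (missingness-pattern) normal
log-likelihood by Fisher scoring with analytic gradients; standard errors
come from the observed information, optionally sandwich-robust.

## Worked example

Simulate a cohort, apply the study's exclusion cascade, and fit the three
schemes (this is `analysis/03_fit_models.py`; n = 20,000 before exclusions):

```
model1 (constrained): q=88 ll=65637.7
model2 (first_free):  q=104 ll=65918.9
model3 (free):        q=120 ll=65939.2

 model   CFI   TLI         AIC         BIC    LogLik  RMSEA
model1 0.995 0.992 -131099.497 -130415.685 65637.748  0.020
model2 1.000 1.000 -131629.792 -130821.651 65918.896  0.005
model3 1.000 1.000 -131638.373 -130705.903 65939.187  0.000

model 3 vs model 1: dchi2(32) = 602.9, p = 1.52e-106
model 3 vs model 2: dchi2(16) = 40.6, p = 0.00064
selected: model3
grand means tied over waves: dchi2(12) = 5462.2, p = 0
```

The generator's truth has wave-varying dynamics, so the fully free model 3
wins both chi-square tests (on 32 and 16 released parameters — the exact df
the four-construct design implies) and the grand means differ across waves
(12 released parameters). `analysis/04_report_structure.py` then reports the
between-person structure of the selected model:

```
intra-class correlations: {'relsat': 0.63, 'posaff': 0.58, 'dep': 0.48, 'anx': 0.48}
PGI -> RI standardized betas: {'relsat': 0.09, 'posaff': 0.09, 'dep': -0.17, 'anx': -0.16}
RI variance explained across indicators: 48-63%
standardized RI loadings: 0.69-0.79
32/48 transition paths significant at p<0.01; autoregressive range [0.07, 0.36]
residual correlations range [-0.34, 0.39]
```

Each ICC is the share of a construct's variance owned by its stable
component; the standardized betas say the polygenic index raises the stable
wellbeing components and lowers the stable symptom components by the
configured small-to-moderate amounts, all recovered from the simulated data.

The same pipeline runs from the command line on item-level CSVs
(`<construct>_<item#>_t<wave>` columns plus `pgi` and exclusion flags):

```sh
riclpm simulate cohort/ --n 20000 --seed 1 --apply-exclusions
riclpm run cohort/items.csv results/run1 --seed 1
riclpm compare results/run1
```

The numbered scripts under `analysis/` walk the full study flow:
cohort generation and exclusions (01), scale scoring and descriptives (02),
model fitting and comparison (03), structure reports (04), and the
parameter-recovery and test-calibration experiments (05).

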