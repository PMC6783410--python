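# gliorad

MRI radiomics for newly diagnosed glioblastoma (GBM): a tested,
end-to-end re-implementation of a multi-sequence texture-analysis and
survival-modeling pipeline, together with a synthetic phantom-cohort
generator so that every stage can be validated against planted ground
truth without access to clinical images.

It is intended for researchers in quantitative neuro-imaging and
imaging-biomarker methodology who want a transparent, scriptable version
of this class of analysis: normalize structural MR series to 256 gray
levels, extract a fixed 489-name texture/shape catalog over the enhancing
core (VOI_core) and peritumoral edema (VOI_edema), stratify survival risk
with a supervised principal component model, predict the MGMT-promoter
methylation label and long-term survival with L1-penalized logistic
regression under repeated nested cross-validation, and combine radiomic
and molecular risk into a three-group stratification.

## The models in brief

**Supervised principal components for survival.** Every standardized
feature x_j gets the univariate Cox score statistic
s_j = U_j(0)/√I_j(0) (Breslow ties); features with |s_j| > θ are
retained, θ tuned by 10-fold cross-validation on the held-out Cox
likelihood-ratio statistic. The continuous risk score is the first
principal component of the retained standardized submatrix, oriented so
higher = higher hazard; a median split of training scores gives the
discrete high/low classification.

**L1-penalized logistic regression.** minimize
−(1/n)·loglik(β) + λ‖β‖₁ along a 100-point log-spaced path from λ_max;
λ_min minimizes mean k-fold binomial deviance; reported accuracy,
sensitivity, specificity, PPV and NPV come from 10-fold-outer nested CV
repeated 5 times (inner tuning never sees held-out cases).

**Survival analysis.** Kaplan-Meier product-limit curves with medians at
the first time S(t) ≤ 0.5, log-rank tests, and a multivariate Cox model
(age, KPS, surgery, methylation status, radiomic risk) reporting hazard
ratios with 95 % Wald intervals.

**Phantom cohort.** Ellipsoidal enhancing cores with a controllable
Gaussian-random-field texture (known SD and correlation length) inside an
edema shell; exponential proportional-hazards survival driven by the
planted lesion properties; a weakly texture-linked binary molecular
label; independent exponential censoring. Fully deterministic given one
seed. See `docs/methods.md` for every formula and convention.

## Worked example

The numbered drivers under `analysis/` run the whole study on a 100-case
phantom cohort (volumes land under `scratch/`, tables under `results/`):

```bash
python analysis/01_simulate_cohort.py    # phantom cohort -> scratch/cohort
python analysis/02_extract_features.py   # 489-feature table (~70 s)
python analysis/03_prognostic_spca.py    # radiomic risk stratification
python analysis/04_predict_mgmt.py       # methylation-label prediction
python analysis/05_survivor_sweep.py     # long-term-survivor sweep
python analysis/06_survival_report.py    # KM / Cox / combined risk
```

Output of steps 03, 04 and 06 on the default seed:

```
tuned threshold = 5.039; 14 features retained
median OS: high-risk 6.0 mo (n=50), low-risk 42.5 mo (n=50); log-rank p = 8.1e-06

nested-CV prediction of the methylation label (average of 5 repeats):
  accuracy      58.6 %
  sensitivity   70.4 %
  ...
7 features selected at lambda_min = 0.1047

combined_risk: log-rank p = 2.6e-05   (medians 5.4 / 16.5 / 42.5 months)
  pMGMT unmethylated         1.27 (0.75-2.13)  p=0.371
  Radiomic high-risk         3.15 (1.77-5.62)  p=0.000101
```

Reading this: the screening threshold tuned to 5.04 retains 14 of 489
features; the resulting high/low split separates survival strongly
because the phantom hazard really is driven by planted texture and
volume. The methylation label is only weakly linked to texture by
design, so its nested-CV accuracy sits modestly above chance — the
qualitative behaviour of this class of predictor. In the multivariate
Cox model the radiomic stratification stays prognostic after adjustment
for the molecular label and clinical covariates.

The same stages run on real data: `NIfTI` volumes + masks per case and a
clinical CSV (`case_id,age,sex,kps,surgery,pmgmt,os_months,event`), or —
bypassing the image stages — a precomputed feature CSV via
`PipelineConfig(features_csv=..., clinical_csv=...)`. A `gliorad` CLI
(`simulate`, `extract`, `prognosticate`, `predict-mgmt`,
`survivor-sweep`, `validate`, `run-all`) wraps the same library calls.

## Layout

```
src/gliorad/        library: synthetic, preproc, voi, catalog, features,
                    spca, lasso, survival, pipeline, cli
analysis/           numbered narrative drivers (the study, start to end)
tests/              pytest suite incl. brute-force oracles and
                    acceptance-level checks
scripts/acceptance.py
docs/methods.md     full model/convention documentation
```
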