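# radsurv

Predicting **biochemical recurrence-free survival (BCRFS)** after
prostate radiotherapy by combining T2-weighted MRI radiomics, hypoxia
gene-signature scores (Ragnum-32, West-28) and clinical variables — as a
tested, reusable Python pipeline. It is aimed at imaging/outcomes
researchers who want to run, audit or extend this kind of radiogenomic
survival analysis, including a synthetic cohort generator so the whole
chain runs at desk scale with no patient data.

## What it does

1. **Synthetic cohorts** (`radsurv.synthcohort`) — 3D images with
   prostate masks (stationary Gaussian random fields whose correlation
   length ℓ is a per-patient "texture dial"), realistic clinical
   marginals, correlated hypoxia scores, multi-scanner intensity batch
   effects, and exponential survival with hazard
   h₀·exp(βᵀz + γ·s(ℓ)), s = standardized log ℓ. Defaults are
   calibrated to a 178-patient high-risk cohort with a 32% recurrence
   rate and 84-month median follow-up.
2. **Intensity preparation** (`radsurv.imgprep`) — Nyúl piecewise-linear
   histogram standardization, isotropic resampling, fixed-bin-number
   grey-level discretization.
3. **Radiomics** (`radsurv.texturefeat`) — first-order, GLCM, GLRLM,
   GLSZM, GLDM, NGTDM and shape features; original image plus the 8
   sub-bands of an undecimated 3D Coiflet-1 wavelet transform.
4. **Harmonization** (`radsurv.combat`) — parametric / nonparametric
   empirical-Bayes batch adjustment across scanners (validated against
   Bioconductor `sva::ComBat`).
5. **Robustness screen** (`radsurv.robustsel`) — ICC(2,1) > 0.8 across a
   bin-number x voxel-size sweep, settings treated as raters.
6. **Feature selection** (`radsurv.cvselect`) — tumour-volume and
   redundancy filters, then univariable / multivariable-LR / MRMR
   selectors compared over 200 event-matched stratified CV samples
   (40 x 5-fold), with stability (selection-frequency) ranking.
7. **Survival modelling** (`radsurv.coxsuite`) — Cox partial-likelihood
   Newton–Raphson (Efron/Breslow ties), Harrell's C, nested
   likelihood-ratio tests, AIC (= 2k − 2·logPL), 500-resample bootstrap
   validation, and the four-model ladder: clinical, +hypoxia,
   +radiomics, +both. The nested test can also be reconstructed from two
   printed AIC values alone: LR = AIC_base − AIC_ext + 2Δk, p =
   χ²_Δk upper tail.

See `docs/methods.md` for the models, conventions and design choices.

## Worked example

```python
import pandas as pd
from radsurv.synthcohort import CohortConfig, generate_cohort, cohort_frame
from radsurv.coxsuite import build_four_models, compare_from_aic

cfg = CohortConfig(seed=1)              # 178 patients, default calibration
tab = cohort_frame(generate_cohort(cfg))
print(f"events: {tab.event.sum()}/{len(tab)} ({100*tab.event.mean():.1f}%)")

rad = pd.DataFrame({"texture_s": tab["texture_s"]})  # oracle texture covariate
report = build_four_models(tab, rad, bootstrap_B=200, seed=2)
for name, fit in report.fits.items():
    c = report.bootstrap[name]
    line = f"{name:28s} AIC {fit.aic:7.2f}  C {c.median:.2f} [{c.ci[0]:.2f}-{c.ci[1]:.2f}]"
    if name in report.comparisons:
        line += f"  p_vs_clinical {report.comparisons[name].p_value:.4f}"
    print(line)
print("AIC-only reconstruction:", round(compare_from_aic(481.86, 478.71, 3), 3))
```

prints

```
events: 53/178 (29.8%)
clinical                     AIC  492.02  C 0.69 [0.61-0.71]
clinical+hypoxia             AIC  494.07  C 0.69 [0.65-0.71]  p_vs_clinical 0.3773
clinical+radiomics           AIC  478.11  C 0.73 [0.70-0.74]  p_vs_clinical 0.0001
clinical+radiomics+hypoxia   AIC  479.88  C 0.73 [0.69-0.74]  p_vs_clinical 0.0004
AIC-only reconstruction: 0.027
```

Reading this: on a synthetic cohort with a planted texture effect, the
clinical-only model concordance is ~0.69; adding the (oracle) texture
covariate lowers AIC by ~14 and is significant in the nested LR test,
while adding the hypoxia scores — which carry no outcome signal in the
generator — raises AIC and is not. The last line recovers a nested-test
p-value purely from two AIC values and the added degrees of freedom.

The same analysis end to end, from a config file:

```sh
radsurv run --config demo.yaml --seed 7    # simulate → … → model report
radsurv extract --config demo.yaml         # any single stage, from files
```

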