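# eegaec

Source-space EEG functional connectivity around the subgenual anterior
cingulate (sgACC) and dorsolateral prefrontal cortex (DLPFC), the circuit
most consistently implicated in major depression.  The package implements
the full analysis chain a resting-state connectivity study needs —

* **orthogonalized amplitude-envelope correlation (AEC)**: per frequency
  band, ROI timeseries are band-pass filtered, jointly replaced by the
  closest set of mutually orthogonal signals (symmetric leakage
  correction for volume conduction), converted to Hilbert envelopes and
  Pearson-correlated per ROI pair;
* **minimum-norm source reconstruction** with a diagonal noise model:
  `K = Gᵀ(GGᵀ + λ²I)⁻¹W`, `G = WL`, `W = C^(−1/2)`, λ² = 1/9 by default;
* **non-parametric group statistics**: two-tailed permutation t-tests
  (Welch statistic, add-one Monte-Carlo p) per ROI-pair × band cell, with
  Benjamini–Hochberg FDR over the 36-cell family;
* **clinical associations**: Monte-Carlo permutation tests of Pearson
  correlations between AEC and covariates, FDR across the covariate
  family, and an ANCOVA-style adjusted linear model;
* **diagnostic evaluation**: leave-one-out cross-validated RBF-SVM
  (Gaussian kernel, box constraint 3) on the four sgACC–DLPFC AEC
  features, reporting sensitivity / specificity / accuracy;
* **a synthetic-cohort generator** that plants band-specific envelope
  coupling (amplitude modulation of band-limited carriers by correlated
  slow modulators), mixes sources to sensors through a toy lead field
  with additive noise, and ties a clinical covariate ("lifetime number of
  episodes") to the planted connectivity — so every downstream stage is
  testable against known ground truth.

See `docs/methods.md` for the models, defaults and known limitations.

## Worked example

A complete synthetic study — 20 controls vs 20 patients, 60 s at 256 Hz,
32 sensors, with a planted beta-1 (13–17 Hz) coupling deficit at the
sgACC_L–DLPFC_R pair (modulator correlation 0.7 in controls vs 0.2 in
patients) — straight through the pipeline:

```python
from eegaec.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    out_dir="demo_out",
    seed=7,
    simulate={"n_per_group": 20, "fs": 256.0, "duration": 60.0, "n_sensors": 32},
)
report = run_pipeline(cfg)
```

or equivalently from the shell, with the same settings in a YAML file:

```bash
eegaec run-all --config demo.yaml
```

The beta-1 rows of the resulting `group_stats.tsv`:

```
roi_a    roi_b    band   t            p             p_unc_lt_01  fdr_reject
DLPFC_L  DLPFC_R  beta1   1.75        0.086         False        False
DLPFC_L  sgACC_L  beta1   0.21        0.840         False        False
DLPFC_L  sgACC_R  beta1  -0.16        0.875         False        False
DLPFC_R  sgACC_L  beta1   7.35        9.999e-05     True         True
DLPFC_R  sgACC_R  beta1  -0.17        0.878         False        False
sgACC_L  sgACC_R  beta1  -1.49        0.149         False        False
```

Exactly the planted cell (sgACC_L–DLPFC_R, beta-1) stands out: t = 7.35
with the sign convention *t > 0 means controls > patients* — controls
carry the stronger coupling — at the smallest attainable permutation p
(1/10001), surviving the 36-cell FDR (step-up threshold 0.0014).  All 30
unplanted cells are quiet.

`clinical.tsv` (patients only, permutation Pearson correlations with the
sgACC_L–DLPFC_R beta-1 AEC, FDR across the three covariates):

```
covariate      n   r       p          fdr_reject
onset_age      20   0.199  0.397      False
episodes       20  -0.806  0.00030    True
episode_weeks  20  -0.292  0.230      False
```

The planted negative association — fewer envelope-coupling units, more
lifetime episodes — is recovered (r = −0.81) and survives adjustment for
age, sex, education and severity (ANCOVA F(6,13) = 5.90, p = 0.0037);
the covariates generated independently of connectivity stay null.

`classifier.json` reports the leave-one-out SVM on the four sgACC–DLPFC
beta-1 features: sensitivity 0.80, specificity 0.90, accuracy 0.85 over
the 40 subjects.

All outputs carry the configuration hash and master seed; rerunning the
same configuration reproduces every file byte for byte.

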