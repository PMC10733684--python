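# nirconfound

Confounder control for machine-learning assessment of tissue-engineered
constructs (TECs) from near-infrared (NIR) spectra.

## The problem

Diffuse-reflectance NIR spectroscopy is a non-destructive way to follow
neotissue growth in engineered cartilage: spectra (943.8–2491 nm) reflect the
overall chemical composition of a construct, and classifiers can read
maturity from them. But the spectrum is label-free and non-specific, so it
also carries every **non-neotissue constituent** of the sample — the scaffold
chemistry (an HAV N-cadherin mimetic peptide conjugated to a NorHA hydrogel),
supplemented growth factors (BMP-9 or TGF-β1), and the storage/lysis buffer
(PBS or M-PER). When such a constituent is unevenly distributed between the
classes of interest it becomes a confounder: a model trained to predict
maturity may instead learn the buffer's absorption band.

`nirconfound` implements, as a reusable and tested pipeline:

- **Workflow A** — detectability: stratified 10-fold CV of nine classifier
  families per constituent flag, pooled out-of-fold F1/AUC
  (F1 = 2TP/(2TP+FP+FN); AUC as the Mann–Whitney statistic
  P(s⁺ > s⁻) + ½P(s⁺ = s⁻)).
- **Workflow B step 1** — confounding: per constituent, an *uncontrolled*
  training design in which every Day-28 sample carries the constituent and
  every Day-7 sample lacks it, versus a *controlled* design built by
  propensity-score matching (logistic regression of Day-28 membership on the
  four flags; greedy 1:1 nearest-neighbour matching on the logit, without
  replacement). Both model groups are evaluated on the same test set;
  per-algorithm score differences are compared with the Wilcoxon rank-sum
  test.
- **Workflow B step 2** — Monte Carlo cross-validation: 100 seeded random
  splits with Day-7 undersampling; per-iteration ΔF1 (controlled −
  uncontrolled) summarised by a paired t-test with 95% CI.
- A **synthetic-data generator** reproducing the study design (69 test
  constructs: 41 Day-7 / 28 Day-28 with the published constituent marginals,
  12 controls, 3 technical replicates, 2 missing) with controllable spectral
  effect sizes, so the whole pipeline is testable without the measured data.

All spectra are preprocessed with a Savitzky–Golay first derivative
(window 13, 2nd-order polynomial) before any analysis; technical replicates
are averaged before cross-validation and testing, and always share one
train/test membership (the "replicate trap").

## Worked example

```sh
python examples/04_monte_carlo_confounding.py
```

prints, for the default synthetic dataset (seed 0):

```
mper   mean dF1 +0.993  CI95 [+0.985, +1.001]  p = 2.39e-139
hav    mean dF1 +0.000  CI95 [+0.000, +0.000]  p = 1
bmp9   mean dF1 +0.003  CI95 [-0.001, +0.007]  p = 0.127
tgfb1  mean dF1 +0.118  CI95 [+0.055, +0.181]  p = 0.000347
```

Each line is one constituent's Monte Carlo confounding assessment: the mean
improvement in maturity-prediction F1 obtained by controlling for it. The
M-PER buffer — a strong, narrow band at ~1050 nm deliberately aligned with
maturity in the uncontrolled design — wrecks the uncontrolled models (ΔF1
near 1, i.e. they go from useless to near-perfect once controlled), while
the subtle broadband signatures barely bias training on this synthetic
dataset. `examples/02_detect_constituents.py` shows the complementary
Workflow A result: every constituent is *detectable* (best F1 1.00 for
M-PER down to 0.48 for TGF-β1), which is precisely what makes each a
potential confounder.

The CLI wraps the same library:

```sh
nirconfound run-all --seed 0 --out run0          # full pipeline + artifacts
nirconfound simulate --seed 0 --out data/        # just the synthetic CSVs
nirconfound report run0                          # summarise a finished run
```

`run-all` writes `table3_style.csv` (detection metrics), `table4_style.csv`
(controlled vs uncontrolled), `fig4_style.csv` + `mc_summary.csv` (Monte
Carlo), `group_mean_spectra.csv`, membership CSVs, an `algorithms.lock`
parameter dump and a seed-stamped log; two runs with one root seed produce
byte-identical CSVs.

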