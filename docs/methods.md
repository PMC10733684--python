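# Methods

## Data model and preprocessing

A *sample* is one tissue-engineered construct with an incubation day
(7 = immature, 28 = mature), a control flag, four binary non-neotissue
constituent flags (`mper`, `hav`, `bmp9`, `tgfb1`; `bmp9` and `tgfb1` are
mutually exclusive, controls carry no HAV or growth factors), and 1–3
technical replicate spectra on a shared strictly-increasing wavelength grid
(default 943.8–2491 nm, 256 channels).

Every analysis operates on Savitzky–Golay first-derivative spectra
(window 13 channels, 2nd-order polynomial). The derivative is taken per
channel index, treating the grid as evenly indexed — the standard
chemometrics convention for this instrument class, and what a toolkit
operating on the channel grid computes. Edge channels are obtained by
evaluating the polynomial fitted to the first/last full window at the edge
positions, so output length equals input length and grid alignment is
preserved across spectra (`scipy.signal.savgol_filter(mode="interp")`
implements exactly this; the test suite checks it against an independent
windowed polynomial-fit oracle to 1e-9).

Replicate handling: replicates are averaged channel-wise to one spectrum per
sample before cross-validation (Workflow A) and before evaluation on any
test set (Workflow B); since the derivative is linear, preprocessing and
averaging commute. Training in Workflow B uses replicate-level spectra. All
replicates of a sample always share one train/test membership. Before the
Monte Carlo step the dataset is cleaned: channels with zero variance across
all spectra are dropped, and samples with missing technical replicates are
brought to 3 by *simple replacement* — duplicating the sample's first
available replicate. (The phrase admits other readings, e.g. duplicating a
random replicate; duplicating the first is the simplest deterministic one.)

## Synthetic-data generator

The generator is first-class, tested code; it defines the study conditions
for every downstream test.

**Roster.** 69 test constructs (41 Day-7, 28 Day-28) plus 12 cell-free
controls (6 per day, stored in PBS, i.e. `mper=False` — the buffer
assignment of controls is not fixed by the design, so the neutral default
was chosen). Only per-day one-way marginals of the four flags are part of
the published design (Day-7: 11 M-PER / 24 HAV / 22 BMP-9 / 14 TGF-β1;
Day-28: 10 / 16 / 12 / 7). The generator takes explicit joint cell counts
over (growth factor × HAV × M-PER) per day; the shipped default allocation
apportions the HAV and M-PER totals across the three growth-factor cells by
largest remainder and sets each cell's HAV∩M-PER overlap to the rounded
independence expectation clipped to feasibility. Any feasible joint with
correct marginals serves equally for testing; the true joint table is not
public.

**Spectra.** Each clean spectrum is

    base(λ) + maturity(λ)·[day = 28, not control]
            + Σ_f signature_f(λ)·[flag f]

with Gaussian-mixture shapes normalised to unit peak magnitude:

| component | shape | amplitude (reflectance units) |
|---|---|---|
| base | offset 0.55 + bands at 1450/1940/1150 nm | 0.10–0.30 |
| maturity | broad bands at 1500/2100/1180 nm | 0.03 |
| M-PER | single narrow band, 1050 nm, σ 25 nm | 0.05 |
| BMP-9 | 3 broad bands across the grid | 0.010 |
| HAV | 3 broad bands across the grid | 0.006 |
| TGF-β1 | 3 broad bands across the grid | 0.004 |

Per replicate, a constant offset (SD 0.002), a smooth random cubic baseline
drift (coefficient SD 0.003) and iid channel noise (SD 0.004) are added.
Controls keep the immature baseline (no maturity term) — immature constructs
resemble the cell-free scaffold. Exactly `n_missing_replicates` (default 2)
non-control samples, chosen by a seeded draw, lose one replicate.

Amplitudes were set by signal-to-noise arithmetic on the derivative scale:
the narrow M-PER band survives the derivative at ~25× the per-channel
derivative noise (strongly detectable, like a bulk buffer), the maturity
shift at ~3× (reliably detectable), and the broadband constituent
signatures at <1× per channel, detectable only by pooling many channels
(high-to-fair classification, mirroring the qualitative pattern of real
constructs). The M-PER amplitude is ≥5× every subtle amplitude, and the
maturity shift exceeds the subtle effects.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: absolute reflectance levels, instrument response
and wavelength-dependent noise, water-band dominance, scatter effects,
biological heterogeneity between constructs beyond iid noise, and any
correlation between constituents and neotissue chemistry. Tests on this
generator validate the *pipeline logic* (partitioning, matching, metric
arithmetic, seeding) and the *qualitative* confounding phenomenology, not
numeric performance on measured spectra.

**Randomness.** One root seed; independent sub-streams per stage
(`numpy.random.SeedSequence` spawn keys), so adding a stage never perturbs
earlier draws; Monte Carlo iteration seeds derive from
(root seed, constituent, iteration) and are recorded in the output.

## Classifier zoo

Nine families behind one train/score contract, with fixed hyperparameters:
AdaBoost (50 estimators, learning rate 1), gradient boosting (100 trees,
rate 0.1, depth 3, min-split 2), kNN (k = 7, Euclidean, uniform), logistic
regression (ridge, C = 1), Gaussian naive Bayes, a neural network (one
hidden layer of 100 ReLU units, Adam, ≤200 iterations), random forest
(10 trees, min-split 5), an RBF SVM (C = 1, tol 1e-3, 100-iteration cap;
scores are the signed margin) and a decision tree (depth ≤10, min-split 5)
post-pruned so any node whose majority class reaches 95% becomes a leaf —
scikit-learn has no such stopping rule natively, so the tree is pruned
after fitting, which yields the same predictions as stopping. Knobs not
fixed above stay at scikit-learn defaults and are dumped verbatim into
`algorithms.lock` with every run, so results are reproducible even if
ecosystem defaults move. No hyperparameter tuning anywhere, by design: the
comparisons are controlled-vs-uncontrolled with identical settings, so
conclusions are comparative, not absolute.

## Propensity-score matching and partitions

Propensity scores are fitted by maximum-likelihood logistic regression of
Day-28 membership on the four flags (constant columns dropped; on perfect
separation or non-convergence — detected via convergence flags and a
|coef| < 15 sanity bound — the fit falls back to a ridge-penalised logistic
regression with a log notice). Matching is greedy 1:1 nearest-neighbour on
the propensity logit, without replacement, treated (Day-28) samples visited
in descending propensity, ties broken by smallest sample id; an optional
caliper (`max_distance`) excludes distant pairs. Matching is performed once
on the full non-control inventory.

**Controlled-set size.** With four binary covariates the Day-7 pool nearly
always contains an admissible match for every Day-28 sample, so an uncapped
controlled set would absorb *all* Day-28 samples and leave the shared test
sets without a single mature sample. Workflow B therefore retains the 10
best-distance pairs by default (20 samples, day-balanced), the controlled-set
size of the reference design; the cap is configurable (`n_pairs`). The
Monte Carlo step instead subsamples the full uncapped pair pool per
iteration, which is what its undersampling scheme requires.

**Partitions.** Per constituent: uncontrolled Day-28 arm = all Day-28
samples with the constituent, Day-7 arm = all Day-7 samples without it
(on the default roster: M-PER 10/30, BMP-9 12/19, TGF-β1 7/27, HAV 16/17);
test set = every non-control sample in neither training set. Controls are
excluded from all of Workflow B.

## Statistics

- F1 = 2TP/(2TP+FP+FN), positive class = constituent present (Workflow A)
  or Day-28 (Workflow B; the observed F1 = 0 of collapsed uncontrolled
  models is only meaningful with the mature class as positive). F1 is 0 when
  TP = 0 with errors present, and an error when no positives exist at all.
- AUC is computed as the Mann–Whitney pair statistic (exact under ties,
  equal to trapezoidal ROC integration).
- Workflow B step 1 compares the nine per-algorithm scores of the two model
  groups with the two-sided Wilcoxon rank-sum test, as the reference design
  prescribes, even though the scores are paired by algorithm; a signed-rank
  variant is available behind a flag (`paired_test=True`) for sensitivity
  analysis. The rank-sum p-value is exact whenever there are no ties and
  the combined n ≤ 30 (covering the 9-vs-9 case, and matching R's
  `wilcox.test` behaviour at these sizes), and a tie-corrected normal
  approximation with continuity correction otherwise. Identical samples
  give p = 1 by convention.
- The Monte Carlo ΔF1 column is summarised by a paired t-test
  (t = mean/(sd/√n), n−1 df, two-sided) with the 95% CI mean ± t₀.₉₇₅·se.
  If every iteration yields the same ΔF1 (possible when a constituent is too
  weak to bias any split), the CI degenerates to the point value and p is
  reported as 1 (mean 0) — there is no sampling variability to test against.
- No multiple-testing correction is applied (none is part of the design).

## Numerical and degenerate-input choices

- Zero-variance channel removal uses exact equality across all spectra, is
  idempotent, and errors if every channel is constant.
- Day must be 7 or 28; duplicate sample ids, non-numeric intensities, and
  duplicate (sample, replicate, wavelength) keys are rejected with the
  offending key named. Wavelengths are written with one decimal; intensities
  at full float precision, so a written inventory re-reads exactly.
- Propensity scores are clipped to (1e-12, 1−1e-12) before the logit.
- Stratified folds come from seeded `StratifiedKFold(shuffle=True)`;
  metrics are computed on out-of-fold predictions pooled over the 10 folds
  into a single confusion matrix per model (matching how one confusion
  matrix per model is reported), not averaged per fold.

## Problem sizes used by the test suite

The suite exercises the full 81-sample design throughout. The Monte Carlo
behavioural checks use 25 iterations (the acceptance script uses 100), the
chance-level and null-confounder checks use 3 generator seeds with majority
or median decisions, and the end-to-end determinism audit runs the pipeline
twice with a reduced algorithm set and 10 Monte Carlo iterations. These
sizes give stable qualitative outcomes while keeping the suite fast.

## Known limitations

- The generator's phenomenological spectra cannot support numeric
  comparison with measured-construct results; only qualitative patterns
  (detectability ranking, confounding direction and ordering) transfer.
- On this synthetic dataset maturity is separable enough that weak
  confounders (HAV, BMP-9 at default amplitudes) often bias nothing at all,
  yielding degenerate ΔF1 = 0 columns; real constructs show small positive
  improvements instead.
- The rank-sum test applied to algorithm-paired scores ignores the pairing
  (fidelity to the reference design); the signed-rank flag exists for that
  reason.
- Greedy nearest-neighbour matching is order-dependent by construction;
  optimal/full matching and weighting estimators are out of scope.
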