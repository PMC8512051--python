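# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `imbfall`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

Binary classification of one-second windows of waist-worn tri-axial
accelerometer data: label 0 = activity of daily life (ADL), label 1 = fall.
The operating regime is class-imbalanced — the imbalance ratio
ρ = n_majority / n_minority is of order 10 — so a posterior-threshold
decision rule at the conventional 0.5 systematically under-detects falls.

## Synthetic-data generator

Real fall corpora cannot be bundled, so the generator emulates their
*structure*, not their biomechanics. All signals are in m/s² with gravity
9.81; trials record their unit so downstream stages are unit-agnostic.

* **ADL trials** are gravity along a randomly tilted sensor axis plus a
  kind-specific periodic oscillation (standing/sitting: noise-level;
  walking ≈ 2 Hz; jogging ≈ 2.8 Hz, larger amplitude) plus white sensor
  noise (σ = 0.3 m/s²). Oscillation amplitudes are scaled so the per-trial
  SMV maximum stays inside `adl_peak_range` (default 9.9–25 m/s², i.e. up
  to ≈ 2.5 g).
* **Fall trials** realize the canonical two-stage signature: pre-fall
  walking, a free-fall interval where the SMV decays toward ~0–1.5 m/s²,
  one sharp 50 ms half-sine impact whose crest — the trial's unique global
  SMV maximum — lies inside `impact_peak_range` (default 30–60 m/s²,
  ≈ 3–6 g), a short damped bounce, then lying-still rest at gravity.
* The two peak ranges are required to be disjoint, so **trial-level**
  SMVmax separates the classes by construction, mirroring the separation
  real corpora exhibit between fall impacts and even vigorous ADL.

The scalar SMV profile is projected onto a fixed per-trial direction and
noise is added per axis; only channels 1–3 carry signal. Per-trial seeds
derive from a master seed through a seed sequence, making whole corpora
byte-identical across runs.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: subject-specific gait, orientation change
during the fall, gyroscope channels, soft falls with weak impacts, fall-like
ADL (jumping onto a bed), sensor saturation and drift. Results on this
corpus demonstrate the *mechanism* of threshold moving, not field accuracy.

### Window-level ambiguity is intentional

Fall trials are reduced to the 3 s around the SMV peak and then cut into
1 s windows (0.5 s stride → 5 windows per fall). Only the central windows
contain the impact; the flanking ones hold pre-fall movement, the free-fall
onset, or post-impact rest — signals that legitimately resemble ADL yet
carry the fall label. This reproduces the situation that makes threshold
moving matter: minority posteriors spread over (0, 1) instead of
saturating, so the default 0.5 cutoff leaves recall on the table. It also
caps window-level fall recall well below 100 %.

## Preprocessing

* SMV_i = sqrt(Ax_i² + Ay_i² + Az_i²); SMVmax is its per-trial maximum with
  first-occurrence tie-breaking.
* Fall trials: 3 s segment centred on the SMVmax index, shifted (not
  shrunk) into the interior when the peak is near an edge, so all segments
  have full length and contain the parent's global maximum. ADL trials are
  windowed over their full length.
* Sliding windows: width 1 s, default stride 0.5 s (the stride is a free
  parameter; 50 % overlap is the common convention in inertial activity
  recognition), offsets 0, S, 2S, …, count = floor((L−W)/S) + 1, half-open
  0-based indexing, trailing remainder dropped.
* Split: 6:2:2 train/validation/test, shuffled with a fixed seed and
  **stratified by label** — plain random division can empty the minority
  class out of a split at high ρ. Per-split class proportions match the
  corpus within one window.

## Classifier

A compact 1D residual network ("ResNet10" layout): four residual blocks
with channel widths 16/32/64/128, each block = conv(1×3) → batch norm →
ReLU → conv(1×3) → batch norm, added elementwise to the shortcut and passed
through a final ReLU. The shortcut is the identity when shapes match and a
1×1 convolution + batch norm projection when the channel count or stride
changes (blocks 2–4 downsample by stride 2). Global average pooling feeds a
fully connected layer with softmax over the two classes.

Choices where the layout was genuinely open: channel widths (smallest
standard ladder consistent with four blocks and CPU training), global
average pooling before the head (shape independence, parameter economy),
conv → BN → ReLU ordering (the conventional one), "same" zero padding so
block outputs align with shortcuts, Adam (optimizer unstated in the
original description) at the stated learning rate 0.001, batch size 64,
best-validation-loss checkpoint selection, no early stopping.

The implementation is plain NumPy. Convolutions run as im2col + GEMM;
backward passes are exact analytic gradients (verified against central
finite differences in the test suite); batch norm keeps running statistics
(momentum 0.1, ε = 1e−5) for inference. He-normal initialization from a
seeded generator; training shuffles with a generator derived from the same
seed, so histories are bit-reproducible. At the default sizes one epoch on
~3,300 windows takes ~10 s on one CPU core.

Losses: cross-entropy (optionally per-class weighted), and focal loss
−α_t(1−p_t)^γ log p_t with defaults γ = 2, α = 0.75 on the minority class
(γ is the cited method's canonical value; α oriented to up-weight the
minority; both configurable).

## Threshold moving

* Empirical rule: λ̂ = argmin_λ |f − f_λ| over a candidate grid; f is the
  train minority frequency, f_λ the fraction of posteriors ≥ λ. The grid is
  the 0.01 lattice on (0,1) united with the observed posterior values —
  finite, exact, reproducible; ties break to the smallest λ. λ̂ is fitted on
  **validation** posteriors, never test.
* Closed form: λ* = k·exp(−ρ/(10k)) + k/10 with k the default threshold
  0.5. Strictly decreasing in ρ, increasing in k; λ* → k/10 as ρ → ∞;
  λ*(ρ=11.23, k=0.5) = 0.1029 ≈ 0.1. The decision rule is "fall iff
  P(fall|window) ≥ λ", boundary inclusive.
* Threshold moving is applied post hoc to the trained model's posteriors.
  Architecturally it can be drawn as a final network layer, but it is
  mathematically a decision rule, not a learned transform; implementing it
  post hoc is functionally identical and keeps it reusable across models.
* For the SMOTE + threshold combination, λ* uses the **original**
  (pre-SMOTE) train imbalance ratio: SMOTE balances the training set
  (post-SMOTE ρ = 1 would give λ* ≈ 0.46, i.e. no movement) but the
  deployment class distribution is unchanged, and the threshold corrects
  for deployment.

## Comparison strategies

`pipeline.compare_strategies` runs, on one shared corpus/split/seed:
baseline cross-entropy, inverse-frequency class weights
(w_c = n_total / (2 n_c), frequency-weighted mean 1), SMOTE (minority
oversampled to balance, train split only), SMOTE + threshold, focal loss,
closed-form threshold moving, and empirical threshold moving. SMOTE
synthesizes x + u(x_nn − x) with u ~ U(0,1) and x_nn among the k = 5
nearest minority neighbours (Euclidean distance on flattened windows;
neighbour search via scikit-learn).

## Evaluation

The confusion matrix uses the fall-detection convention with **positive =
ADL, negative = fall**: TP = ADL classified ADL, TN = fall detected, FP =
missed fall, FN = false alarm. Thus sensitivity = TP/(TP+FN) is ADL recall
and specificity = TN/(TN+FP) is fall recall. F-β = (1+β²)·Sens·Spec /
(β²·Sens + Spec) on percentages, β = 0.5 (specificity weighted more).
Note F-β here combines sensitivity and specificity, not precision and
recall: applied to the headline pair (Sens 99.33, Spec 91.86) it yields
97.74, not the 98.44 sometimes quoted alongside those rates — the formula
is implemented exactly as defined, and the discrepancy is flagged rather
than reconciled. AUC is the normalized Mann–Whitney rank statistic on the
fall posterior (ties count ½), identical in value to the trapezoidal area
under the ROC and invariant under any strictly monotone rescaling of the
scores — hence provably identical under any decision threshold. Rates with
zero denominators are reported as missing (NaN) with a warning, never 0
or 1.

## Problem sizes in the shipped experiments

The scaled headline experiment uses 265 ADL trials (10 s) and 91 fall
trials (12 s) at 200 Hz → 5,035 ADL + 455 fall windows (5,490 total,
ρ ≈ 11.1), trained 10 epochs (convergence on this corpus is reached within
a few epochs; 10 keeps the run minutes-scale on one core while satisfying
the ≤ 30-epoch protocol). Unit tests use 50 Hz corpora a tenth that size.

## Known limitations

* The generator's phenomenology is invented; parameter defaults (peak
  ranges, noise, phase durations) are plausible for waist-worn sensors but
  not fitted to any real corpus.
* The closed-form ρ→λ map is taken as given; the package evaluates it but
  does not re-fit it (that would require the original multi-ratio
  experiment campaign).
* Real-corpus window counts (94,786 / 8,439) are treated as reported
  accounting — they fix ρ = 11.23 — and are not reconstructible from the
  published preprocessing description alone (the stride is unstated), so
  the package exposes the stride as a parameter instead of claiming to
  reproduce those counts.
* Single-accelerometer only; gyroscope/second-accelerometer channels are
  accepted but zero-filled and unused.
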