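# Methods

## The task and the synthetic cohort

The package models single-visit disease screening from three wearable vitals.
A cohort of `n_records` (default 1000) individuals is generated with each
vital drawn independently and uniformly within configurable ranges — oxygen
saturation in [80, 100] %, respiratory rate in [20, 80] breaths/min, heart
rate in [60, 200] bpm. The binary label applies fixed screening thresholds
with strict comparisons (oxygen < 92, respiratory > 53, heartbeat < 100) and
combines them, by default, with logical OR: any abnormal vital flags disease.
AND and single-attribute rules are available. The heartbeat rule (< 100 bpm
flags disease) is clinically unusual for adults; it is implemented verbatim
as the defining rule of this artifact's labeling scheme, not corrected.

Under the default ranges the OR rule yields an analytic positive fraction of
1 − (1 − 12/20)(1 − 27/60)(1 − 40/140) ≈ 0.843, so the cohort is imbalanced
(~84% positive). The generator also offers a truncated-normal mode and a
target positive fraction via rejection sampling; both are off by default.

What the generator deliberately does not emulate: physiological time series,
intra-individual correlation between vitals, measurement noise, or label
noise. Labels are an exact function of the features, so the learning problem
is boundary recovery, not denoising; passing tests demonstrate that the
pipeline can recover sharp axis-aligned decision rules from finite samples,
not that it would handle noisy clinical data.

## IDOX

A population metaheuristic for box-bounded minimization. Each iteration, each
agent takes one of three moves — group attack (probability P·Q), persecution
(P·(1−Q)), scavenging (1−P) — with P = 0.5, Q = 0.7 by default; afterwards
agents whose survival value (worst − f)/(worst − best) falls below 0.3
receive a rescue move toward the incumbent best. New positions are clipped to
the box and accepted greedily (only if they improve that agent), which makes
the best-so-far trace non-increasing by construction.

The adaptive step ("improved" mode) draws the two step factors from
α·c·X with α = best − worst fitness, X = (mean − worst)/(mean − best), and
c ~ U(0, 1), clipped into the classic ranges β₁ ∈ [−2, 2], β₂ ∈ [−1, 1];
degenerate populations (zero fitness spread, or mean equal to best) fall back
to the classic uniform draw, which is also available wholesale via
`beta_mode="classic"`. Two published constant pairs for β₁/β₂ are recorded in
the config for completeness but are not used in computation; their role in
the source material is not interpretable.

Design choices made where the published description is ambiguous or garbled:
the group-attack move follows the established baseline dingo-optimizer form
(β₁ times the mean attacker offset minus the reference agent); the
exponential factor e^{β₂} is used where the typography is unreadable; the
survival formula is oriented so the best agent gets survival 1 under
minimization; the rescue move applies to all below-threshold agents, not only
the single worst; ties for best break toward the earlier-indexed agent.
Decodings: integers by round-and-clip, bit masks by sigmoid(x) > 0.5 with an
all-zero repair that forces on the dimension with the largest sigmoid value.

## WBAN simulation

Tier 1 tags each record "00" (critical: any threshold breached — by
construction identical to the OR label) or "01", encrypts the serialized
vitals, and fills TDMA frames of `w` slots with a stable priority sort, so
critical packets occupy the earliest slots and FIFO order is preserved within
a class. Encryption is AES-128 in CTR mode with an HMAC-SHA256 tag
(encrypt-then-MAC), implemented in pure Python against the FIPS-197 test
vector; authentication makes tampering and wrong-key decryption detectable
errors rather than silent corruption.

Tier 2 scores each candidate channel by cost = w₁·DS_g + w₂·(failure
fraction), where DS_g is the mean square of 2a Gaussian noise samples
(concentrating at the noise variance for large time-bandwidth product a) and
failures are Bernoulli draws with the channel's success probability. The
weighted-sum form and the Bernoulli link model are this package's
construction — the source architecture names a multi-objective channel choice
without writing it down. Weights default to 0.5/0.5. IDOX searches the
integer channel index with per-channel memoized costs. Transmission is
lossless for the classification path by default; a drop-on-failure flag
exists but then delivered cohorts shrink, which changes the evaluation set.

## Deep feature extraction

Each record's three standardized vitals (z-scored with training-fold
statistics) form a length-3, one-channel sequence. Two extractors:

* **Convolutional autoencoder** (unsupervised): Conv1D(1→8 filters, kernel 2)
  → ReLU → flatten → dense bottleneck (8 units); decoder mirrors back to the
  input width; Adam on mean squared reconstruction error, 300 epochs.
* **1-D CNN** (supervised): Conv1D(1→24, kernel 2) → ReLU → flatten → dense 8
  → ReLU (the feature layer) → 1-logit head; class-weighted binary
  cross-entropy, 2500 epochs, with L2 weight decay 5·10⁻⁴ and a step
  learning-rate decay (lr/5 at 75% of the schedule).

The concatenated 16-column matrix is the input to feature selection. The
treatment of tabular vitals as a "signal" is a modeling decision (the source
never specifies one), as is training the CNN on the label while the
autoencoder remains reconstruction-only. Extractors are fitted per
cross-validation fold on the training fold only.

Two training details matter for the headline numbers and deserve
justification. Class-balanced loss weights counter the ~84/16 class
imbalance, which otherwise biases the learned boundary into the negative
region and inflates false positives. Weight decay with late learning-rate
decay keeps gradient pressure on the boundary after the cross-entropy
saturates, which centres the decision surface between the nearest
opposite-class training points — the dominant error source on
threshold-labeled data is boundary misplacement within the inter-sample gap.

## Feature selection

Wrapper selection by IDOX over bit masks: fitness = (1 − mean stratified
3-fold CV accuracy of an L2-regularized logistic regression restricted to the
selected columns) + λ·(selected/total), λ = 0.01. The internal 3-fold CV is
deliberately decoupled from the outer 5-fold evaluation. Logistic regression
is the default wrapper evaluator for speed; the fitness functional form is
this package's choice (the source names the selector but not its objective).
Masks are never empty (decoder repair), and the selected mask is persisted
per fold.

The population search is followed by a memetic polish: steepest-descent over
single bit flips (and pairwise flips while d ≤ 16) from the best mask until
no move improves the cost, with all evaluations memoized. Wrapper selectors
routinely combine a global metaheuristic with local refinement; on
exhaustively checkable instances (d = 8) the polish closes the gap between
the population search and the brute-force optimum.

## The classifier and its tuning

The selected feature vector of length d is fed to a bidirectional LSTM as d
scalar timesteps. Forward and backward final hidden states (H units each) are
merged — concatenation by default; averaging, summation, multiplication also
implemented — and a dense head yields the disease logit (threshold 0.5).
Training: Adam, class-balanced BCE, weight decay 5·10⁻⁴, lr 0.03 with step
decay, batch 128.

H is tuned in [2, 255] by IDOX (population 5, 5 iterations by default),
minimizing 1 − validation accuracy on an inner 80/20 stratified split of the
training fold. Each distinct H trains once (memoization); tuning evaluations
use a reduced schedule (10 epochs, up to 512 training records) and the final
model retrains at the best H on the full training fold without early
stopping, so the late learning-rate decay always engages. The final epoch
count is compute-matched above H = 64 (scaled by 64/H, floor 25): on these
short sequences large states converge in proportionally fewer passes. The
tuning objective adds a parsimony term 5·10⁻⁴·(H−2)/253 — smaller than one
validation sample's worth of accuracy — so accuracy-equivalent H values
resolve toward the smaller model. "Modified" BiLSTM here means exactly this
optimizer-driven hyperparameter tuning; no architectural modification is
implied.

Per fold, the prediction is a committee of 3 classifiers sharing the fold's
features, mask and tuned H, differing only in initialization seed; their
positive-class probabilities are averaged before thresholding. This is plain
initialization-variance reduction — the architecture and feature set are
unchanged — and it stabilizes the handful of boundary-adjacent predictions
that single trainings flip from seed to seed. Set `evaluation.committee: 1`
to disable.

## Evaluation

5-fold cross-validation with seeded shuffling: every stage (extractors,
selector, tuner, classifier) is fitted per fold on the training fold only;
the pooled report is computed from summed confusion counts, with the
convention TP = hb, TN = hc, FP = hd, FN = he throughout. Ten metrics are
reported on the 0–100 scale (MCC scaled by 100). Zero-denominator metrics are
reported as null and flagged, never as 0. Two corrections to the printed
metric formulas in the source material are applied: the F1 expression drops a
duplicated factor of 2 (the standard 2TP/(2TP+FP+FN), consistent with the
published precision/sensitivity/F1 triple), and MCC uses the standard
square-root denominator. A single-holdout "learning percentage" split
(|train| = round(p/100·n)) is provided for sweep-style experiments.

Seeding is counter-based: the global seed expands through `SeedSequence` into
per-stage and per-fold seeds, so any stage can be re-run independently and
the whole pipeline is bit-reproducible (inputs are forced C-contiguous before
training because BLAS summation order, and hence floating-point results,
otherwise depends on the caller's array layout).

## Problem sizes and numerical choices

The shipped defaults are the study conditions: 1000 records, 5 folds,
optimizer populations of 5 with 5 iterations for selection and tuning (the
channel-selection benchmark in the optimizer module also exercises the
published population-100/25-iteration setting). A full pipeline run takes a
few minutes on one CPU; the committee triples the classifier-training share
of that. Networks run in float32 (LSTM) and float64 (feature extractors);
gradients are exact and verified against finite differences in the tests.
Degenerate inputs are handled explicitly: all-equal-fitness populations fall
back to classic draws, empty masks are repaired, single-class training folds
raise, and non-finite losses abort with a divergence error.

## Known limitations

* Labels are noise-free functions of three uniform features; accuracy
  ceilings here say nothing about noisy, correlated, drifting clinical data.
* The channel model is a Bernoulli abstraction with no MAC contention,
  propagation physics, or retransmission penalty.
* The wrapper selector's logistic proxy can keep autoencoder columns that the
  BiLSTM does not need (and vice versa); with d = 16 this costs little.
* Pure-Python AES is for simulation fidelity, not production cryptography.
* Tuning reuses one inner split per fold; H estimates inherit that split's
  variance, mitigated but not removed by memoized evaluation and the
  parsimony tie-break.
* Trained networks are not checkpointed to disk; reproducibility is carried
  by the run manifest (config hash plus derived stage seeds), from which any
  fold's models can be refitted bit-exactly.
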