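# Methods

`swpkit` classifies wound-induced plant slow wave potentials (SWPs) — the
surface-potential deflection a plant produces after mechanical wounding, with
a steep depolarization and a slow partial repolarization — according to how
much darkness the plant experienced before wounding (Normal night, short
extended darkness SED, long extended darkness LED). Signals from the wounded
leaf (leaf 8) and a vascularly connected systemic leaf (leaf 13) are treated
as two separate three-class problems throughout; the package never pools
them. Because only a handful of plants can be measured per condition
(20/20/15), the workflow is built around few-shot augmentation: a generative
model per (leaf, condition) group manufactures virtual traces that enlarge
the training sets.

## Preprocessing

A raw recording is a 100 Hz mV series with a marked wounding sample. Four
stages turn it into the fixed-length vector all later stages consume:

1. **Extraction.** The useful window starts at the wounding sample and ends
   at the first sample, after the depolarization minimum, at or above
   `baseline − (baseline − minimum)/2`, where the baseline is the potential
   *at the wounding sample* — the only sample-local choice, since no
   pre-wound averaging convention is defined. Plateaus are resolved to the
   earliest qualifying sample (`≥`, not `>`). Recordings that end before half
   recovery return the full tail with a `truncated` flag; recordings that
   never drop below baseline are flagged degenerate and rejected by the
   pipeline rather than silently processed.
2. **Local mean compression.** Non-overlapping 100-sample block means, so one
   value per second at 100 Hz. A final partial block is averaged over its
   remaining samples rather than dropped: extraction stops at an arbitrary
   index, and discarding up to 0.99 s of repolarization tail would bias the
   stop-region features.
3. **Padding.** Traces are extended to a fixed 411 values by repeating the
   last value, and the real length is recorded. When a dataset's longest
   compressed trace exceeds the target, the tool refuses and tells the caller
   to raise `target_length`; it never truncates.
4. **Normalization and alignment.** The linear map
   `y = 2(x − min)/(max − min) − 1` puts the real region exactly onto
   [−1, 1]; the padded tail is then set to exactly 0 so fill values carry no
   weight in the features. The alternative reading of "aligning the filled
   amplitude to zero" — shifting the whole trace so the fill value sits at
   0 — is available behind `zero_fill=False`; it preserves the trace's shape
   but lets the real region leave [−1, 1] by the shift amount, so the
   tail-zeroing reading is the default. The resulting discontinuity at
   `real_length` is accepted; it is itself informative (it encodes duration).

Whether min/max are computed before or after padding is immaterial: the fill
duplicates the last real value, so both regions share the same extrema.

## Features

Three alternative classifier inputs, all computed on the full 411-sample
vector (zeroed tail included — augmented traces are full vectors, so original
and virtual samples must be featurized identically; helpers accept a
`real_length` subset if a user wants it):

* **12 time-domain scalars** — maximum, minimum, mean, variance, standard
  deviation, skewness, kurtosis, RMS, area, declining slope, rising slope,
  amplitude. Moments are population (1/n) with no small-sample correction;
  kurtosis is non-excess (`m4/m2²`, so a Gaussian scores 3). The area is the
  sum of *absolute* per-step trapezoids. The declining slope runs from the
  first index attaining the global maximum to the first attaining the global
  minimum and carries an explicit minus sign (max-before-min traces score
  negative); the rising slope runs from the minimum to the first index
  attaining the post-minimum maximum. A mean-square column is not included:
  it is the square of RMS and adds no information.
* **first derivative** — average of forward and backward difference
  quotients at interior points (equal to `(y[i+1] − y[i−1])/2` on the unit
  grid), one-sided at the ends; length preserved.
* **cumulative integral** — signed running trapezoid sum starting at 0.

A useful exact identity, asserted in the tests: composing the two vector
operators gives `y + Δ²y/4` at interior points, so derivative-of-integral is
the identity precisely where the trace is locally linear.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
any measured distribution (none is published): baseline at rest, a smooth
half-cosine depolarization of depth `A` over `depol_duration_s` (smooth, not
a step, so the first derivative is informative), then exponential
repolarization `v(t) = baseline − A·2^(−t/t_half)` — parameterized directly
by the half-recovery time so the extraction stop index is analytically
solvable in tests — plus white measurement noise (SD 0.3 mV) and a
random-walk baseline drift (0.01 mV/√s). Depolarization is negative-going,
matching the surface-potential convention. Recordings extend 1.5 half-times
past the minimum, guaranteeing the half-recovery crossing exists.

Default condition profiles (leaf 8: A = 20/28/40 mV, t_half = 60/90/140 s
for Normal/SED/LED; leaf 13 shallower and slower-growing: A = 10/14/20 mV,
t_half = 50/75/120 s) encode a decodable darkness effect — longer darkness
gives deeper, longer-lasting responses — with ≥ 25 % separation between
neighbouring conditions. The magnitudes are illustrative: the design
requirement is only that condition is decodable from trace kinetics, since
amplitude information is deliberately destroyed by per-trace normalization.
What survives preprocessing as class signal is *duration* (the real length
before the zero tail) and depolarization/repolarization shape. Consequently,
passing tests show the pipeline recovers kinetic differences between
classes; they say nothing about how large such differences are in real
recordings, about artifacts (electrode drift steps, spontaneous action
potentials), or about plant-to-plant amplitude variability beyond what
normalization removes. Sample sizes (20/20/15 per condition, both leaves,
110 recordings) mirror the measured-study design.

## Augmentation

One generative model per (leaf, condition) group — the only arrangement
under which class-labeled virtual samples exist. All three methods share
the published training constants: 200 epochs, reconstruction learning rate
1e−4, adversarial/generation learning rate 5e−4, dropout 0.2 on hidden
layers (training only), plain SGD, seed 10 by default.

**AAE (primary).** Encoder 411→200→100→100→50, decoder mirrored,
discriminator 50→100→100→50→25→1 with a terminal sigmoid. The
discriminator's interior widths are this package's assumption — only its
input/output widths and five-map depth are fixed — and are configurable.
Per epoch and mini-batch: (1) encoder+decoder descend the sum-over-dims L1
reconstruction loss; (2) the discriminator learns to separate prior draws
`z ~ N(0, I₅₀)` from encoder codes; (3) the encoder is updated to make its
codes score real. The generator-side update uses the non-saturating
objective (maximize `log D`), a standard stabilization with the same
optimum as the minimax form. Virtual traces decode prior draws and are
clipped to [−1, 1]; the zero tail is learned, not re-imposed (a
`rezero_tail` flag can force it beyond the group's longest real length).

Three numerical choices matter at this scale and are deliberate:

* **Per-sample updates (batch size 1).** The stated constants allow only
  200 full-batch steps, far too few for the decoder to converge at lr 1e−4;
  one update per sample per epoch (the literal reading of *stochastic*
  gradient descent, 4 000 updates for a 20-trace group) trains to good
  reconstruction within the fixed epoch budget. Batch size is configurable.
* **Code-layer calibration at initialization.** After weight init, the
  encoder's output layer is rescaled so the training codes start at the
  prior's scale (a data-dependent init in the LSUV spirit, one global scale
  plus centering). Without it codes start an order of magnitude smaller
  than the prior and the fixed-rate adversarial updates cannot close the
  gap, so prior draws decode far outside the trained region.
* **Small-gain decoder init.** Decoder weights start at 0.3× the He scale,
  so the decoder grows its response to the latent during training instead
  of wildly amplifying prior draws that fall outside the code cloud. This
  is what makes decoded prior samples template-like on a 15–20-sample
  group; with plain He init their cosine similarity to the class template
  drops by ~0.6 instead of ≤ 0.15.

**VAE baseline.** Same widths; the encoder trunk stops one layer short and
two linear heads emit the posterior mean and log-variance (clipped to ±10);
objective is L1 reconstruction plus the analytic diagonal-Gaussian KL, all
at the reconstruction rate.

**GAN baseline.** Fully connected generator 50→100→200→411 and
discriminator 411→200→100→50→1 (only the 411-width input/output is
published; interior widths are package choices), standard adversarial
training with the non-saturating generator update.

Training is bit-reproducible: a single seeded generator drives
initialization, batch order, dropout masks and prior draws. Five-fold
monitoring splits are available but off by default — groups of 15–20 leave
folds of 3–4 samples, useful for monitoring only, and no early stopping is
wired to them.

**Fidelity evaluation.** Each group's template is the element-wise mean of
its original traces. Euclidean distance, Pearson correlation (ordinary
means) and cosine similarity are computed per sample against the template
and averaged. Augmented material is considered reliable when its mean CS and
PCC sit within 0.15 of the original samples' values. Degenerate
(zero-variance) samples are skipped for PCC with a warning rather than
propagating NaN.

## Classification

SVM (RBF, C = 1, gamma = 1/n_features), KNN (k = 5, Euclidean, majority
vote, ties broken by the single nearest neighbour, k clamped to the fold
size with a warning), Random Forest (100 trees — the tree count is not
published, so the ubiquitous default is used — `random_state = 0`), and an
MLP (one hidden layer of 10 rectifier units, softmax output, full-batch
gradient descent at lr 0.01 for a fixed 500 epochs — no optimizer or epoch
count is published, so plain seeded gradient descent without early stopping
is the transparent choice). No feature standardization by default (traces
are already in [−1, 1]); z-scoring is available behind a flag for the
scalar features.

Evaluation is leave-one-out by default (five-fold optional). Augmented
samples join every *training* fold and never a test fold — they carry
`aug_`-prefixed ids and `provenance="augmented"` so the splitter can prove
it. The alternative reading (pooling virtual samples into cross-validation)
is available behind `train_only_augmentation=False` / `--augment-in-pool`,
but inflates scores by testing on generated material and is off by default.
Fold predictions pool into one confusion matrix (rows true, columns
predicted), from which accuracy and macro one-vs-rest precision/recall/F1
are computed; a never-predicted class contributes precision 0 (flagged),
a truth-absent class recall 0.

## Problem sizes and degenerate inputs

The test suite and the acceptance script run the full published scale: 110
synthetic recordings, six 200-epoch AAE trainings, 50 virtual traces per
group, and complete leave-one-out protocols (55 folds per leaf); the
label-shuffle control repeats LOOCV over 10 seeds on leaf 8. End-to-end
discrimination properties are asserted on leaf 8; leaf 13 is an independent
copy of the same construction and is exercised by the preprocessing,
augmentation-fidelity and acceptance-script paths.

Degenerate inputs fail loudly and early: flat recordings are rejected at
extraction, constant traces raise on normalization and on moment features,
zero-variance samples are skipped in PCC, unknown config keys abort before
any computation, and traces longer than the fixed length refuse rather than
truncate.

## Known limitations

* The synthetic generator is the only data source; its defaults are
  illustrative, and results on it bound nothing about measured recordings.
* The AAE's latent space is not interpretable, and with 15–20 training
  traces per group the generative models necessarily interpolate a narrow
  manifold; virtual traces increase density near the class template rather
  than adding genuinely new modes.
* Augmentation quality is judged only by template similarity; distributional
  metrics (e.g. two-sample tests in feature space) are not implemented.
* Wound-time detection is out of scope: `wound_index` is an input.
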