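# swpkit

Few-shot classification of wound-induced plant slow wave potentials (SWPs).

When a plant leaf is wounded it fires an electrical signal — a steep
depolarization of the surface potential followed by a slow partial
repolarization — that travels to distant leaves and shapes the defense
response. The shape of that signal carries information about the plant's
recent environment: plants deprived of light to different extents (normal
night, short or long extended darkness) produce kinetically different SWPs
in both the wounded leaf (leaf 8) and a connected systemic leaf (leaf 13).
`swpkit` is for plant electrophysiologists and ML practitioners who want to
decode such conditions from single traces when only a handful of recordings
per condition exist.

The package implements the full small-sample workflow:

* **Preprocessing** — extract the wound-to-half-recovery window, compress it
  with 100-sample block means (1 value/s at 100 Hz), pad to a fixed 411
  values, and normalize each trace by
  `y = 2(x − x_min)/(x_max − x_min) − 1` onto [−1, 1] with the padded tail
  zeroed.
* **Features** — 12 time-domain scalars (max, min, mean, σ², S, skewness,
  kurtosis, x_rms, area, declining/rising slope, amplitude; population
  moments), the first derivative `f'(xᵢ) = ½[(yᵢ₊₁−yᵢ)/Δ + (yᵢ−yᵢ₋₁)/Δ]`,
  or the cumulative trapezoid integral.
* **Augmentation** — an adversarial autoencoder (encoder
  411→200→100→100→50, mirrored decoder, discriminator on the 50-dim latent)
  trained per (leaf, condition) group with a sum-of-|·| (L1) reconstruction
  loss and the minimax game
  `min_G max_D E[log D(p(z)) + log(1 − D(G(q(z))))]` against a standard
  Gaussian prior; decoding prior draws yields virtual traces. GAN and VAE
  baselines share the interface. All networks are NumPy with manual
  backpropagation and plain SGD — bit-reproducible under a fixed seed.
* **Evaluation** — per-class template (element-wise mean trace) similarity
  via Euclidean distance, Pearson correlation and cosine similarity; and
  confusion-matrix metrics (accuracy, macro precision/recall/F1).
* **Classification** — SVM (RBF, C=1), KNN (k=5), Random Forest
  (100 trees, seed 0) and a 10-unit MLP under leave-one-out
  cross-validation, with augmented samples confined to training folds.
* **Synthetic generator** — SWP-like recordings (sigmoidal depolarization,
  exponential repolarization, noise and drift at 100 Hz) with
  condition-dependent kinetics, standing in for unavailable measured data.

## Worked example

```python
from swpkit import (SyntheticConfig, AAEConfig, ClassifierSpec, SplitProtocol,
                    augment_dataset, build_feature_matrix, preprocess_pipeline,
                    run_classification, class_template, similarity_metrics)
from swpkit.synthetic import synthesize_leaf

# 55 wounded-leaf recordings: 20 Normal, 20 SED, 15 LED, sampled at 100 Hz
recordings = synthesize_leaf(SyntheticConfig(seed=10), leaf=8)
traces = [preprocess_pipeline(rec, provenance="synthetic") for rec in recordings]
print(f"{len(traces)} traces, each {len(traces[0].values)} samples after preprocessing")

X, y = build_feature_matrix(traces, "deriv_1st")
report = run_classification(X, y, ClassifierSpec("random_forest"), SplitProtocol("loocv"))
print(f"LOOCV accuracy without augmentation: {report.accuracy:.2f}")

augmented, models = augment_dataset(traces, method="aae", n_per_group=50,
                                    cfg=AAEConfig(seed=10))
normal = [t for t in traces if t.condition == "Normal"]
template = class_template(normal)
_, pcc, cs = similarity_metrics([t for t in augmented if t.condition == "Normal"], template)
print(f"augmented Normal vs template: PCC={pcc:.2f}, CS={cs:.2f}")

X_aug, y_aug = build_feature_matrix(augmented, "deriv_1st")
boosted = run_classification(X, y, ClassifierSpec("random_forest"),
                             SplitProtocol("loocv"), X_aug=X_aug, y_aug=y_aug)
print(f"LOOCV accuracy with augmentation: {boosted.accuracy:.2f} "
      f"(macro F1 {boosted.macro_f1:.2f})")
```

Output:

```
55 traces, each 411 samples after preprocessing
LOOCV accuracy without augmentation: 1.00
augmented Normal vs template: PCC=0.95, CS=0.95
LOOCV accuracy with augmentation: 1.00 (macro F1 1.00)
```

The three synthetic classes differ by ≥ 25 % in depolarization depth and
repolarization half-time, so the derivative features separate them
perfectly under leave-one-out cross-validation — with and without the 150
virtual traces. The PCC/CS values say the virtual Normal traces correlate
with the Normal class template almost as strongly as the measured-style
originals do (0.95 vs 1.00), the criterion under which augmented material
is considered reliable.

The same stages are available from the shell:

```bash
swpkit simulate --out data --seed 10
swpkit preprocess --manifest data/manifest_leaf8.csv --out pp8.csv
swpkit features --in pp8.csv --kind deriv_1st --out feat8.csv
swpkit augment --in pp8.csv --method aae --n-per-group 50 --out aug8.csv
swpkit eval-augmentation --original pp8.csv --augmented aug8.csv --out sim8.csv
swpkit classify --features feat8.csv --classifier random_forest --out report.json
swpkit run --out run_dir        # everything above in one command
```

See `docs/methods.md` for the model details, parameter defaults and the
numerical choices behind the augmenter training.

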