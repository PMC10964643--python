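"""Augmentation-fidelity and classification metrics.

Augmentation quality is judged against per-class *templates*: the
element-wise mean trace of each (leaf, condition) group's original samples.
Three indicators compare a set of samples to a template, each computed per
sample and then averaged over the set:

* **ED** — Euclidean distance,
* **PCC** — Pearson correlation coefficient (ordinary means),
* **CS** — cosine similarity.

If the augmented samples score close to the original samples on these
indicators, the generated material is considered reliable.

Classification quality comes from the confusion matrix (rows = true label,
columns = predicted): overall accuracy plus macro-averaged one-vs-rest
precision, recall and F1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from swpkit.errors import DataError


def class_template(traces) -> np.ndarray:
    """Element-wise mean over a group's traces: the class template vector."""
    rows = [np.asarray(t.values if hasattr(t, "values") else t, dtype=float)
            for t in traces]
    if not rows:
        raise DataError("cannot build a template from an empty group")
    return np.mean(np.vstack(rows), axis=0)


def similarity_metrics(samples, template) -> tuple[float, float, float]:
    """Mean per-sample (ED, PCC, CS) of a sample set against a template.

    Samples with zero variance are skipped for PCC (with a warning) and the
    average taken over the remainder; if every sample is degenerate a
    :class:`~swpkit.errors.DataError` is raised.
    """
    template = np.asarray(template, dtype=float)
    rows = [np.asarray(s.values if hasattr(s, "values") else s, dtype=float)
            for s in samples]
    if not rows:
        raise DataError("similarity_metrics needs at least one sample")
    for r in rows:
        if r.shape != template.shape:
            raise DataError("sample length does not match template length")
    t_dev = template - template.mean()
    t_ss = float(np.sqrt(np.sum(t_dev**2)))
    t_norm = float(np.linalg.norm(template))
    if t_ss == 0.0:
        raise DataError("constant template: PCC undefined")
    if t_norm == 0.0:
        raise DataError("zero template: cosine similarity undefined")

    eds, pccs, css = [], [], []
    skipped = 0
    for x in rows:
        eds.append(float(np.linalg.norm(x - template)))
        x_norm = float(np.linalg.norm(x))
        css.append(float(np.dot(x, template) / (x_norm * t_norm)) if x_norm else 0.0)
        x_dev = x - x.mean()
        x_ss = float(np.sqrt(np.sum(x_dev**2)))
        if x_ss == 0.0:
            skipped += 1
            continue
        pccs.append(float(np.dot(x_dev, t_dev) / (x_ss * t_ss)))
    if skipped:
        warnings.warn(f"{skipped} zero-variance sample(s) skipped for PCC", stacklevel=2)
    if not pccs:
        raise DataError("all samples degenerate: PCC undefined")
    return float(np.mean(eds)), float(np.mean(pccs)), float(np.mean(css))


def similarity_report(original_by_group: dict, augmented_by_group: dict) -> dict:
    """Per-group ED/PCC/CS for augmented-vs-template and original-vs-template.

    Templates are built from the *original* traces of each group. Returns a
    mapping ``{group: {"augmented": {...}, "original": {...}}}`` with keys
    ``ed``, ``pcc``, ``cs``.
    """
    report = {}
    for key, originals in original_by_group.items():
        template = class_template(originals)
        entry = {}
        for name, samples in (("original", originals),
                              ("augmented", augmented_by_group.get(key, []))):
            if not samples:
                continue
            ed, pcc, cs = similarity_metrics(samples, template)
            entry[name] = {"ed": ed, "pcc": pcc, "cs": cs}
        report[key] = entry
    return report


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion matrix plus accuracy and macro precision/recall/F1."""

    classes: tuple[str, ...]
    confusion: np.ndarray  # rows = true, columns = predicted
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": {k: dict(v) for k, v in self.per_class.items()},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "ClassificationReport":
        return cls(
            classes=tuple(data["classes"]),
            confusion=np.asarray(data["confusion"], dtype=int),
            accuracy=data["accuracy"],
            macro_precision=data["macro_precision"],
            macro_recall=data["macro_recall"],
            macro_f1=data["macro_f1"],
            per_class={k: dict(v) for k, v in data.get("per_class", {}).items()},
        )


def confusion_and_metrics(y_true, y_pred, classes) -> ClassificationReport:
    """Build the confusion matrix and macro-averaged metrics.

    A class never predicted (TP + FP = 0) contributes precision 0; a class
    absent from the truth (TP + FN = 0) contributes recall 0; F1 is 0 when
    precision + recall is 0. Both situations are flagged in ``per_class``.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if not y_true or len(y_true) != len(y_pred):
        raise DataError("label sequences must be nonempty and of equal length")
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    unknown = (set(y_true) | set(y_pred)) - set(classes)
    if unknown:
        raise DataError(f"labels outside the class order: {sorted(unknown)}")
    k = len(classes)
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    n = cm.sum()
    accuracy = float(np.trace(cm) / n)
    per_class = {}
    precisions, recalls, f1s = [], [], []
    for i, c in enumerate(classes):
        tp = int(cm[i, i])
        fp = int(cm[:, i].sum() - tp)
        fn = int(cm[i, :].sum() - tp)
        tn = int(n - tp - fp - fn)
        undefined_p = (tp + fp) == 0
        undefined_r = (tp + fn) == 0
        precision = 0.0 if undefined_p else tp / (tp + fp)
        recall = 0.0 if undefined_r else tp / (tp + fn)
        f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
        per_class[c] = {
            "tp": tp, "tn": tn, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall, "f1": f1,
            "precision_undefined": undefined_p, "recall_undefined": undefined_r,
        }
        precisions.append(precision)
        recalls.append(recall)
        f1s.append(f1)
    return ClassificationReport(
        classes=classes,
        confusion=cm,
        accuracy=accuracy,
        macro_precision=float(np.mean(precisions)),
        macro_recall=float(np.mean(recalls)),
        macro_f1=float(np.mean(f1s)),
        per_class=per_class,
    )
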