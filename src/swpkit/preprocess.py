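"""Preprocessing of raw SWP recordings into fixed-length normalized vectors.

Four stages, applied in order:

1. **Signal extraction** — keep the window from the wounding time to the first
   sample (after the depolarization minimum) at which the trace has recovered
   half of the maximum depolarization, measured against the potential at the
   wounding time.
2. **Local mean compression** — non-overlapping block means with a fixed
   window (100 samples at 100 Hz, so one value per second).
3. **Padding** — extend to a fixed length (default 411) by repeating the last
   real value, recording the real length.
4. **Normalization and alignment** — map the trace linearly onto [-1, 1] by
   ``y = 2 (x - min) / (max - min) - 1`` and set the padded tail to exactly 0
   so fill values do not influence downstream features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from swpkit.errors import DataError, DegenerateSignalError, LengthError
from swpkit.io import RawRecording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtractedSignal:
    """The useful window of a recording: wound time to half-recovery stop."""

    values: np.ndarray
    sampling_rate_hz: float
    truncated: bool = False  # recording ended before half recovery
    degenerate: bool = False  # no depolarization below baseline

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class CompressedTrace:
    """Block-mean compressed signal; one value per window (per second at defaults)."""

    values: np.ndarray
    window: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class NormalizedTrace:
    """Fixed-length dimensionless trace in [-1, 1] with a zeroed tail.

    ``real_length`` is the number of leading entries that carry signal; the
    remaining ``target_length - real_length`` entries are exactly 0.
    """

    values: np.ndarray
    real_length: int
    sample_id: str = ""
    leaf: int = 8
    condition: str = "Normal"
    provenance: str = "measured"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return int(self.values.size)


def extract_signal(rec: RawRecording) -> ExtractedSignal:
    """Extract the wound-to-half-recovery window of a recording.

    The baseline is the potential at the wounding sample. The depolarization
    extremum is the minimum after the wound; the stop is the first subsequent
    sample at or above ``baseline - (baseline - minimum)/2``. If the recording
    ends before that level is reached (or the minimum is the final sample),
    the full tail is returned with ``truncated=True``. A recording that never
    drops below baseline is returned with ``degenerate=True`` and rejected by
    the pipeline.
    """
    values = rec.values
    start = int(rec.wound_index)
    baseline = values[start]
    seg = values[start:]
    min_off = int(np.argmin(seg))
    minimum = seg[min_off]
    if minimum >= baseline:
        return ExtractedSignal(seg[: min_off + 1] if min_off else seg[:2],
                               rec.sampling_rate_hz, degenerate=True)
    half_level = baseline - (baseline - minimum) / 2.0
    if min_off == seg.size - 1:
        return ExtractedSignal(seg, rec.sampling_rate_hz, truncated=True)
    after = seg[min_off + 1:]
    crossed = np.nonzero(after >= half_level)[0]
    if crossed.size == 0:
        return ExtractedSignal(seg, rec.sampling_rate_hz, truncated=True)
    stop_off = min_off + 1 + int(crossed[0])
    return ExtractedSignal(seg[: stop_off + 1], rec.sampling_rate_hz)


def local_mean_compress(sig: ExtractedSignal | np.ndarray, window: int = 100) -> CompressedTrace:
    """Replace consecutive non-overlapping blocks of ``window`` samples by their mean.

    A final partial block is averaged over its remaining samples rather than
    dropped, so up to ``window - 1`` trailing samples still contribute.
    Output length is ``ceil(n / window)``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    values = sig.values if isinstance(sig, ExtractedSignal) else np.asarray(sig, dtype=float)
    n = values.size
    if n == 0:
        raise DataError("cannot compress an empty signal")
    n_full = n // window
    out = np.empty(-(-n // window), dtype=float)
    if n_full:
        out[:n_full] = values[: n_full * window].reshape(n_full, window).mean(axis=1)
    if n_full * window < n:
        out[n_full] = values[n_full * window:].mean()
    return CompressedTrace(values=out, window=window)


def pad_trace(ct: CompressedTrace | np.ndarray, target_length: int = 411) -> tuple[np.ndarray, int]:
    """Extend a compressed trace to ``target_length`` by repeating its last value.

    Returns ``(padded, real_length)``. Refuses traces longer than the target:
    the fixed length must be set to the longest trace in the dataset, never
    achieved by truncation.
    """
    values = ct.values if isinstance(ct, CompressedTrace) else np.asarray(ct, dtype=float)
    n = values.size
    if n > target_length:
        raise LengthError(
            f"trace length {n} exceeds target_length {target_length}; "
            "raise target_length to at least the longest compressed trace"
        )
    padded = np.full(target_length, values[-1], dtype=float)
    padded[:n] = values
    return padded, n


def normalize_and_align(
    padded: np.ndarray, real_length: int, zero_fill: bool = True
) -> np.ndarray:
    """Map the real region onto [-1, 1] and align the fill region to 0.

    The linear map is ``y = 2 (x - min) / (max - min) - 1`` with min/max taken
    over the real region (the fill duplicates the last real value, so taking
    them over the whole vector is equivalent). With ``zero_fill`` (default)
    the fill region is then set to exactly 0; otherwise the whole trace is
    shifted so the fill value sits at 0 (the alternative reading of aligning
    the filled amplitude, at the cost of leaving the real region outside
    [-1, 1] by the shift amount).
    """
    padded = np.asarray(padded, dtype=float)
    real = padded[:real_length]
    lo, hi = float(real.min()), float(real.max())
    if hi == lo:
        raise DegenerateSignalError("constant real region: cannot normalize")
    out = 2.0 * (padded - lo) / (hi - lo) - 1.0
    if zero_fill:
        out[real_length:] = 0.0
    else:
        out -= out[real_length] if real_length < out.size else 0.0
    return out


def preprocess_pipeline(
    rec: RawRecording,
    window: int = 100,
    target_length: int = 411,
    zero_fill: bool = True,
    provenance: str = "measured",
) -> NormalizedTrace:
    """Full preprocessing of one recording; raises with sample context on failure."""
    try:
        sig = extract_signal(rec)
        if sig.degenerate:
            raise DegenerateSignalError(
                "extract_signal: no depolarization below the wound-time baseline"
            )
        if sig.truncated:
            warnings.warn(
                f"{rec.sample_id}: recording ended before half recovery; "
                "using the full tail",
                stacklevel=2,
            )
        ct = local_mean_compress(sig, window=window)
        padded, real_length = pad_trace(ct, target_length=target_length)
        values = normalize_and_align(padded, real_length, zero_fill=zero_fill)
    except Exception as exc:
        raise type(exc)(f"[{rec.sample_id}] {exc}") from exc
    logger.debug(
        "preprocess %s: extracted=%d compressed=%d padded=%d",
        rec.sample_id, sig.values.size, len(ct), values.size,
    )
    return NormalizedTrace(
        values=values,
        real_length=real_length,
        sample_id=rec.sample_id,
        leaf=rec.leaf,
        condition=rec.condition,
        provenance=provenance,
    )


class SWPPreprocessor(BaseEstimator, TransformerMixin):
    """Transformer from raw recordings to the fixed-length normalized matrix.

    ``transform`` accepts a sequence of :class:`~swpkit.io.RawRecording` and
    returns an ``(n, target_length)`` float array. Per-sample metadata from
    the most recent call is kept on the estimator (``traces_``,
    ``real_lengths_``, ``labels_``) for downstream bookkeeping.

    Parameters
    ----------
    window : int, default 100
        Block width of the local mean compression, in samples.
    target_length : int, default 411
        Fixed output length after padding.
    zero_fill : bool, default True
        Zero the padded tail (see :func:`normalize_and_align`).
    """

    def __init__(self, window: int = 100, target_length: int = 411, zero_fill: bool = True):
        self.window = window
        self.target_length = target_length
        self.zero_fill = zero_fill

    def fit(self, X, y=None):  # stateless; kept for pipeline compatibility
        self.n_features_in_ = None
        return self

    def transform(self, X) -> np.ndarray:
        traces = [
            preprocess_pipeline(
                rec,
                window=self.window,
                target_length=self.target_length,
                zero_fill=self.zero_fill,
            )
            for rec in X
        ]
        self.traces_ = traces
        self.real_lengths_ = np.array([t.real_length for t in traces], dtype=int)
        self.labels_ = np.array([t.condition for t in traces], dtype=object)
        if not traces:
            return np.empty((0, self.target_length))
        return np.vstack([t.values for t in traces])

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y).transform(X)
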