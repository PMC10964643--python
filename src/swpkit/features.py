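"""Feature representations of normalized SWP traces.

Three alternative inputs to the classifiers:

* **12 time-domain scalars** — maximum, minimum, mean, variance, standard
  deviation, skewness, kurtosis, root mean square, area, declining slope,
  rising slope and amplitude, all computed with population (1/n) moments on
  the full fixed-length trace (zeroed tail included).
* **first derivative** — central difference (average of forward and backward
  quotients) at interior points, one-sided at the ends, with a 1 s step.
* **cumulative integral** — running trapezoid sum with a 1 s step, signed,
  starting at 0.

Moment conventions follow the operative definitions: skewness is
``m3 / m2**1.5`` and kurtosis ``m4 / m2**2`` (non-excess), with no
small-sample correction. The declining slope carries an explicit minus sign:
``(max - min) / -(t_min - t_first_max)``, so a maximum-before-minimum trace
yields a negative value. The scalar ``area`` sums the *absolute* trapezoid
segments, unlike the signed cumulative integral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from swpkit.errors import DataError, DegenerateSignalError

TIME_DOMAIN_COLUMNS: tuple[str, ...] = (
    "maximum",
    "minimum",
    "mean",
    "variance",
    "standard_deviation",
    "skewness",
    "kurtosis",
    "rms",
    "area",
    "decline_slope",
    "rising_slope",
    "amplitude",
)

FEATURE_KINDS: tuple[str, ...] = ("time_domain", "deriv_1st", "integral")


@dataclass(frozen=True)
class TimeDomainFeatures:
    maximum: float
    minimum: float
    mean: float
    variance: float
    standard_deviation: float
    skewness: float
    kurtosis: float
    rms: float
    area: float
    decline_slope: float
    rising_slope: float
    amplitude: float
    rising_slope_fallback: bool = False  # no maximum strictly after the minimum

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in TIME_DOMAIN_COLUMNS], dtype=float)


def _values(trace) -> np.ndarray:
    x = trace.values if hasattr(trace, "values") else trace
    return np.asarray(x, dtype=float)


def time_domain_features(trace) -> TimeDomainFeatures:
    """Compute the 12 time-domain scalars of a trace (dt = 1 s).

    Raises
    ------
    DegenerateSignalError
        If the trace has zero variance (skewness/kurtosis undefined).
    """
    x = _values(trace)
    n = x.size
    if n < 2:
        raise DataError("time_domain_features requires length >= 2")
    mean = x.mean()
    dev = x - mean
    m2 = np.mean(dev**2)
    if m2 == 0.0:
        raise DegenerateSignalError("zero variance: moments undefined")
    m3 = np.mean(dev**3)
    m4 = np.mean(dev**4)
    maximum = float(x.max())
    minimum = float(x.min())
    rms = float(np.sqrt(np.mean(x**2)))
    # area: sum of absolute trapezoid segments with unit step
    area = float(np.sum(np.abs((x[:-1] + x[1:]) / 2.0)))

    t_first_max = int(np.argmax(x))          # first index attaining the global max
    t_min = int(np.argmin(x))                # first index attaining the global min
    amp = maximum - minimum
    dt_d = t_min - t_first_max
    decline = amp / (-dt_d) if dt_d != 0 else np.inf * np.sign(amp) if amp else 0.0
    fallback = False
    if t_min < n - 1:
        after = x[t_min + 1:]
        t_next_max = t_min + 1 + int(np.argmax(after))
    else:
        t_next_max = n - 1
        fallback = True
    dt_r = t_next_max - t_min
    rising = amp / dt_r if dt_r != 0 else np.inf if amp else 0.0
    if fallback:
        warnings.warn(
            "minimum at the final sample: rising slope uses the last index",
            stacklevel=2,
        )
    return TimeDomainFeatures(
        maximum=maximum,
        minimum=minimum,
        mean=float(mean),
        variance=float(m2),
        standard_deviation=float(np.sqrt(m2)),
        skewness=float(m3 / m2**1.5),
        kurtosis=float(m4 / m2**2),
        rms=rms,
        area=area,
        decline_slope=float(decline),
        rising_slope=float(rising),
        amplitude=float(amp),
        rising_slope_fallback=fallback,
    )


def first_derivative(trace) -> np.ndarray:
    """First derivative with unit step: central differences inside, one-sided at ends.

    The interior value is the average of the forward and backward difference
    quotients, which equals ``(y[i+1] - y[i-1]) / 2`` on a unit grid. Output
    length equals input length; units 1/s.
    """
    y = _values(trace)
    if y.size < 2:
        raise DataError("first_derivative requires length >= 2")
    d = np.empty_like(y)
    d[0] = y[1] - y[0]
    d[-1] = y[-1] - y[-2]
    if y.size > 2:
        d[1:-1] = (y[2:] - y[:-2]) / 2.0
    return d


def cumulative_integral(trace) -> np.ndarray:
    """Signed running trapezoid integral with unit step; element 0 is 0. Units s."""
    y = _values(trace)
    if y.size < 2:
        raise DataError("cumulative_integral requires length >= 2")
    out = np.empty_like(y)
    out[0] = 0.0
    np.cumsum((y[1:] + y[:-1]) / 2.0, out=out[1:])
    return out


def build_feature_matrix(traces, kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-trace features into a design matrix plus aligned label vector.

    Parameters
    ----------
    traces : sequence of NormalizedTrace
    kind : {"time_domain", "deriv_1st", "integral"}

    Returns
    -------
    X : ndarray of shape (n, 12) or (n, L)
    labels : ndarray of condition strings, aligned with the rows of X
    """
    if kind not in FEATURE_KINDS:
        raise ValueError(f"kind must be one of {FEATURE_KINDS}, got {kind!r}")
    traces = list(traces)
    labels = np.array([getattr(t, "condition", "") for t in traces], dtype=object)
    if not traces:
        width = len(TIME_DOMAIN_COLUMNS) if kind == "time_domain" else 0
        return np.empty((0, width)), labels
    lengths = {len(_values(t)) for t in traces}
    if len(lengths) != 1:
        raise DataError(f"mixed trace lengths {sorted(lengths)}")
    if kind == "time_domain":
        X = np.vstack([time_domain_features(t).as_array() for t in traces])
    elif kind == "deriv_1st":
        X = np.vstack([first_derivative(t) for t in traces])
    else:
        X = np.vstack([cumulative_integral(t) for t in traces])
    return X, labels


class TraceFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer from an (n, L) trace matrix to a feature matrix.

    Operates row-wise on plain arrays so it slots into sklearn pipelines
    downstream of :class:`~swpkit.preprocess.SWPPreprocessor`.
    """

    def __init__(self, kind: str = "deriv_1st"):
        self.kind = kind

    def fit(self, X, y=None):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"kind must be one of {FEATURE_KINDS}, got {self.kind!r}")
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else None
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise DataError("expected a 2-D (n_samples, trace_length) array")
        if self.kind == "time_domain":
            return np.vstack([time_domain_features(row).as_array() for row in X]) \
                if X.shape[0] else np.empty((0, len(TIME_DOMAIN_COLUMNS)))
        if self.kind == "deriv_1st":
            return np.vstack([first_derivative(row) for row in X]) if X.shape[0] else X
        return np.vstack([cumulative_integral(row) for row in X]) if X.shape[0] else X
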