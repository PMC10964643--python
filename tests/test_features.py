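"""Feature formulas against independent loop-based oracles and hand values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from swpkit.errors import DataError, DegenerateSignalError
from swpkit.features import (
    TIME_DOMAIN_COLUMNS,
    TraceFeaturizer,
    build_feature_matrix,
    cumulative_integral,
    first_derivative,
    time_domain_features,
)
from swpkit.preprocess import NormalizedTrace


# ---------------------------------------------------------------------------
# Independent oracles: literal loop re-implementations of each formula
# ---------------------------------------------------------------------------

def oracle_scalars(x):
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    out = {
        "maximum": max(x),
        "minimum": min(x),
        "mean": mean,
        "variance": m2,
        "standard_deviation": math.sqrt(m2),
        "skewness": m3 / m2 ** 1.5,
        "kurtosis": m4 / m2 ** 2,
        "rms": math.sqrt(sum(v * v for v in x) / n),
        "area": sum(abs((x[i] + x[i + 1]) / 2.0) for i in range(n - 1)),
        "amplitude": max(x) - min(x),
    }
    t_max = x.index(max(x))
    t_min = x.index(min(x))
    out["decline_slope"] = (max(x) - min(x)) / -(t_min - t_max)
    post = x[t_min + 1:]
    t_next = (t_min + 1 + post.index(max(post))) if post else len(x) - 1
    out["rising_slope"] = (max(x) - min(x)) / (t_next - t_min) if t_next != t_min else 0.0
    return out


def oracle_derivative(x):
    n = len(x)
    d = [0.0] * n
    d[0] = x[1] - x[0]
    d[-1] = x[-1] - x[-2]
    for i in range(1, n - 1):
        d[i] = 0.5 * ((x[i + 1] - x[i]) + (x[i] - x[i - 1]))
    return d


def oracle_integral(x):
    out = [0.0]
    for i in range(1, len(x)):
        out.append(out[-1] + (x[i] + x[i - 1]) / 2.0)
    return out


class TestTimeDomainScalars:
    def test_hand_example_symmetric_pulse(self):
        f = time_domain_features(np.array([-1.0, 0.0, 1.0, 0.0, 0.0]))
        assert f.maximum == 1.0 and f.minimum == -1.0
        assert f.mean == pytest.approx(0.0)
        assert f.variance == pytest.approx(0.4)
        assert f.standard_deviation == pytest.approx(math.sqrt(0.4))
        assert f.rms == pytest.approx(math.sqrt(0.4))
        assert f.amplitude == 2.0
        assert f.skewness == pytest.approx(0.0)
        assert f.kurtosis == pytest.approx(2.5)
        assert f.area == pytest.approx(1.5)

    def test_hand_example_slopes(self):
        f = time_domain_features(np.array([1.0, 0.0, -1.0, 0.0, 1.0]))
        assert f.decline_slope == pytest.approx(-1.0)
        assert f.rising_slope == pytest.approx(1.0)

    def test_constant_trace_raises(self):
        with pytest.raises(DegenerateSignalError):
            time_domain_features(np.ones(10))

    def test_min_at_last_index_falls_back_with_flag(self):
        with pytest.warns(UserWarning, match="rising slope"):
            f = time_domain_features(np.array([1.0, 0.0, -1.0]))
        assert f.rising_slope_fallback

    def test_matches_loop_oracle_on_random_vectors(self, rng):
        done = 0
        while done < 1000:
            x = rng.normal(0.0, 2.0, int(rng.integers(4, 60))).round(4)
            if np.argmin(x) == x.size - 1 or np.ptp(x) == 0:
                continue  # rising-slope fallback case, tested separately
            f = time_domain_features(x)
            expect = oracle_scalars(list(x))
            for name, val in expect.items():
                assert getattr(f, name) == pytest.approx(val, rel=1e-12, abs=1e-12), name
            done += 1


class TestDerivativeAndIntegral:
    def test_linear_ramp_derivative_constant(self):
        d = first_derivative(2.0 * np.arange(10.0))
        np.testing.assert_allclose(d, 2.0)

    def test_constant_trace_zero_derivative(self):
        np.testing.assert_array_equal(first_derivative(np.full(5, 3.0)), 0.0)

    def test_hand_example_derivative(self):
        np.testing.assert_allclose(first_derivative(np.array([0.0, 1.0, 4.0])),
                                   [1.0, 2.0, 3.0])

    def test_constant_one_integral_counts_steps(self):
        np.testing.assert_allclose(cumulative_integral(np.ones(5)),
                                   [0.0, 1.0, 2.0, 3.0, 4.0])

    def test_ramp_integral_hand_values(self):
        np.testing.assert_allclose(cumulative_integral(np.arange(5.0)),
                                   [0.0, 0.5, 2.0, 4.5, 8.0])

    def test_zero_trace_integral_zero(self):
        np.testing.assert_array_equal(cumulative_integral(np.zeros(7)), 0.0)

    def test_match_loop_oracles(self, rng):
        for _ in range(1000):
            x = rng.normal(size=int(rng.integers(2, 40)))
            np.testing.assert_allclose(first_derivative(x), oracle_derivative(list(x)),
                                       atol=1e-12)
            np.testing.assert_allclose(cumulative_integral(x), oracle_integral(list(x)),
                                       atol=1e-12)

    @given(arrays(float, st.integers(4, 100),
                  elements=st.floats(-100, 100, allow_nan=False)))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_derivative_of_integral_smoothing_identity(self, y):
        # composing the two unit-step operators yields y plus a quarter of its
        # second difference at interior points — exactly
        recovered = first_derivative(cumulative_integral(y))
        second_diff = y[2:] - 2 * y[1:-1] + y[:-2]
        np.testing.assert_allclose(recovered[1:-1], y[1:-1] + second_diff / 4.0,
                                   atol=1e-9)

    def test_derivative_of_integral_recovers_affine_traces(self, rng):
        # the second-difference term vanishes for locally linear traces, so
        # the operators are mutual inverses there
        for _ in range(50):
            a, b = rng.normal(size=2)
            y = a * np.arange(411.0) + b
            recovered = first_derivative(cumulative_integral(y))
            np.testing.assert_allclose(recovered[1:-1], y[1:-1], atol=1e-9)


class TestFeatureMatrix:
    def test_shapes_per_kind(self, leaf8_traces):
        X, y = build_feature_matrix(leaf8_traces, "deriv_1st")
        assert X.shape == (55, 411) and len(y) == 55
        X, _ = build_feature_matrix(leaf8_traces, "integral")
        assert X.shape == (55, 411)
        X, _ = build_feature_matrix(leaf8_traces, "time_domain")
        assert X.shape == (55, 12)
        assert len(TIME_DOMAIN_COLUMNS) == 12

    def test_row_order_and_labels_aligned(self, leaf8_traces):
        _, y = build_feature_matrix(leaf8_traces, "time_domain")
        assert list(y) == [t.condition for t in leaf8_traces]

    def test_empty_input_gives_empty_matrix(self):
        X, y = build_feature_matrix([], "time_domain")
        assert X.shape == (0, 12) and len(y) == 0

    def test_mixed_lengths_rejected(self):
        a = NormalizedTrace(values=np.arange(10.0), real_length=10)
        short = NormalizedTrace(values=np.arange(5.0), real_length=5)
        with pytest.raises(DataError, match="mixed"):
            build_feature_matrix([a, short], "deriv_1st")

    def test_transformer_matches_functions(self, rng):
        X = rng.normal(size=(4, 30))
        np.testing.assert_array_equal(
            TraceFeaturizer("deriv_1st").fit_transform(X),
            np.vstack([first_derivative(row) for row in X]),
        )
        td = TraceFeaturizer("time_domain").fit_transform(X)
        assert td.shape == (4, 12)


class TestZeroPaddingEffect:
    def test_max_min_amplitude_invariant_when_zero_interior(self, rng):
        # appending zeros leaves max/min/amplitude unchanged exactly when the
        # range already brackets zero, as it does for normalized traces
        x = np.concatenate([rng.uniform(-1, -0.2, 10), rng.uniform(0.2, 1, 10)])
        fx = time_domain_features(x)
        fpad = time_domain_features(np.concatenate([x, np.zeros(20)]))
        assert fx.maximum == fpad.maximum
        assert fx.minimum == fpad.minimum
        assert fx.amplitude == fpad.amplitude
        # but the mean-dependent moments do change: computed over the full vector
        assert fx.variance != fpad.variance
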