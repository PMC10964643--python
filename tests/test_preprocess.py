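"""Preprocessing stages: extraction, compression, padding, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swpkit.errors import DegenerateSignalError, LengthError
from swpkit.io import RawRecording
from swpkit.preprocess import (
    SWPPreprocessor,
    extract_signal,
    local_mean_compress,
    normalize_and_align,
    pad_trace,
    preprocess_pipeline,
)


def rec_from(values, wound_index=0, **kw):
    defaults = dict(sample_id="s", leaf=8, condition="Normal",
                    values=np.asarray(values, dtype=float), wound_index=wound_index)
    defaults.update(kw)
    return RawRecording(**defaults)


def brute_force_stop(values, start):
    """Independent oracle: literal scan for the half-recovery stop index."""
    baseline = values[start]
    seg = values[start:]
    min_idx = start + int(np.argmin(seg))
    minimum = values[min_idx]
    if minimum >= baseline or min_idx == len(values) - 1:
        return None
    half = baseline - (baseline - minimum) / 2.0
    for j in range(min_idx + 1, len(values)):
        if values[j] >= half:
            return j
    return None


class TestExtractSignal:
    def test_linear_drop_and_rise_geometry(self):
        # baseline 0 at wound 100, linear drop to -10 at index 300 (200 past
        # wound), then rise at 0.05 mV/sample: half level -5 first reached
        # 100 samples past the minimum
        values = np.zeros(1000)
        values[100:301] = np.linspace(0.0, -10.0, 201)
        values[301:] = -10.0 + 0.05 * np.arange(1, 700)
        sig = extract_signal(rec_from(values, wound_index=100))
        assert sig.values[0] == 0.0
        assert sig.values[-1] >= -5.0 and sig.values[-2] < -5.0
        assert len(sig.values) == 301  # indices 100..400 inclusive
        assert not sig.truncated

    def test_flat_recording_flagged_degenerate(self):
        sig = extract_signal(rec_from(np.zeros(100)))
        assert sig.degenerate

    def test_no_recovery_returns_tail_with_flag(self):
        values = np.concatenate([np.zeros(10), np.linspace(0, -10, 90)])
        sig = extract_signal(rec_from(values))
        assert sig.truncated
        assert len(sig.values) == 100

    def test_stop_is_first_at_or_above_half_level(self):
        # plateau exactly at the half level: >= takes the first plateau sample
        values = np.array([0.0, -10.0, -6.0, -5.0, -5.0, -4.0])
        sig = extract_signal(rec_from(values))
        assert len(sig.values) == 4

    def test_matches_brute_force_on_random_traces(self, rng):
        for _ in range(1000):
            n = int(rng.integers(10, 120))
            values = rng.normal(0.0, 1.0, n).cumsum()
            start = int(rng.integers(0, n - 2))
            expected = brute_force_stop(values, start)
            sig = extract_signal(rec_from(values, wound_index=start))
            if expected is None:
                assert sig.truncated or sig.degenerate
            else:
                assert not sig.truncated and not sig.degenerate
                assert start + len(sig.values) - 1 == expected


class TestLocalMeanCompress:
    def test_12800_points_window_100_gives_128(self):
        out = local_mean_compress(np.arange(12_800, dtype=float), window=100)
        assert len(out) == 128

    def test_constant_signal_preserved(self):
        out = local_mean_compress(np.full(250, 3.5), window=100)
        np.testing.assert_array_equal(out.values, [3.5, 3.5, 3.5])

    def test_block_means_with_partial_tail(self):
        out = local_mean_compress(np.arange(1.0, 251.0), window=100)
        np.testing.assert_allclose(out.values, [50.5, 150.5, 225.5])

    @given(st.integers(1, 400), st.integers(1, 50))
    @settings(deadline=None, derandomize=True)
    def test_length_is_ceil_n_over_window(self, n, window):
        out = local_mean_compress(np.zeros(n), window=window)
        assert len(out) == -(-n // window)

    def test_mean_preserving_per_block(self, rng):
        x = rng.normal(size=537)
        window = 100
        out = local_mean_compress(x, window=window)
        for b in range(len(out)):
            block = x[b * window: (b + 1) * window]
            assert out.values[b] == pytest.approx(block.mean(), abs=1e-12)


class TestPadTrace:
    def test_repeat_last_value(self):
        padded, real = pad_trace(np.concatenate([np.zeros(127), [7.0]]), 411)
        assert real == 128
        np.testing.assert_array_equal(padded[128:], 7.0)
        assert len(padded) == 411

    def test_exact_length_unchanged(self):
        x = np.arange(411, dtype=float)
        padded, real = pad_trace(x, 411)
        np.testing.assert_array_equal(padded, x)
        assert real == 411

    def test_too_long_refused(self):
        with pytest.raises(LengthError, match="target_length"):
            pad_trace(np.zeros(412), 411)


class TestNormalizeAndAlign:
    def test_hand_example(self):
        padded, real = pad_trace(np.array([0.0, 5.0, 10.0]), 5)
        out = normalize_and_align(padded, real)
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0, 0.0, 0.0])

    def test_fixed_point_on_full_range_real_region(self):
        x = np.array([-1.0, 0.25, 1.0, 1.0, 1.0])
        out = normalize_and_align(x, 3)
        np.testing.assert_allclose(out[:3], x[:3])
        np.testing.assert_array_equal(out[3:], 0.0)

    def test_constant_region_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            normalize_and_align(np.ones(10), 5)

    def test_idempotent_on_real_region(self, rng):
        x = rng.normal(size=20)
        padded, real = pad_trace(x, 30)
        once = normalize_and_align(padded, real)
        twice = normalize_and_align(once.copy(), real)
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_global_shift_variant_zeroes_fill(self):
        padded, real = pad_trace(np.array([0.0, 5.0, 10.0, 2.0]), 6)
        out = normalize_and_align(padded, real, zero_fill=False)
        np.testing.assert_allclose(out[real:], 0.0, atol=1e-12)
        # shifted, not clipped: real region keeps its shape
        np.testing.assert_allclose(np.diff(out[:real]),
                                   np.diff(normalize_and_align(padded, real)[:real]))


class TestPipeline:
    def test_invariants_on_synthetic_dataset(self, leaf8_traces):
        assert len(leaf8_traces) == 55
        for t in leaf8_traces:
            assert len(t.values) == 411
            assert t.values.min() >= -1.0 and t.values.max() <= 1.0
            np.testing.assert_array_equal(t.values[t.real_length:], 0.0)
            real = t.values[: t.real_length]
            assert real.min() == pytest.approx(-1.0)
            assert real.max() == pytest.approx(1.0)

    def test_degenerate_recording_names_stage(self):
        flat = rec_from(np.zeros(100))
        with pytest.raises(DegenerateSignalError, match="extract_signal"):
            preprocess_pipeline(flat)

    def test_error_carries_sample_id(self):
        flat = rec_from(np.zeros(100), sample_id="bad_one")
        with pytest.raises(DegenerateSignalError, match="bad_one"):
            preprocess_pipeline(flat)

    def test_transformer_matches_function(self, leaf8_recordings, leaf8_traces):
        X = SWPPreprocessor().fit_transform(leaf8_recordings[:5])
        assert X.shape == (5, 411)
        np.testing.assert_array_equal(X[0], leaf8_traces[0].values)
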