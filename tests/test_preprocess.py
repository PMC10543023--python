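"""Resampling, re-referencing, notch, streaming normalization, artifacts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from nstream.preprocess import (
    NormalizerState,
    detect_artifacts,
    notch_filter,
    rereference,
    resample,
    running_normalize,
)
from nstream.stream_io import ChannelTable, SignalBatch, _normalize_channel_frame


def _batch(data, fs, names=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    names = names or [f"ch{i}" for i in range(data.shape[0])]
    return SignalBatch(data=data, fs=fs, end_time_s=data.shape[1] / fs,
                       channel_names=names)


def _table(names, reref, status=None, target=None):
    n = len(names)
    frame = pd.DataFrame(
        {
            "name": names,
            "type": ["ecog"] * n,
            "status": status or ["good"] * n,
            "used": 1,
            "target": target or [0] * n,
            "rereference": reref,
        }
    )
    return ChannelTable(_normalize_channel_frame(frame))


class TestResample:
    def test_sinusoid_survives_downsampling(self):
        fs = 4000.0
        t = np.arange(int(2 * fs)) / fs
        x = np.sin(2 * np.pi * 10 * t)
        out = resample(_batch(x, fs), 1000.0)
        assert out.data.shape[1] == 2000
        freqs = np.fft.rfftfreq(2000, 1 / 1000.0)
        spec = np.abs(np.fft.rfft(out.data[0]))
        assert freqs[np.argmax(spec)] == pytest.approx(10.0, abs=0.5)
        assert out.data[0].std() == pytest.approx(x.std(), rel=0.01)

    def test_same_rate_is_identity(self, rng):
        x = rng.normal(size=(2, 500))
        out = resample(_batch(x, 1000.0), 1000.0)
        np.testing.assert_array_equal(out.data, x)

    def test_white_noise_variance_matches_band_limited_expectation(self, rng):
        # downsampling keeps only the 0-125 Hz quarter of a white spectrum;
        # cross-check against a direct decimation oracle
        fs = 1000.0
        x = rng.normal(size=int(10 * fs))
        out = resample(_batch(x, fs), 250.0)
        assert out.data[0].var() == pytest.approx(x.var() / 4.0, rel=0.10)
        import scipy.signal

        oracle = scipy.signal.decimate(x, 4)
        assert out.data[0].var() == pytest.approx(oracle.var(), rel=0.20)

    def test_too_few_output_samples_raises(self):
        with pytest.raises(ValueError):
            resample(_batch(np.zeros(100), 1000.0), 5.0)


class TestRereference:
    def test_identical_channels_car_to_zero(self):
        table = _table(["a", "b", "c"], ["common_average"] * 3)
        x = np.tile(np.sin(np.arange(100)), (3, 1))
        out = rereference(_batch(x, 1000.0, ["a", "b", "c"]), table)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_car_mean_is_zero_for_random_channels(self, rng):
        names = list("abcd")
        table = _table(names, ["common_average"] * 4)
        x = rng.normal(size=(4, 256))
        out = rereference(_batch(x, 1000.0, names), table)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-12

    def test_bipolar_pair_of_identical_channels_is_zero(self):
        table = _table(["a", "b"], ["bipolar:b", "none"])
        x = np.vstack([np.sin(np.arange(50)), np.sin(np.arange(50))])
        out = rereference(_batch(x, 1000.0, ["a", "b"]), table)
        np.testing.assert_allclose(out.data[0], 0.0, atol=1e-15)

    def test_target_passes_through_and_is_excluded_from_car(self, rng):
        names = ["a", "b", "mov"]
        table = _table(names, ["common_average", "common_average", "none"],
                       target=[0, 0, 1])
        x = rng.normal(size=(3, 64))
        out = rereference(_batch(x, 1000.0, names), table)
        np.testing.assert_array_equal(out.data[2], x[2])
        car = x[:2].mean(axis=0)
        np.testing.assert_allclose(out.data[0], x[0] - car)

    def test_bad_bipolar_partner_raises(self, rng):
        table = _table(["a", "b"], ["bipolar:b", "none"], status=["good", "bad"])
        # b stays in the table (bad channels are retained) but cannot serve
        # as a bipolar reference
        table.frame.loc[1, "used"] = True
        x = rng.normal(size=(2, 32))
        with pytest.raises(ValueError, match="bad"):
            rereference(_batch(x, 1000.0, ["a", "b"]), table)

    def test_rereferencing_is_linear(self, rng):
        names = list("abcd")
        table = _table(names, ["common_average"] * 3 + ["bipolar:a"])
        xa = rng.normal(size=(4, 128))
        xb = rng.normal(size=(4, 128))
        out_sum = rereference(_batch(xa + xb, 1000.0, names), table).data
        out_a = rereference(_batch(xa, 1000.0, names), table).data
        out_b = rereference(_batch(xb, 1000.0, names), table).data
        np.testing.assert_allclose(out_sum, out_a + out_b, atol=1e-12)


class TestNotchFilter:
    fs = 1000.0

    def _rms(self, x):
        return float(np.sqrt(np.mean(x**2)))

    def test_line_frequency_suppressed(self):
        t = np.arange(int(2 * self.fs)) / self.fs
        x = np.sin(2 * np.pi * 50 * t)
        out = notch_filter(_batch(x, self.fs), 50.0)
        assert self._rms(out.data[0]) < 0.1 * self._rms(x)

    def test_passband_preserved(self):
        t = np.arange(int(2 * self.fs)) / self.fs
        x = np.sin(2 * np.pi * 10 * t)
        out = notch_filter(_batch(x, self.fs), 50.0)
        assert self._rms(out.data[0]) == pytest.approx(self._rms(x), rel=0.05)

    def test_zero_in_zero_out(self):
        out = notch_filter(_batch(np.zeros(500), self.fs), 50.0)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_line_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            notch_filter(_batch(np.zeros(500), self.fs), 500.0)


class TestRunningNormalize:
    def test_constant_series_normalizes_to_zero(self):
        state = NormalizerState()
        outs = [running_normalize(np.array([5.0]), t / 10, state)[0]
                for t in range(50)]
        assert all(o == 0.0 for o in outs)

    def test_population_sd_arithmetic(self):
        state = NormalizerState()
        running_normalize(np.array([0.0]), 0.0, state)
        running_normalize(np.array([10.0]), 0.1, state)
        out = running_normalize(np.array([20.0]), 0.2, state)
        # past {0, 10}: mean 5, population sd 5 -> (20-5)/5 = 3.0
        assert out[0] == pytest.approx(3.0)

    def test_extreme_value_clipped_to_three(self, rng):
        state = NormalizerState()
        for t in range(20):
            running_normalize(rng.normal(size=(3,)), t / 10, state)
        out = running_normalize(np.full(3, 1e6), 2.0, state)
        np.testing.assert_array_equal(out, 3.0)

    def test_online_equals_explicit_trailing_window(self, rng):
        # oracle: explicit slice per row, recomputed from scratch
        times = np.arange(400) * 0.1
        series = rng.normal(size=(400, 2))
        state = NormalizerState(window_s=5.0, clip=3.0)
        online = np.vstack(
            [running_normalize(series[i], times[i], state) for i in range(400)]
        )
        for i in range(400):
            past = series[(times >= times[i] - 5.0 - 1e-9) & (times < times[i])]
            if len(past) < 2:
                expected = np.zeros(2)
            else:
                sd = past.std(axis=0)
                expected = np.clip((series[i] - past.mean(axis=0)) / sd, -3, 3)
                expected[sd == 0] = 0.0
            np.testing.assert_allclose(online[i], expected, atol=1e-12)

    @hyp_settings(max_examples=50, deadline=None)
    @given(
        values=st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=3,
            max_size=40,
        )
    )
    def test_outputs_always_within_clip_bound(self, values):
        state = NormalizerState(window_s=10.0, clip=3.0)
        for i, v in enumerate(values):
            out = running_normalize(np.array([v]), i * 0.5, state)
            assert -3.0 <= out[0] <= 3.0

    def test_nan_rows_pass_through_as_nan(self, rng):
        state = NormalizerState()
        for t in range(5):
            running_normalize(rng.normal(size=(2,)), t / 10.0, state)
        out = running_normalize(np.array([np.nan, 1.0]), 0.6, state)
        assert np.isnan(out[0]) and np.isfinite(out[1])


class TestDetectArtifacts:
    fs = 250.0

    def _noise_with_run(self, rng, run_len, kind="flat"):
        x = rng.normal(size=1000)
        if kind == "flat":
            x[400 : 400 + run_len] = x[400]
        else:  # constant-slope ramp (dyadic base keeps the diffs exact, as
            # quantized amplifier output would)
            x[400 : 400 + run_len] = 2.0 + 0.5 * np.arange(run_len)
        return x

    def test_twelve_sample_flatline_masked_exactly(self, rng):
        x = self._noise_with_run(rng, 12)
        mask = detect_artifacts(x, self.fs)
        np.testing.assert_array_equal(np.flatnonzero(mask.mask[0]),
                                      np.arange(400, 412))

    def test_eleven_sample_flatline_not_masked(self, rng):
        x = self._noise_with_run(rng, 11)
        assert not detect_artifacts(x, self.fs).mask.any()

    def test_linear_ramp_is_clipping_artifact(self, rng):
        # brute-force oracle: scan runs of identical first differences
        x = self._noise_with_run(rng, 20, kind="ramp")
        mask = detect_artifacts(x, self.fs).mask[0]
        d = np.diff(x)
        expected = np.zeros_like(mask)
        i = 0
        while i < d.size:
            j = i
            while j < d.size and d[j] == d[i]:
                j += 1
            if (j - i) + 1 >= 12:
                expected[i : j + 1] = True
            i = j
        np.testing.assert_array_equal(mask, expected)
        assert mask[400:420].all()

    def test_stim_masks_exactly_two_seconds(self):
        x = np.random.default_rng(0).normal(size=(2, 2500))
        mask = detect_artifacts(x, self.fs, stim_times_s=[2.0])
        lo, hi = int(2.0 * self.fs), int(4.0 * self.fs)
        assert mask.mask[:, lo : hi + 1].all()
        assert not mask.mask[:, : lo - 1].any()
        assert not mask.mask[:, hi + 2 :].any()
        assert mask.events[0]["kind"] == "post_stimulation"
        assert mask.events[0]["end_s"] - mask.events[0]["start_s"] == 2.0

    def test_idempotent_on_nan_masked_regions(self, rng):
        x = rng.normal(size=500)
        x[100:160] = np.nan
        assert not detect_artifacts(x, self.fs).mask.any()
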