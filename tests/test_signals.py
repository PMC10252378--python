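"""Filtering, normalization, and segmentation behaviour."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from drivestress.errors import EmptyInputError, InvalidSpecError
from drivestress.signals import (
    ChannelSignal,
    FilterSpec,
    MultiChannelRecording,
    PhaseAnnotation,
    apply_filter,
    clean_channel,
    minmax_normalize,
    resample_channel,
    segment_record,
)


def tone(freq, fs, duration=20.0, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def band_power(x, fs, freq, half_width=0.5):
    """FFT amplitude oracle: total spectral power within freq +/- half_width."""
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    return spec[(freqs >= freq - half_width) & (freqs <= freq + half_width)].sum()


class TestApplyFilter:
    def test_zero_signal_stays_zero(self):
        x = ChannelSignal("z", np.zeros(4000), fs=496.0)
        for spec in (
            FilterSpec("notch", (59, 61), order=2),
            FilterSpec("fir-bandpass", (1.5, 150), order=101),
            FilterSpec("butterworth-lowpass", (4.0,)),
            FilterSpec("gaussian", sigma_s=0.5),
        ):
            assert np.allclose(apply_filter(x, spec).samples, 0.0)

    def test_length_and_rate_preserved(self):
        x = ChannelSignal("s", tone(10, 496.0), fs=496.0)
        y = apply_filter(x, FilterSpec("fir-bandpass", (1.5, 150), order=101))
        assert len(y.samples) == len(x.samples)
        assert y.fs == x.fs

    def test_notch_kills_60hz(self):
        fs = 496.0
        x = ChannelSignal("hum", tone(60, fs), fs=fs)
        y = apply_filter(x, FilterSpec("notch", (59, 61), order=2))
        in_rms = np.sqrt((x.samples**2).mean())
        out_rms = np.sqrt((y.samples**2).mean())
        assert out_rms < 0.05 * in_rms
        assert band_power(y.samples, fs, 60) < 0.01 * band_power(x.samples, fs, 60)

    def test_fir_bandpass_passes_10hz(self):
        fs = 496.0
        x = ChannelSignal("t", tone(10, fs), fs=fs)
        y = apply_filter(x, FilterSpec("fir-bandpass", (1.5, 150), order=101))
        in_rms = np.sqrt((x.samples**2).mean())
        out_rms = np.sqrt((y.samples**2).mean())
        assert abs(out_rms - in_rms) < 0.10 * in_rms

    def test_zero_phase_no_delay(self):
        fs = 200.0
        x = ChannelSignal("t", tone(5, fs), fs=fs)
        y = apply_filter(x, FilterSpec("butterworth-lowpass", (20.0,), zero_phase=True))
        lag = np.argmax(np.correlate(y.samples, x.samples, "full")) - (len(x.samples) - 1)
        assert lag == 0

    def test_filter_idempotent_in_passband(self):
        fs = 496.0
        spec = FilterSpec("fir-bandpass", (1.5, 150), order=101)
        x = ChannelSignal("t", tone(20, fs), fs=fs)
        once = apply_filter(x, spec)
        twice = apply_filter(once, spec)
        rms = lambda s: np.sqrt((s.samples**2).mean())
        assert abs(rms(twice) - rms(once)) < 0.01 * rms(once)

    def test_edge_clipping_warns_and_collapsed_band_raises(self):
        spec = FilterSpec("butterworth-bandpass", (0.5, 500.0))
        with pytest.warns(UserWarning, match="clipped"):
            edges = spec.effective_edges(495.0)
        assert edges[1] == pytest.approx(0.45 * 495.0)
        with pytest.raises(InvalidSpecError, match="collapsed"):
            FilterSpec("notch", (59, 61), order=2).effective_edges(30.0)

    def test_empty_signal_rejected(self):
        with pytest.raises(EmptyInputError):
            ChannelSignal("e", np.array([]), fs=10.0)
        x = ChannelSignal("e", np.zeros(5), fs=10.0)
        x.samples = np.array([])  # mutation past validation
        with pytest.raises(EmptyInputError):
            apply_filter(x, FilterSpec("butterworth-lowpass", (2.0,)))


class TestCleanChannel:
    def test_constant_gsr_scales_to_one(self):
        x = ChannelSignal("gsr", np.full(2000, 3.5), fs=31.0)
        y = clean_channel(x, "gsr")
        assert np.allclose(y.samples, 1.0, atol=1e-6)

    def test_ecg_drift_and_hum_removed(self):
        fs = 496.0
        t = np.arange(int(30 * fs)) / fs
        pulses = (np.mod(t, 0.5) < 0.02).astype(float)  # 2 Hz pulse train
        drift = 2.0 * np.sin(2 * np.pi * 0.2 * t)
        hum = 0.5 * np.sin(2 * np.pi * 60.0 * t)
        x = ChannelSignal("ecg", pulses + drift + hum, fs=fs)
        y = clean_channel(x, "ecg")
        # min-max rescales; compare band powers relative to the 2 Hz fundamental
        before = x.samples
        after = y.samples - y.samples.mean()
        for noise_freq in (0.2, 60.0):
            ratio_before = band_power(before, fs, noise_freq) / band_power(before, fs, 2.0)
            ratio_after = band_power(after, fs, noise_freq) / band_power(after, fs, 2.0)
            assert ratio_after < 0.01 * ratio_before  # >= 20 dB relative reduction

    def test_resp_high_frequency_attenuated(self):
        fs = 31.0
        x = ChannelSignal("resp", tone(0.25, fs, 120) + tone(5.0, fs, 120), fs=fs)
        y = clean_channel(x, "resp")
        ratio_before = band_power(x.samples, fs, 5.0, 0.2) / band_power(x.samples, fs, 0.25, 0.1)
        ratio_after = band_power(y.samples, fs, 5.0, 0.2) / band_power(y.samples, fs, 0.25, 0.1)
        assert ratio_after < 0.01 * ratio_before

    def test_unknown_kind_and_low_fs_errors(self):
        x = ChannelSignal("x", tone(1, 31.0), fs=31.0)
        with pytest.raises(ValueError, match="unknown channel kind"):
            clean_channel(x, "eeg")
        with pytest.raises(InvalidSpecError, match="notch"):
            clean_channel(x, "ecg")  # 59-61 Hz notch unrealizable at 31 Hz


class TestMinMax:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([0, 5, 10], [0, 0.5, 1]),
            ([-1, 0, 3], [0, 0.25, 1]),
            ([7, 7, 7], [0, 0, 0]),
        ],
    )
    def test_examples(self, x, expected):
        assert np.allclose(minmax_normalize(x), expected)

    @given(
        x=st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50),
        a=st.floats(0.1, 100.0),
        b=st.floats(-100.0, 100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_positive_affine_invariance(self, x, a, b):
        x = np.asarray(x)
        # guard against floating-point absorption: a*x + b must keep the
        # spread of x representable next to b
        assume(a * (x.max() - x.min()) > 1e-9 * (1.0 + abs(b)))
        assert np.allclose(
            minmax_normalize(a * x + b), minmax_normalize(x), atol=1e-9
        )

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            minmax_normalize([])


def make_recording(intervals, fs=8.0, n_channels=2, scheme="three", names=None):
    dur = intervals[-1][1]
    names = names or [f"c{i}" for i in range(n_channels)]
    channels = {
        name: ChannelSignal(name, np.arange(int(dur * fs)) * (i + 1.0), fs=fs)
        for i, name in enumerate(names)
    }
    return MultiChannelRecording(
        channels=channels, annotation=PhaseAnnotation(intervals, label_scheme=scheme)
    )


class TestSegmentation:
    def test_single_phase_counts_and_labels(self):
        rec = make_recording([(0, 100, "rest")])
        seg = segment_record(rec, window_s=10, overlap=0.0, common_fs=8.0)
        assert len(seg) == 10
        assert (seg.labels == 0).all()

    def test_half_overlap_count(self):
        rec = make_recording([(0, 100, "rest")])
        seg = segment_record(rec, window_s=10, overlap=0.5, common_fs=8.0)
        assert len(seg) == 19

    @pytest.mark.parametrize("n_s,w_s,overlap", [(60, 7, 0.0), (60, 7, 0.5), (45, 10, 0.25)])
    def test_window_count_matches_enumeration_oracle(self, n_s, w_s, overlap):
        fs = 8.0
        rec = make_recording([(0, n_s, "city")])
        seg = segment_record(rec, window_s=w_s, overlap=overlap, common_fs=fs)
        n, w = int(n_s * fs), int(round(w_s * fs))
        stride = max(1, int(round(w * (1 - overlap))))
        brute = sum(1 for start in range(0, n) if start % stride == 0 and start + w <= n)
        assert len(seg) == brute == (n - w) // stride + 1

    def test_phase_boundary_majority_labels(self):
        rec = make_recording([(0, 30, "rest"), (30, 60, "city")])
        seg = segment_record(rec, window_s=10, overlap=0.0, common_fs=8.0)
        assert seg.labels.tolist() == [0, 0, 0, 2, 2, 2]

    def test_straddling_window_takes_majority(self):
        rec = make_recording([(0, 14, "rest"), (14, 34, "city")])
        # windows [0,10) rest, [10,20) 4s rest/6s city -> city, [20,30) city
        seg = segment_record(rec, window_s=10, overlap=0.0, common_fs=8.0)
        assert seg.labels.tolist() == [0, 2, 2]

    def test_two_level_scheme_maps_driving_to_stressed(self):
        rec = make_recording([(0, 20, "rest"), (20, 40, "highway"), (40, 60, "city")], scheme="two")
        seg = segment_record(rec, window_s=10, overlap=0.0, common_fs=8.0)
        assert seg.labels.tolist() == [0, 0, 1, 1, 1, 1]
        assert seg.class_names == ("relaxed", "stressed")

    def test_channel_order_never_changes_labels(self):
        ivals = [(0, 30, "rest"), (30, 60, "highway")]
        a = make_recording(ivals, names=["ecg", "gsr", "resp"])
        b = make_recording(ivals, names=["resp", "ecg", "gsr"])
        sa = segment_record(a, 10, 0.5)
        sb = segment_record(b, 10, 0.5)
        assert sa.labels.tolist() == sb.labels.tolist()
        assert sa.channel_names == sb.channel_names  # alphabetical stacking

    def test_window_longer_than_recording_errors(self):
        rec = make_recording([(0, 20, "rest")])
        with pytest.raises(ValueError, match="longer than"):
            segment_record(rec, window_s=30, overlap=0.0)

    def test_mixed_rate_channels_resampled_to_common_grid(self):
        channels = {
            "slow": ChannelSignal("slow", np.ones(40 * 4), fs=4.0),
            "fast": ChannelSignal("fast", np.ones(40 * 496), fs=496.0),
        }
        rec = MultiChannelRecording(
            channels=channels, annotation=PhaseAnnotation([(0, 40, "rest")])
        )
        seg = segment_record(rec, window_s=10, overlap=0.0, common_fs=8.0)
        assert seg.windows.shape == (4, 80, 2)

    def test_resample_preserves_linear_signal(self):
        x = ChannelSignal("r", np.arange(100, dtype=float), fs=10.0)
        y = resample_channel(x, 5.0)
        assert y.fs == 5.0
        assert np.allclose(y.samples, np.arange(0, 100, 2.0))
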