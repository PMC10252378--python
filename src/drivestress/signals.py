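"""Physiological-signal cleaning, normalization, and windowed segmentation.

Each sensor modality gets the cleaning chain that is standard for it in
ambulatory stress research:

* **ECG / HR** — mains-interference notch (59–61 Hz), 1.5–150 Hz FIR
  band-pass (removes baseline wander while keeping waveform morphology),
  then min–max normalization.  The classic 5–15 Hz QRS-detection band is
  available separately via :func:`qrs_band`.
* **GSR / EDA** — 4 Hz low-pass, Gaussian smoothing (σ = 0.5 s by default),
  then scaling to the maximum.
* **EMG** — 0.5–500 Hz Butterworth band-pass (the upper edge is clipped to
  0.45·fs when the sampling rate cannot support it), 60 Hz notch, min–max.
* **RESP** — 0.05 Hz high-pass (baseline) and 0.70 Hz low-pass (noise).

All filters are applied forward-backward by default so cleaning introduces
no net delay.  Cleaned recordings are cut into equal-length, overlapping,
phase-labelled windows by :func:`segment_record`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from drivestress.errors import EmptyInputError, InvalidSpecError

__all__ = [
    "ChannelSignal",
    "FilterSpec",
    "PhaseAnnotation",
    "MultiChannelRecording",
    "SegmentSet",
    "apply_filter",
    "clean_channel",
    "qrs_band",
    "minmax_normalize",
    "scale_to_maximum",
    "resample_channel",
    "segment_record",
    "PHASES",
    "PHASE_TO_LEVEL",
    "SCHEME_CLASSES",
    "phase_label",
]

#: Recognized drive phases.
PHASES = ("rest", "city", "highway")

#: Three-level stress mapping: rest → low, highway → medium, city → high.
PHASE_TO_LEVEL = {"rest": "low", "highway": "medium", "city": "high"}

#: Class names per labelling scheme, index = integer label.
SCHEME_CLASSES = {
    "two": ("relaxed", "stressed"),
    "three": ("low", "medium", "high"),
}

#: Band edges are clipped to this fraction of the sampling rate.
EDGE_CLIP_FRACTION = 0.45

FILTER_FAMILIES = (
    "butterworth-bandpass",
    "butterworth-highpass",
    "butterworth-lowpass",
    "fir-bandpass",
    "notch",
    "gaussian",
)


def phase_label(phase: str, scheme: str) -> int:
    """Integer stress label of a drive phase under a labelling scheme.

    ``scheme="three"``: rest → 0 (low), highway → 1 (medium), city → 2 (high).
    ``scheme="two"``: rest → 0 (relaxed), city/highway → 1 (stressed).
    """
    if scheme == "three":
        return {"rest": 0, "highway": 1, "city": 2}[phase]
    if scheme == "two":
        return 0 if phase == "rest" else 1
    raise ValueError(f"unknown labelling scheme {scheme!r}")


@dataclass
class ChannelSignal:
    """A single uniformly sampled physiological channel."""

    name: str
    samples: np.ndarray
    fs: float
    units: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError(f"channel {self.name!r}: samples must be 1-D")
        if self.samples.size == 0:
            raise EmptyInputError(f"channel {self.name!r} has no samples")
        if self.fs <= 0:
            raise ValueError(f"channel {self.name!r}: fs must be positive, got {self.fs}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class FilterSpec:
    """Declarative description of one filtering stage.

    ``edges`` are in Hz: (low, high) for band filters, a single cutoff for
    low/high-pass, and the stop-band bounds for the notch.  For the
    ``gaussian`` family ``edges`` is unused and ``sigma_s`` (seconds) sets the
    kernel width.  Any edge at or above ``EDGE_CLIP_FRACTION * fs`` is clipped
    with a warning; a band that collapses after clipping is an invalid spec.
    """

    family: str
    edges: tuple = ()
    order: int = 4
    zero_phase: bool = True
    sigma_s: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in FILTER_FAMILIES:
            raise InvalidSpecError(f"unknown filter family {self.family!r}")
        if self.order < 1:
            raise InvalidSpecError("filter order must be >= 1")
        self.edges = tuple(float(e) for e in np.atleast_1d(self.edges))

    def effective_edges(self, fs: float) -> tuple:
        """Edges after the Nyquist clipping rule, validated for rate *fs*."""
        limit = EDGE_CLIP_FRACTION * fs
        clipped = []
        for e in self.edges:
            if e <= 0:
                raise InvalidSpecError(f"{self.family}: non-positive edge {e} Hz")
            if e >= limit:
                warnings.warn(
                    f"{self.family}: edge {e} Hz clipped to {limit:.4g} Hz "
                    f"(0.45 x fs at fs={fs:g} Hz)",
                    stacklevel=3,
                )
                e = limit
            clipped.append(e)
        if len(clipped) == 2 and not clipped[0] < clipped[1]:
            raise InvalidSpecError(
                f"{self.family}: band ({self.edges[0]}, {self.edges[1]}) Hz collapsed "
                f"after clipping at fs={fs:g} Hz"
            )
        return tuple(clipped)


@dataclass
class PhaseAnnotation:
    """Ordered, non-overlapping drive-phase intervals with a labelling scheme."""

    intervals: list  # of (start_s, end_s, phase)
    label_scheme: str = "three"

    def __post_init__(self) -> None:
        if self.label_scheme not in SCHEME_CLASSES:
            raise ValueError(f"unknown labelling scheme {self.label_scheme!r}")
        ivals = []
        prev_end = -np.inf
        for start, end, phase in self.intervals:
            start, end = float(start), float(end)
            if phase not in PHASES:
                raise ValueError(f"unknown phase {phase!r}")
            if end <= start:
                raise ValueError(f"empty interval ({start}, {end})")
            if start < prev_end:
                raise ValueError("phase intervals overlap or are unordered")
            prev_end = end
            ivals.append((start, end, phase))
        if not ivals:
            raise EmptyInputError("annotation has no intervals")
        self.intervals = ivals

    @property
    def duration_s(self) -> float:
        return self.intervals[-1][1]

    @property
    def class_names(self) -> tuple:
        return SCHEME_CLASSES[self.label_scheme]

    def with_scheme(self, scheme: str) -> "PhaseAnnotation":
        return PhaseAnnotation(list(self.intervals), label_scheme=scheme)


@dataclass
class MultiChannelRecording:
    """Named channels with independent sampling rates plus phase annotations."""

    channels: dict  # name -> ChannelSignal
    annotation: PhaseAnnotation
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise EmptyInputError("recording has no channels")
        for name, ch in self.channels.items():
            if name != ch.name:
                raise ValueError(f"channel key {name!r} != channel name {ch.name!r}")

    @property
    def duration_s(self) -> float:
        return min(ch.duration_s for ch in self.channels.values())

    def channel_names(self) -> list:
        return sorted(self.channels)


@dataclass
class SegmentSet:
    """Equal-length labelled windows, shape ``(n_windows, n_samples, n_channels)``."""

    windows: np.ndarray
    labels: np.ndarray
    window_s: float
    overlap: float
    fs: float
    channel_names: tuple
    class_names: tuple

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.windows.ndim != 3:
            raise ValueError("windows must be (n, samples, channels)")
        if len(self.labels) != len(self.windows):
            raise ValueError("label count must equal window count")
        if len(self.labels) and not (
            (self.labels >= 0).all() and (self.labels < len(self.class_names)).all()
        ):
            raise ValueError("labels outside the active scheme")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def n_channels(self) -> int:
        return self.windows.shape[2]

    def subset(self, idx) -> "SegmentSet":
        return replace(self, windows=self.windows[idx], labels=self.labels[idx])

    def normalized(self) -> "SegmentSet":
        """Per-channel min–max rescaling over the whole window set.

        Brings channels stored in their native units onto a common [0, 1]
        scale before training; constant channels map to zero.
        """
        lo = self.windows.min(axis=(0, 1), keepdims=True)
        hi = self.windows.max(axis=(0, 1), keepdims=True)
        span = np.where(hi - lo > 0, hi - lo, 1.0)
        return replace(self, windows=(self.windows - lo) / span)


# ---------------------------------------------------------------------------
# filtering


def apply_filter(x: ChannelSignal, spec: FilterSpec) -> ChannelSignal:
    """Apply one filter stage, preserving length and sampling rate."""
    if len(x.samples) == 0:
        raise EmptyInputError(f"channel {x.name!r} is empty")
    y = _apply_to_array(x.samples, x.fs, spec)
    return replace(x, samples=y)


def _apply_to_array(data: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    if spec.family == "gaussian":
        return gaussian_filter1d(data, sigma=spec.sigma_s * fs, mode="nearest")

    edges = spec.effective_edges(fs)
    if spec.family == "fir-bandpass":
        numtaps = spec.order if spec.order % 2 == 1 else spec.order + 1
        b = sps.firwin(numtaps, edges, pass_zero=False, fs=fs)
        if spec.zero_phase:
            return sps.filtfilt(b, [1.0], data)
        return sps.lfilter(b, [1.0], data)

    btype = {
        "butterworth-bandpass": "bandpass",
        "butterworth-highpass": "highpass",
        "butterworth-lowpass": "lowpass",
        "notch": "bandstop",
    }[spec.family]
    wn = edges if len(edges) == 2 else edges[0]
    sos = sps.butter(spec.order, wn, btype=btype, fs=fs, output="sos")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, data)
    return sps.sosfilt(sos, data)


#: Per-modality cleaning chains.  Each entry is (stage-name, FilterSpec) or a
#: normalization marker resolved inside clean_channel.
def _chain_for(kind: str, gaussian_sigma_s: float) -> list:
    if kind in ("ecg", "hr"):
        return [
            ("notch 59-61 Hz", FilterSpec("notch", (59.0, 61.0), order=2)),
            # 1001 taps: at ECG rates the transition band must be well under
            # the 1.5 Hz low edge or baseline wander survives the chain
            ("FIR band-pass 1.5-150 Hz", FilterSpec("fir-bandpass", (1.5, 150.0), order=1001)),
            ("min-max normalization", "minmax"),
        ]
    if kind == "gsr":
        return [
            ("low-pass 4 Hz", FilterSpec("butterworth-lowpass", (4.0,), order=4)),
            ("Gaussian smoothing", FilterSpec("gaussian", sigma_s=gaussian_sigma_s)),
            ("scale to maximum", "scalemax"),
        ]
    if kind == "emg":
        return [
            ("band-pass 0.5-500 Hz", FilterSpec("butterworth-bandpass", (0.5, 500.0), order=4)),
            ("notch 59-61 Hz", FilterSpec("notch", (59.0, 61.0), order=2)),
            ("min-max normalization", "minmax"),
        ]
    if kind == "resp":
        return [
            ("high-pass 0.05 Hz", FilterSpec("butterworth-highpass", (0.05,), order=4)),
            ("low-pass 0.70 Hz", FilterSpec("butterworth-lowpass", (0.70,), order=4)),
        ]
    raise ValueError(f"unknown channel kind {kind!r}")


def clean_channel(x: ChannelSignal, kind: str, gaussian_sigma_s: float = 0.5) -> ChannelSignal:
    """Run the per-modality cleaning chain on one channel.

    Raises :class:`InvalidSpecError` naming the offending stage when the
    sampling rate is too low to realize a stage.
    """
    if len(x.samples) == 0:
        raise EmptyInputError(f"channel {x.name!r} is empty")
    y = x.samples
    for stage_name, stage in _chain_for(kind, gaussian_sigma_s):
        if stage == "minmax":
            y = minmax_normalize(y)
        elif stage == "scalemax":
            y = scale_to_maximum(y)
        else:
            try:
                y = _apply_to_array(y, x.fs, stage)
            except InvalidSpecError as err:
                raise InvalidSpecError(
                    f"channel {x.name!r} ({kind}): stage '{stage_name}' cannot be "
                    f"realized at fs={x.fs:g} Hz: {err}"
                ) from err
    return replace(x, samples=np.asarray(y, dtype=float))


def qrs_band(x: ChannelSignal, order: int = 4) -> ChannelSignal:
    """5–15 Hz Butterworth band-pass: the classic QRS-detection band of ECG."""
    return apply_filter(x, FilterSpec("butterworth-bandpass", (5.0, 15.0), order=order))


# ---------------------------------------------------------------------------
# normalization


def minmax_normalize(x) -> np.ndarray:
    """Affine map onto [0, 1]; a constant sequence maps to all zeros."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise EmptyInputError("cannot normalize an empty sequence")
    lo, hi = x.min(), x.max()
    if hi - lo == 0:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def scale_to_maximum(x) -> np.ndarray:
    """Divide by the maximum absolute value (GSR convention); zero stays zero."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise EmptyInputError("cannot scale an empty sequence")
    m = np.abs(x).max()
    return x / m if m > 0 else np.zeros_like(x)


def resample_channel(x: ChannelSignal, fs: float) -> ChannelSignal:
    """Linearly resample a channel onto a uniform grid at rate *fs*."""
    if len(x.samples) == 0:
        raise EmptyInputError(f"channel {x.name!r} is empty")
    if fs <= 0:
        raise ValueError("target rate must be positive")
    n_out = int(np.floor(x.duration_s * fs))
    t_out = np.arange(n_out) / fs
    y = np.interp(t_out, x.times(), x.samples)
    return replace(x, samples=y, fs=float(fs))


# ---------------------------------------------------------------------------
# segmentation


def segment_record(
    rec: MultiChannelRecording,
    window_s: float = 10.0,
    overlap: float = 0.5,
    ann: PhaseAnnotation | None = None,
    common_fs: float = 8.0,
) -> SegmentSet:
    """Cut a recording into equal-length labelled sliding windows.

    All channels are linearly resampled to ``common_fs`` and stacked (channel
    order is alphabetical, so labels never depend on channel ordering).  Each
    window takes the stress label of the phase covering the majority of its
    span; ties go to the earliest interval.  Windows extending past the
    annotated region are dropped.
    """
    if ann is None:
        ann = rec.annotation
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    if window_s <= 0:
        raise ValueError("window_s must be positive")

    duration = min(rec.duration_s, ann.duration_s)
    if window_s > duration:
        raise ValueError(
            f"window of {window_s:g} s is longer than the usable recording ({duration:g} s)"
        )

    names = rec.channel_names()
    res = [resample_channel(rec.channels[n], common_fs) for n in names]
    n = min(len(r.samples) for r in res)
    frames = np.stack([r.samples[:n] for r in res], axis=1)  # (N, C)

    w = int(round(window_s * common_fs))
    stride = max(1, int(round(w * (1.0 - overlap))))
    n_windows = (n - w) // stride + 1 if n >= w else 0
    if n_windows <= 0:
        raise ValueError("window longer than recording after resampling")

    windows, labels = [], []
    for i in range(n_windows):
        start = i * stride
        t0, t1 = start / common_fs, (start + w) / common_fs
        lab = _majority_label(t0, t1, ann)
        if lab is None:
            continue
        windows.append(frames[start : start + w])
        labels.append(lab)
    if not windows:
        raise EmptyInputError("no window overlaps the annotated region")

    return SegmentSet(
        windows=np.stack(windows),
        labels=np.asarray(labels, dtype=int),
        window_s=window_s,
        overlap=overlap,
        fs=common_fs,
        channel_names=tuple(names),
        class_names=ann.class_names,
    )


def _majority_label(t0: float, t1: float, ann: PhaseAnnotation):
    """Label of the phase covering most of [t0, t1); None when uncovered."""
    best_label, best_cover = None, 0.0
    for start, end, phase in ann.intervals:
        cover = min(t1, end) - max(t0, start)
        if cover > best_cover:  # strict: ties keep the earliest interval
            best_cover = cover
            best_label = phase_label(phase, ann.label_scheme)
    return best_label
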