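"""Synthetic driving-protocol recordings with stress-dependent physiology.

The generator emulates the structure of a real-world drive-protocol
experiment: two rest periods (15 min at full scale) bracketing
city → highway → city driving on a fixed route, with rest, highway, and
city phases assumed to trigger low, medium, and high stress.  Channels are
statistical stand-ins, not physiologically validated waveforms: their
contract is (i) realistic sampling rates, (ii) the standard noise taxonomy
(white noise, baseline wander, 60 Hz powerline interference) so cleaning
stages have something to remove, and (iii) a controllable stress-dependent
class separation so classifier tests have a tunable difficulty dial.

All randomness flows from a single seed; the same seed reproduces the same
recording bit for bit.  Values are rounded to fixed precision on write, so
stored cohorts are platform-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from drivestress.signals import (
    PHASE_TO_LEVEL,
    ChannelSignal,
    MultiChannelRecording,
    PhaseAnnotation,
)

__all__ = [
    "DriveProtocol",
    "ChannelModel",
    "default_channel_models",
    "phase_schedule",
    "generate_drive",
    "generate_cohort",
]

#: Full-scale phase plan (seconds): two 900 s rests bracketing
#: city → highway → city driving; 3000 s ≈ the short end of a real drive.
_FULL_SCALE_PLAN = (
    ("rest", 900.0),
    ("city", 300.0),
    ("highway", 600.0),
    ("city", 300.0),
    ("rest", 900.0),
)

_LEVELS = ("low", "medium", "high")


@dataclass(frozen=True)
class DriveProtocol:
    """Ordered (phase, duration) plan; must start and end with rest."""

    phases: tuple = _FULL_SCALE_PLAN
    scale: float = 1.0

    def __post_init__(self):
        if not self.phases:
            raise ValueError("protocol has no phases")
        if self.phases[0][0] != "rest" or self.phases[-1][0] != "rest":
            raise ValueError("protocol must start and end with a rest phase")
        for phase, dur in self.phases:
            if phase not in PHASE_TO_LEVEL:
                raise ValueError(f"unknown phase {phase!r}")
            if dur <= 0:
                raise ValueError("phase durations must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @classmethod
    def standard(cls, scale: float = 0.1) -> "DriveProtocol":
        """The default desk-scale protocol (scale 0.1 → 300 s total)."""
        return cls(phases=_FULL_SCALE_PLAN, scale=scale)

    @property
    def duration_s(self) -> float:
        return sum(d for _, d in self.phases) * self.scale


@dataclass
class ChannelModel:
    """Generative stand-in for one physiological channel.

    The signal is baseline + per-stress-level offset + oscillatory component
    + event process + noise terms (white, baseline wander, powerline).
    ``event_rate`` is a per-level Poisson rate (events/s) for phasic
    responses (GSR) or bursts (EMG); events are one-sided bumps with an
    exponential decay.
    """

    kind: str
    fs: float
    baseline: float = 0.0
    stress_offsets: dict = field(default_factory=lambda: {lv: 0.0 for lv in _LEVELS})
    osc_rate_hz: dict = field(default_factory=dict)  # per-level oscillation rate
    osc_amp: float = 0.0
    noise_sigma: float = 0.0
    wander_amp: float = 0.0
    wander_freq: float = 0.2
    powerline_amp: float = 0.0
    powerline_freq: float = 60.0
    event_rate: dict = field(default_factory=dict)  # per-level events/s
    event_amp: float = 0.0
    event_decay_s: float = 2.0
    units: str = ""

    def __post_init__(self):
        if self.kind not in ("ecg", "hr", "gsr", "emg", "resp"):
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if self.fs <= 0:
            raise ValueError(f"channel {self.kind!r}: fs must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")
        if any(r < 0 for r in self.event_rate.values()):
            raise ValueError("event rates must be nonnegative")


def default_channel_models() -> dict:
    """The stock five-channel inventory (ECG, HR, GSR, EMG, RESP)."""
    return {
        "hr": ChannelModel(
            kind="hr",
            fs=496.0,
            baseline=70.0,
            stress_offsets={"low": 0.0, "medium": 10.0, "high": 20.0},
            noise_sigma=5.0,
            wander_amp=1.0,
            wander_freq=0.05,
            units="bpm",
        ),
        "ecg": ChannelModel(
            kind="ecg",
            fs=496.0,
            baseline=0.0,
            stress_offsets={"low": 0.0, "medium": 0.0, "high": 0.0},
            noise_sigma=0.05,
            wander_amp=0.3,
            wander_freq=0.2,
            powerline_amp=0.2,
            units="mV",
        ),
        "gsr": ChannelModel(
            kind="gsr",
            fs=31.0,
            baseline=5.0,
            stress_offsets={"low": 0.0, "medium": 1.0, "high": 2.0},
            noise_sigma=0.05,
            wander_amp=0.2,
            wander_freq=0.01,
            event_rate={"low": 0.01, "medium": 0.05, "high": 0.1},
            event_amp=0.8,
            event_decay_s=2.0,
            units="uS",
        ),
        "emg": ChannelModel(
            kind="emg",
            fs=495.0,
            baseline=0.0,
            stress_offsets={"low": 0.0, "medium": 0.0, "high": 0.0},
            noise_sigma=0.02,
            powerline_amp=0.05,
            event_rate={"low": 0.02, "medium": 0.05, "high": 0.1},
            event_amp=0.5,
            event_decay_s=0.5,
            units="mV",
        ),
        "resp": ChannelModel(
            kind="resp",
            fs=31.0,
            baseline=0.0,
            stress_offsets={"low": 0.0, "medium": 0.0, "high": 0.0},
            osc_rate_hz={"low": 0.20, "medium": 0.25, "high": 0.30},
            osc_amp=1.0,
            noise_sigma=0.1,
            wander_amp=0.3,
            wander_freq=0.02,
            units="au",
        ),
    }


def phase_schedule(protocol: DriveProtocol, label_scheme: str = "three") -> PhaseAnnotation:
    """Contiguous phase intervals covering the whole (scaled) drive."""
    intervals = []
    t = 0.0
    for phase, dur in protocol.phases:
        d = dur * protocol.scale
        intervals.append((t, t + d, phase))
        t += d
    return PhaseAnnotation(intervals=intervals, label_scheme=label_scheme)


def _level_array(ann: PhaseAnnotation, times: np.ndarray) -> np.ndarray:
    """Per-sample stress-level index (0=low, 1=medium, 2=high)."""
    levels = np.zeros(len(times), dtype=int)
    for start, end, phase in ann.intervals:
        mask = (times >= start) & (times < end)
        levels[mask] = _LEVELS.index(PHASE_TO_LEVEL[phase])
    return levels


def _event_train(
    rng: np.random.Generator,
    times: np.ndarray,
    levels: np.ndarray,
    rates: dict,
    amp: float,
    decay_s: float,
    fs: float,
) -> np.ndarray:
    """Poisson event bumps with per-level rates and exponential decay."""
    out = np.zeros(len(times))
    if not rates or amp == 0:
        return out
    rate_per_sample = np.array([rates.get(lv, 0.0) for lv in _LEVELS])[levels] / fs
    onsets = np.flatnonzero(rng.random(len(times)) < rate_per_sample)
    if len(onsets) == 0:
        return out
    kernel_len = max(1, int(round(5 * decay_s * fs)))
    kernel = amp * np.exp(-np.arange(kernel_len) / (decay_s * fs))
    impulses = np.zeros(len(times) + kernel_len)
    impulses[onsets] = 1.0
    out = np.convolve(impulses, kernel)[: len(times)]
    return out


def _synthesize_channel(
    model: ChannelModel,
    ann: PhaseAnnotation,
    duration_s: float,
    rng: np.random.Generator,
    baseline_jitter: float = 0.0,
    noise_scale: float = 1.0,
    separation: float = 1.0,
) -> ChannelSignal:
    n = int(round(duration_s * model.fs))
    t = np.arange(n) / model.fs
    levels = _level_array(ann, t)

    offsets = np.array([model.stress_offsets.get(lv, 0.0) for lv in _LEVELS]) * separation
    x = np.full(n, model.baseline + baseline_jitter) + offsets[levels]

    if model.osc_amp and model.osc_rate_hz:
        # phase-continuous oscillation whose rate follows the stress level
        rate = np.array([model.osc_rate_hz.get(lv, 0.0) for lv in _LEVELS])[levels]
        phase = 2 * np.pi * np.cumsum(rate) / model.fs
        x = x + model.osc_amp * np.sin(phase)

    if model.kind == "ecg":
        # periodic pulse train tied to a stress-dependent heart rate;
        # no morphological realism claimed
        beat_hz = (70.0 + np.array([0.0, 10.0, 20.0])[levels] * separation) / 60.0
        phase = 2 * np.pi * np.cumsum(beat_hz) / model.fs
        x = x + np.exp(-((np.mod(phase, 2 * np.pi) - np.pi) ** 2) * 8.0)

    x = x + _event_train(
        rng, t, levels, model.event_rate, model.event_amp, model.event_decay_s, model.fs
    )
    if model.wander_amp:
        x = x + model.wander_amp * np.sin(2 * np.pi * model.wander_freq * t + rng.uniform(0, 2 * np.pi))
    if model.powerline_amp:
        x = x + model.powerline_amp * np.sin(2 * np.pi * model.powerline_freq * t)
    if model.noise_sigma:
        x = x + noise_scale * model.noise_sigma * rng.standard_normal(n)

    return ChannelSignal(name=model.kind, samples=x, fs=model.fs, units=model.units)


def generate_drive(
    protocol: DriveProtocol,
    channel_models: dict | None = None,
    seed: int = 0,
    label_scheme: str = "three",
    noise_scale: float = 1.0,
    separation: float = 1.0,
    baseline_jitter: dict | None = None,
) -> MultiChannelRecording:
    """One reproducible synthetic drive.

    ``noise_scale`` multiplies every white-noise σ; ``separation`` multiplies
    every stress-level offset — together they set the class separation the
    downstream classifier sees.
    """
    models = channel_models if channel_models is not None else default_channel_models()
    if not models:
        raise ValueError("no channel models given")
    ann = phase_schedule(protocol, label_scheme=label_scheme)
    duration = ann.duration_s

    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF])
    channels = {}
    jitter = baseline_jitter or {}
    for name, child in zip(sorted(models), ss.spawn(len(models))):
        model = models[name]
        sig = _synthesize_channel(
            model,
            ann,
            duration,
            np.random.default_rng(child),
            baseline_jitter=jitter.get(name, 0.0),
            noise_scale=noise_scale,
            separation=separation,
        )
        channels[name] = replace(sig, name=name)
    return MultiChannelRecording(
        channels=channels, annotation=ann, meta={"seed": int(seed), "scale": protocol.scale}
    )


def generate_cohort(
    n_drives: int,
    protocol: DriveProtocol | None = None,
    seed: int = 0,
    channel_models: dict | None = None,
    label_scheme: str = "three",
    noise_scale: float = 1.0,
    separation: float = 1.0,
    jitter_sigma: float = 1.0,
) -> list:
    """A list of drives with per-drive seeds and mild baseline jitter."""
    if n_drives < 1:
        raise ValueError("need at least one drive")
    protocol = protocol or DriveProtocol.standard()
    models = channel_models if channel_models is not None else default_channel_models()
    master = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xC0F0])
    rng = np.random.default_rng(master)
    drives = []
    for k in range(n_drives):
        drive_seed = int(rng.integers(0, 2**31 - 1))
        jitter = {name: float(rng.normal(0.0, jitter_sigma)) for name in sorted(models)}
        drives.append(
            generate_drive(
                protocol,
                channel_models=models,
                seed=drive_seed,
                label_scheme=label_scheme,
                noise_scale=noise_scale,
                separation=separation,
                baseline_jitter=jitter,
            )
        )
    return drives
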