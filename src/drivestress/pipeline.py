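"""End-to-end pipeline: synthesize → preprocess → train → evaluate → rank.

Configuration is plain YAML key-value with a strict schema — unknown keys
are errors, because silent typos are the dominant failure mode of pipeline
configs.  All randomness flows from the single top-level ``seed``.  Every
run emits exactly one JSON manifest carrying the fully resolved
configuration (defaults included), the package version, per-stage output
digests, and timing, so any output file is regenerable from the manifest
alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from drivestress import __version__, io, metrics, nets, signals, synth
from drivestress.errors import SchemaError

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "clean_recording", "segment_cohort"]

log = logging.getLogger("drivestress")

_KNOWN_KINDS = ("ecg", "hr", "gsr", "emg", "resp")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with explicit defaults."""

    out_dir: str
    seed: int = 0
    scheme: str = "two"
    window_s: float = 10.0
    overlap: float = 0.5
    common_fs: float = 8.0
    architecture: str = "cnn"
    profile: str = "srad"
    n_drives: int = 4
    scale: float = 0.1
    separation: float = 1.0
    clean: bool = True
    gaussian_sigma_s: float = 0.5
    input_dir: str | None = None
    epochs: int | None = None
    minibatch: int | None = None
    split: float = 0.8
    learning_rate: float = 1e-3
    validation_frequency: int = 10
    rank_class: str | None = None
    weights: list | None = None
    subsets: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        allowed = set(cls.__dataclass_fields__)
        unknown = set(raw) - allowed
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise SchemaError("config requires 'out_dir'")
        cfg = cls(**raw)
        if cfg.scheme not in signals.SCHEME_CLASSES:
            raise SchemaError(f"scheme must be one of {sorted(signals.SCHEME_CLASSES)}")
        if cfg.architecture not in ("cnn", "cnn_lstm"):
            raise SchemaError("architecture must be 'cnn' or 'cnn_lstm'")
        for sub in cfg.subsets:
            bad = set(sub) - {"name", "channels", "noise_scale", "separation"}
            if bad:
                raise SchemaError(f"unknown subset keys: {sorted(bad)}")
            if "name" not in sub:
                raise SchemaError("every subset needs a 'name'")
        return cfg


@dataclass
class RunManifest:
    """One manifest per pipeline run."""

    config: dict
    version: str
    stages: dict
    outputs: dict
    started: float
    finished: float

    def write(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)
        return path


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def kind_of_channel(name: str) -> str | None:
    """Map a channel name to its cleaning kind by prefix (gsr_hand → gsr)."""
    low = name.lower()
    for kind in _KNOWN_KINDS:
        if low == kind or low.startswith(kind + "_") or low.startswith(kind + "-"):
            return kind
    return None


def clean_recording(rec: signals.MultiChannelRecording, gaussian_sigma_s: float = 0.5):
    """Clean every channel whose name maps to a known modality."""
    cleaned = {}
    for name, ch in rec.channels.items():
        kind = kind_of_channel(name)
        if kind is None:
            log.info("channel %s: no cleaning chain, passed through", name)
            cleaned[name] = ch
        else:
            cleaned[name] = signals.clean_channel(ch, kind, gaussian_sigma_s=gaussian_sigma_s)
    return signals.MultiChannelRecording(channels=cleaned, annotation=rec.annotation, meta=rec.meta)


def segment_cohort(recordings, cfg: PipelineConfig, channels=None) -> signals.SegmentSet:
    """Clean, segment, and pool windows across a cohort of recordings."""
    pooled_windows, pooled_labels = [], []
    ref = None
    for rec in recordings:
        if channels:
            rec = signals.MultiChannelRecording(
                channels={n: rec.channels[n] for n in channels},
                annotation=rec.annotation,
                meta=rec.meta,
            )
        if cfg.clean:
            rec = clean_recording(rec, cfg.gaussian_sigma_s)
        seg = signals.segment_record(
            rec,
            window_s=cfg.window_s,
            overlap=cfg.overlap,
            ann=rec.annotation.with_scheme(cfg.scheme),
            common_fs=cfg.common_fs,
        )
        pooled_windows.append(seg.windows)
        pooled_labels.append(seg.labels)
        ref = seg
    return signals.SegmentSet(
        windows=np.concatenate(pooled_windows),
        labels=np.concatenate(pooled_labels),
        window_s=ref.window_s,
        overlap=ref.overlap,
        fs=ref.fs,
        channel_names=ref.channel_names,
        class_names=ref.class_names,
    )


def _training_options(cfg: PipelineConfig) -> nets.TrainingOptions:
    opts = nets.default_training_options(cfg.profile, seed=cfg.seed)
    if cfg.epochs is not None:
        opts.epochs = cfg.epochs
    if cfg.minibatch is not None:
        opts.minibatch = cfg.minibatch
    opts.split = cfg.split
    opts.learning_rate = cfg.learning_rate
    opts.validation_frequency = cfg.validation_frequency
    log.info("resolved training options: %s", opts)
    return opts


def run_pipeline(config) -> RunManifest:
    """Execute all stages in order; any stage failure aborts with its name."""
    if isinstance(config, (str, Path)):
        cfg = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        cfg = PipelineConfig.from_dict(config)
    else:
        cfg = config

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("resolved config: %s", asdict(cfg))

    started = time.time()
    stages: dict = {}
    outputs: dict = {}
    subsets = cfg.subsets or [{"name": "all"}]

    def run_stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as err:
            raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err
        stages[name] = {"seconds": round(time.time() - t0, 3)}
        return result

    # --- synth / load ------------------------------------------------------
    def stage_synth():
        if cfg.input_dir:
            return {None: [io.read_recording(cfg.input_dir)]}
        protocol = synth.DriveProtocol.standard(scale=cfg.scale)
        cohorts = {}
        for sub in subsets:
            cohorts[sub["name"]] = synth.generate_cohort(
                cfg.n_drives,
                protocol,
                seed=cfg.seed,
                noise_scale=float(sub.get("noise_scale", 1.0)),
                separation=float(sub.get("separation", cfg.separation)),
            )
        return cohorts

    cohorts = run_stage("synth", stage_synth)

    # --- preprocess --------------------------------------------------------
    def stage_preprocess():
        segs = {}
        for sub in subsets:
            recs = cohorts.get(sub["name"]) or next(iter(cohorts.values()))
            segs[sub["name"]] = segment_cohort(recs, cfg, channels=sub.get("channels"))
        return segs

    segments = run_stage("preprocess", stage_preprocess)

    # --- train -------------------------------------------------------------
    def stage_train():
        opts = _training_options(cfg)
        n_classes = len(signals.SCHEME_CLASSES[cfg.scheme])
        build = nets.build_cnn if cfg.architecture == "cnn" else nets.build_cnn_lstm
        spec = build(cfg.profile, n_classes)
        return {name: nets.train(spec, seg, opts) for name, seg in segments.items()}

    fitted = run_stage("train", stage_train)

    # --- evaluate ----------------------------------------------------------
    def stage_evaluate():
        rows, overall, per_subset = [], {}, {}
        for name, model in fitted.items():
            seg = segments[name]
            val = seg.subset(model.val_idx if len(model.val_idx) else model.train_idx)
            cm = metrics.confusion_matrix(val.labels, nets.predict(model, val), seg.class_names)
            io.write_confusion_matrix(cm, out / f"confusion_{name}.csv")
            outputs[f"confusion_{name}.csv"] = _digest(out / f"confusion_{name}.csv")
            per_class = metrics.all_class_metrics(cm)
            overall[name] = metrics.overall_accuracy(cm)
            per_subset[name] = per_class
            for cls, row in per_class.items():
                rows.append((name, cls, row))
        io.write_metrics_table(rows, out / "metrics.csv", overall=overall)
        outputs["metrics.csv"] = _digest(out / "metrics.csv")
        return per_subset

    per_subset_metrics = run_stage("evaluate", stage_evaluate)

    # --- rank --------------------------------------------------------------
    def stage_rank():
        from drivestress.edas import run_edas

        rank_class = cfg.rank_class or signals.SCHEME_CLASSES[cfg.scheme][0]
        rows = []
        for name, per_class in per_subset_metrics.items():
            row = per_class[rank_class]
            if not row.is_complete():
                log.warning("subset %s: incomplete metrics for %r; skipped in ranking",
                            name, rank_class)
                continue
            rows.append((name, row))
        if not rows:
            log.warning("no complete metric rows; ranking skipped")
            return None
        dm = metrics.decision_matrix_from_metrics(rows, weights=cfg.weights)
        result = run_edas(dm)
        io.write_edas_result(result, out / "edas")
        for f in sorted((out / "edas").iterdir()):
            outputs[f"edas/{f.name}"] = _digest(f)
        return result

    run_stage("rank", stage_rank)

    manifest = RunManifest(
        config=asdict(cfg),
        version=__version__,
        stages=stages,
        outputs=outputs,
        started=started,
        finished=time.time(),
    )
    manifest.write(out / "manifest.json")
    return manifest
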