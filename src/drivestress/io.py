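"""Delimited-text readers and writers for recordings, metrics, and rankings.

On-disk layout of a recording directory::

    <dir>/
      channels/<name>.csv     # header "time_s,value", one row per sample
      phases.csv              # header "start_s,end_s,phase"
      recording.json          # per-channel fs/units plus free-form metadata

Sample values are stored at fixed precision (9 significant digits) so a
written cohort is platform-independent.  Decision matrices travel as CSV
with a header row of criterion names and a leading ``__weights__`` row.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from drivestress.edas import DecisionMatrix, EdasResult
from drivestress.errors import SchemaError
from drivestress.metrics import METRIC_NAMES, ConfusionMatrix, MetricsRow
from drivestress.signals import ChannelSignal, MultiChannelRecording, PhaseAnnotation

__all__ = [
    "write_recording",
    "read_recording",
    "write_decision_matrix",
    "read_decision_matrix",
    "write_metrics_table",
    "write_confusion_matrix",
    "write_edas_result",
]

_WEIGHTS_ROW = "__weights__"


# ---------------------------------------------------------------------------
# recordings


def write_recording(rec: MultiChannelRecording, out_dir) -> Path:
    out = Path(out_dir)
    (out / "channels").mkdir(parents=True, exist_ok=True)
    meta = {"channels": {}, "label_scheme": rec.annotation.label_scheme, "meta": rec.meta}
    for name in rec.channel_names():
        ch = rec.channels[name]
        meta["channels"][name] = {"fs": ch.fs, "units": ch.units}
        with open(out / "channels" / f"{name}.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_s", "value"])
            for t, v in zip(ch.times(), ch.samples):
                w.writerow([f"{t:.6f}", f"{v:.9g}"])
    with open(out / "phases.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["start_s", "end_s", "phase"])
        for start, end, phase in rec.annotation.intervals:
            w.writerow([f"{start:.6f}", f"{end:.6f}", phase])
    with open(out / "recording.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return out


def _read_channel_file(path: Path, name: str, fs: float | None, units: str) -> ChannelSignal:
    times, values = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["time_s", "value"]:
            raise SchemaError(f"{path}: expected header 'time_s,value'")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                times.append(float(row[0]))
                values.append(float(row[1]))
            except (IndexError, ValueError) as err:
                raise SchemaError(f"{path}:{lineno}: malformed row {row!r}") from err
    if not values:
        raise SchemaError(f"{path}: channel file has no samples")
    if fs is None:
        if len(times) < 2:
            raise SchemaError(f"{path}: cannot infer fs from a single sample")
        fs = 1.0 / float(np.median(np.diff(times)))
    return ChannelSignal(name=name, samples=np.asarray(values), fs=float(fs), units=units)


def read_recording(in_dir) -> MultiChannelRecording:
    """Load a recording directory; errors carry file names and line numbers."""
    root = Path(in_dir)
    chan_dir = root / "channels"
    files = sorted(chan_dir.glob("*.csv")) if chan_dir.is_dir() else sorted(root.glob("*.csv"))
    files = [f for f in files if f.name != "phases.csv"]
    if not files:
        raise SchemaError(f"{root}: no channel files found")

    phases_path = root / "phases.csv"
    if not phases_path.exists():
        raise SchemaError(f"{root}: missing annotation file phases.csv")

    meta: dict = {"channels": {}, "label_scheme": "three", "meta": {}}
    meta_path = root / "recording.json"
    if meta_path.exists():
        with open(meta_path) as fh:
            meta.update(json.load(fh))

    channels = {}
    for f in files:
        name = f.stem
        info = meta["channels"].get(name, {})
        channels[name] = _read_channel_file(f, name, info.get("fs"), info.get("units", ""))

    intervals = []
    with open(phases_path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader, None)  # header
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                intervals.append((float(row[0]), float(row[1]), row[2].strip()))
            except (IndexError, ValueError) as err:
                raise SchemaError(f"{phases_path}:{lineno}: malformed row {row!r}") from err
    ann = PhaseAnnotation(intervals=intervals, label_scheme=meta["label_scheme"])
    return MultiChannelRecording(channels=channels, annotation=ann, meta=meta.get("meta", {}))


# ---------------------------------------------------------------------------
# decision matrices and tables


def write_decision_matrix(dm: DecisionMatrix, path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["alternative", *dm.criteria])
        w.writerow([_WEIGHTS_ROW, *[f"{x:.6g}" for x in dm.weights]])
        for name, row in zip(dm.names, dm.x):
            w.writerow([name, *[f"{x:.6g}" for x in row]])
    return path


def read_decision_matrix(path, beneficial=None) -> DecisionMatrix:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if not header or header[0] != "alternative":
            raise SchemaError(f"{path}: expected header starting with 'alternative'")
        criteria = tuple(h.strip() for h in header[1:])
        weights = None
        names, rows = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                values = [float(v) for v in row[1:]]
            except ValueError as err:
                raise SchemaError(f"{path}:{lineno}: malformed row {row!r}") from err
            if len(values) != len(criteria):
                raise SchemaError(f"{path}:{lineno}: expected {len(criteria)} values")
            if row[0] == _WEIGHTS_ROW:
                weights = values
            else:
                names.append(row[0])
                rows.append(values)
    if weights is None:
        raise SchemaError(f"{path}: missing '{_WEIGHTS_ROW}' row")
    if not rows:
        raise SchemaError(f"{path}: no alternatives")
    ben = np.ones(len(criteria), bool) if beneficial is None else np.asarray(beneficial, bool)
    return DecisionMatrix(
        x=np.asarray(rows), weights=np.asarray(weights), beneficial=ben,
        names=tuple(names), criteria=criteria,
    )


def write_metrics_table(rows, path, overall: dict | None = None) -> Path:
    """Write (model, class, MetricsRow) triples as a delimited table."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["model", "class", *METRIC_NAMES, "overall_acc"])
        for model, cls, row in rows:
            vals = ["" if v is None else f"{v:.6f}" for v in row.as_tuple()]
            ov = "" if overall is None or model not in overall else f"{overall[model]:.6f}"
            w.writerow([model, cls, *vals, ov])
    return path


def write_confusion_matrix(cm: ConfusionMatrix, path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["true\\pred", *cm.class_names])
        for name, row in zip(cm.class_names, cm.counts):
            w.writerow([name, *[int(v) for v in row]])
    return path


def write_edas_result(result: EdasResult, out_dir) -> Path:
    """Export the full chain: per-step delimited tables plus a JSON audit."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def table(path, header, rows):
        with open(out / path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            for row in rows:
                w.writerow(row)

    fmt = "{:.6f}".format
    table("average_solution.csv", ["criterion", "psi"],
          [[c, fmt(v)] for c, v in zip(result.criteria, result.psi)])
    for name, mat in (("positive_distance.csv", result.pi), ("negative_distance.csv", result.ni)):
        table(name, ["alternative", *result.criteria],
              [[a, *map(fmt, row)] for a, row in zip(result.names, mat)])
    table(
        "scores.csv",
        ["alternative", "SPI", "SNI", "NSPI", "NSNI", "appraisal", "rank"],
        [
            [a, fmt(result.spi[i]), fmt(result.sni[i]), fmt(result.nspi[i]),
             fmt(result.nsni[i]), fmt(result.lam[i]), int(result.ranks[i])]
            for i, a in enumerate(result.names)
        ],
    )
    with open(out / "edas_audit.json", "w") as fh:
        json.dump(result.to_dict(), fh, indent=1)
    return out
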