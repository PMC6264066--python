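"""Readers, writers and run configuration.

File formats:

* accelerometer CSV — header ``t,ax,ay,az``; ``t`` in seconds, axes in g
  (or m/s² with ``units="ms2"``, converted on read);
* cohort manifest CSV — ``participant_id,group,pair_id,snap_score`` plus one
  ``<site>_csv`` path column per sensor site;
* image stacks — compressed ``.npz`` array container with a JSON sidecar
  manifest (participant, site, per-image center timestamps, label);
* reports — CSV tables plus a JSON summary carrying the config snapshot and
  seed needed to re-run the experiment bit-identically;
* run configuration — YAML mirroring the config dataclass field names.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cnn import ModelSpec, TrainConfig
from .imaging import ImageStack
from .signal_core import STANDARD_GRAVITY, AccelSeries, ProcessingConfig
from .subject_inference import FrameConfig
from .synthetic import SimConfig

__all__ = [
    "RunConfig",
    "read_accel_csv",
    "write_accel_csv",
    "read_manifest",
    "write_manifest",
    "save_image_stack",
    "load_image_stack",
    "export_png",
    "write_report",
]

_ACCEL_COLUMNS = ["t", "ax", "ay", "az"]


@dataclass
class RunConfig:
    """Bundle of all stage configurations for one pipeline run."""

    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    frames: FrameConfig = field(default_factory=FrameConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    simulation: SimConfig = field(default_factory=SimConfig)
    school_hours: tuple[float, float] = (9.0, 15.0)   # wall-clock hours
    site: str = "wrist"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["school_hours"] = list(self.school_hours)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for name, sub in (
            ("processing", ProcessingConfig), ("frames", FrameConfig),
            ("training", TrainConfig), ("model", ModelSpec), ("simulation", SimConfig),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                sub_kwargs = dict(kwargs[name])
                for k, v in sub_kwargs.items():
                    if isinstance(v, list):
                        sub_kwargs[k] = tuple(v)
                kwargs[name] = sub(**sub_kwargs)
        if "school_hours" in kwargs:
            kwargs["school_hours"] = tuple(kwargs["school_hours"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance records."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_accel_csv(path, participant_id: str, sensor_site: str,
                   sample_rate_hz: float = 10.0, units: str = "g") -> AccelSeries:
    """Read one sensor recording (``t,ax,ay,az``) into an :class:`AccelSeries`.

    ``units`` is ``"g"`` (native) or ``"ms2"`` (divided by 9.80665 on read).
    Malformed rows raise with the offending line number.
    """
    if units not in ("g", "ms2"):
        raise ValueError("units must be 'g' or 'ms2'")
    df = pd.read_csv(path)
    missing = [c for c in _ACCEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    numeric = df[_ACCEL_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise ValueError(f"{path}: malformed row at line {line}")
    a = numeric[["ax", "ay", "az"]].to_numpy(dtype=np.float64)
    if units == "ms2":
        a = a / STANDARD_GRAVITY
    return AccelSeries(
        participant_id=participant_id,
        sensor_site=sensor_site,
        sample_rate_hz=sample_rate_hz,
        t=numeric["t"].to_numpy(dtype=np.float64),
        a=a,
    )


def write_accel_csv(series: AccelSeries, path) -> None:
    df = pd.DataFrame({
        "t": series.t,
        "ax": series.a[:, 0], "ay": series.a[:, 1], "az": series.a[:, 2],
    })
    df.to_csv(path, index=False, float_format="%.9g")


def write_manifest(cohort, directory, sites: tuple[str, ...] = ("wrist", "ankle")) -> Path:
    """Write a simulated cohort to CSV recordings plus a manifest.

    Produces ``<participant>_<site>.csv`` per recording and ``manifest.csv``
    linking participants to files, groups, pairs and SNAP scores.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.participants:
        row = {"participant_id": p.participant_id, "group": p.group,
               "pair_id": p.pair_id, "snap_score": p.snap_score}
        for site in sites:
            if site not in p.series:
                continue
            fname = f"{p.participant_id}_{site}.csv"
            write_accel_csv(p.series[site], directory / fname)
            row[f"{site}_csv"] = fname
        rows.append(row)
    path = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_manifest(path, sample_rate_hz: float = 10.0, units: str = "g"):
    """Load a cohort manifest and its referenced recordings.

    Returns a list of objects with the attributes ``encode_cohort`` expects
    (participant_id, group, pair_id, snap_score, series dict).
    """
    from .synthetic import SimParticipant

    path = Path(path)
    df = pd.read_csv(path)
    site_cols = [c for c in df.columns if c.endswith("_csv")]
    participants = []
    for _, row in df.iterrows():
        series = {}
        for col in site_cols:
            if pd.isna(row[col]):
                continue
            site = col[: -len("_csv")]
            series[site] = read_accel_csv(
                path.parent / row[col], participant_id=str(row["participant_id"]),
                sensor_site=site, sample_rate_hz=sample_rate_hz, units=units,
            )
        participants.append(SimParticipant(
            participant_id=str(row["participant_id"]),
            group=str(row["group"]),
            pair_id=str(row["pair_id"]),
            snap_score=float(row["snap_score"]),
            series=series,
        ))
    return participants


def save_image_stack(stack: ImageStack, path) -> None:
    """Serialize a stack as ``.npz`` plus a ``.json`` sidecar manifest."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"),
                        pixels=stack.pixels,
                        center_index=stack.center_index,
                        t_center=stack.t_center)
    sidecar = {
        "participant_id": stack.participant_id,
        "sensor_site": stack.sensor_site,
        "label": stack.label,
        "counts": stack.counts,
        "n_images": int(len(stack)),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_image_stack(path) -> ImageStack:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return ImageStack(
        pixels=arrays["pixels"],
        center_index=arrays["center_index"],
        t_center=arrays["t_center"],
        participant_id=meta["participant_id"],
        sensor_site=meta["sensor_site"],
        label=meta["label"],
        counts=meta["counts"],
    )


def export_png(image_pixels: np.ndarray, path) -> None:
    """Write one binary acceleration image as a 28×28 0/255 PNG."""
    from PIL import Image

    arr = (np.asarray(image_pixels, dtype=np.uint8) * 255).clip(0, 255)
    Image.fromarray(arr, mode="L").save(path)


def _write_score_table(report, path) -> None:
    """Per-participant score table: cl, decision and the th=1..n positive-
    fraction vector (participants with fewer images than one frame get NaNs)."""
    from .subject_inference import threshold_sweep

    n = 20
    eligible = {pid: labels for pid, labels in report.image_labels.items()
                if len(labels) >= n}
    sweep = threshold_sweep(eligible, n=n) if eligible else {}
    rows = []
    site = report.config.get("site", "")
    for _, r in report.predictions.iterrows():
        pid = r["participant_id"]
        row = {"participant_id": pid, "site": site, "n_images": r["n_images"],
               "cl": r["cl"], "predicted": r["predicted"]}
        if "true" in r:
            row["true"] = r["true"]
        fracs = sweep.get(pid)
        for th in range(1, n + 1):
            row[f"frac_th{th}"] = float(fracs[th - 1]) if fracs is not None else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_report(report, directory, run_config: RunConfig | None = None) -> Path:
    """Write an :class:`~kinemap.evaluation.EvaluationReport` to disk.

    Emits ``predictions.csv``, optional ``sweep_p_values.csv``, and
    ``summary.json`` with metrics, seed and config snapshot — enough to
    reproduce the run bit-identically.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    report.predictions.to_csv(directory / "predictions.csv", index=False)
    if report.sweep_p_values is not None:
        report.sweep_p_values.to_csv(directory / "sweep_p_values.csv", index=False)
    if report.image_labels and "cl" in report.predictions.columns:
        _write_score_table(report, directory / "score_table.csv")
    summary = {
        "schema": report.schema,
        "seed": report.seed,
        "config": report.config,
        "metrics": report.metrics.as_dict() if report.metrics else None,
        "fold_metrics": [m.as_dict() for m in report.fold_metrics]
        if report.fold_metrics else None,
    }
    if run_config is not None:
        summary["run_config"] = run_config.to_dict()
        summary["config_digest"] = run_config.digest()
        run_config.to_yaml(directory / "config.yaml")
    (directory / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return directory / "summary.json"
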