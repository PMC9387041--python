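"""File formats: hypnogram/activity CSV, model JSON, cohort manifests,
and report serialization.

Hypnogram CSV: columns ``epoch_index`` (0-based, 30-s grid) and ``stage``
(W|N1|N2|N3|R, legacy tokens accepted); ``# lights_off = <ISO-8601>`` and
``# lights_on = <ISO-8601>`` header comment lines carry the anchors.
Activity CSV: columns ``epoch_index`` (0-based, 2-min grid) and ``count``
(integer 0-31), with a ``# start = <ISO-8601>`` header.  Epoch intervals
are half-open [t, t + delta).
"""

from __future__ import annotations

import csv
import json
import math
from datetime import datetime
from pathlib import Path
from typing import Union

import pandas as pd

from .epochs import ActivitySeries, Hypnogram30, EPOCH_30S, EPOCH_2MIN, normalize_stage
from .errors import ParseError, ValidationError
from .scoring import BUILTIN_MODELS, DiscriminantModel, SWSeries
from .validation import ValidationReport

PathLike = Union[str, Path]


def _read_header_meta(path: Path) -> dict[str, str]:
    """Parse ``# key = value`` comment lines at the top of a CSV file."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            for sep in ("=", ":"):
                if sep in body:
                    key, _, value = body.partition(sep)
                    meta[key.strip()] = value.strip()
                    break
    return meta


def _parse_timestamp(meta: dict[str, str], key: str, path: Path) -> datetime:
    if key not in meta:
        raise ParseError(f"{path}: missing '# {key} = <ISO-8601>' header")
    try:
        return datetime.fromisoformat(meta[key])
    except ValueError as exc:
        raise ParseError(f"{path}: bad {key} timestamp {meta[key]!r}") from exc


def _read_indexed_csv(path: Path, value_col: str) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, comment="#", dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: unreadable CSV ({exc})") from exc
    for col in ("epoch_index", value_col):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    idx = pd.to_numeric(frame["epoch_index"], errors="coerce")
    if idx.isna().any() or not (idx == range(len(frame))).all():
        bad = int(idx.isna().idxmax() if idx.isna().any() else (idx != range(len(frame))).idxmax())
        raise ParseError(
            f"{path}: epoch_index must be contiguous 0-based integers (row {bad})"
        )
    return frame


def read_hypnogram(path: PathLike) -> Hypnogram30:
    """Read a 30-s hypnogram CSV with lights-off/on header metadata."""
    path = Path(path)
    meta = _read_header_meta(path)
    lights_off = _parse_timestamp(meta, "lights_off", path)
    lights_on = _parse_timestamp(meta, "lights_on", path)
    frame = _read_indexed_csv(path, "stage")
    stages = []
    for row, token in enumerate(frame["stage"]):
        try:
            stages.append(normalize_stage(token))
        except ValidationError as exc:
            raise ParseError(f"{path}: row {row}: {exc}") from exc
    try:
        return Hypnogram30(
            stages=tuple(stages), lights_off=lights_off, lights_on=lights_on
        )
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_hypnogram(h: Hypnogram30, path: PathLike) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# lights_off = {h.lights_off.isoformat()}\n")
        fh.write(f"# lights_on = {h.lights_on.isoformat()}\n")
        writer = csv.writer(fh)
        writer.writerow(["epoch_index", "stage"])
        for i, stage in enumerate(h.stages):
            writer.writerow([i, stage])


def read_activity(path: PathLike) -> ActivitySeries:
    """Read a 2-min activity-count CSV (integers 0-31) with start header."""
    path = Path(path)
    meta = _read_header_meta(path)
    start = _parse_timestamp(meta, "start", path)
    frame = _read_indexed_csv(path, "count")
    counts = []
    for row, token in enumerate(frame["count"]):
        value = pd.to_numeric(pd.Series([token]), errors="coerce").iloc[0]
        if pd.isna(value) or float(value) != int(value):
            raise ParseError(f"{path}: row {row}: non-integer count {token!r}")
        counts.append(int(value))
    try:
        return ActivitySeries(counts=tuple(counts), start=start)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_activity(a: ActivitySeries, path: PathLike) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# start = {a.start.isoformat()}\n")
        writer = csv.writer(fh)
        writer.writerow(["epoch_index", "count"])
        for i, count in enumerate(a.counts):
            writer.writerow([i, count])


def read_model(spec: PathLike) -> DiscriminantModel:
    """Load a discriminant model from JSON, or ``builtin:<name>``."""
    text = str(spec)
    if text.startswith("builtin:"):
        name = text.split(":", 1)[1]
        if name not in BUILTIN_MODELS:
            raise ValidationError(
                f"unknown built-in model {name!r}; available: {sorted(BUILTIN_MODELS)}"
            )
        return BUILTIN_MODELS[name]
    path = Path(spec)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"{path}: cannot read model JSON ({exc})") from exc
    return DiscriminantModel.from_dict(data)


def write_model(model: DiscriminantModel, path: PathLike) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def write_scored(
    sw: SWSeries, activity: ActivitySeries, path: PathLike
) -> None:
    """Scored-epoch CSV: epoch_index, count, z, label."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# model = {sw.model_label}\n")
        fh.write(f"# edge_policy = {sw.edge_policy}\n")
        writer = csv.writer(fh)
        writer.writerow(["epoch_index", "count", "z", "label"])
        for i, (count, z, label) in enumerate(zip(activity.counts, sw.scores, sw.labels)):
            writer.writerow([i, count, repr(z), label])


def write_report(
    report: ValidationReport, path: PathLike, fmt: str = "json"
) -> None:
    """Serialize a validation report; JSON round-trips exactly."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    elif fmt == "csv":
        flat = report.to_dict()
        by_stage = flat.pop("agreement_by_stage")
        for stage, value in by_stage.items():
            flat[f"agreement_{stage}_pct"] = value
        pd.DataFrame([flat]).to_csv(path, index=False)
    else:
        raise ValidationError(f"unknown report format {fmt!r}")


def read_report(path: PathLike) -> ValidationReport:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"{path}: cannot read report JSON ({exc})") from exc
    return ValidationReport.from_dict(data)


def read_manifest(path: PathLike) -> pd.DataFrame:
    """Read a cohort manifest CSV.

    Required columns: subject_id, hypnogram, activity; optional: age,
    group.  Relative paths are resolved against the manifest directory;
    referenced files must exist and subject ids must be unique.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#", dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: unreadable manifest ({exc})") from exc
    for col in ("subject_id", "hypnogram", "activity"):
        if col not in frame.columns:
            raise ParseError(f"{path}: manifest missing column {col!r}")
    if frame["subject_id"].duplicated().any():
        dup = frame.loc[frame["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ParseError(f"{path}: duplicate subject_id {dup!r}")
    base = path.parent
    for col in ("hypnogram", "activity"):
        frame[col] = [
            str((base / p) if not Path(p).is_absolute() else Path(p))
            for p in frame[col]
        ]
        for p in frame[col]:
            if not Path(p).exists():
                raise ParseError(f"{path}: referenced file does not exist: {p}")
    if "age" in frame.columns:
        frame["age"] = pd.to_numeric(frame["age"], errors="coerce")
    return frame


def load_cohort(
    manifest: Union[PathLike, pd.DataFrame],
) -> list[tuple[str, Hypnogram30, ActivitySeries]]:
    """Load every subject referenced by a manifest."""
    frame = manifest if isinstance(manifest, pd.DataFrame) else read_manifest(manifest)
    return [
        (row.subject_id, read_hypnogram(row.hypnogram), read_activity(row.activity))
        for row in frame.itertuples()
    ]
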