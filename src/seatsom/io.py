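"""Frame and dataset file formats.

A frame file is plain CSV: 32 rows of 32 comma-separated non-negative
numbers, full printed precision (lossless round-trip). A dataset directory
holds one ``frame_NNNNN.csv`` per frame plus a ``manifest.csv`` sidecar with
columns ``file,label,subject_id,weight_kg`` (empty fields for absent
metadata). Feature matrices travel as headerless CSV, one 256-element vector
per row. All indices in files are 0-based.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .sensor import POSTURE_CLASSES, PressureFrame

__all__ = [
    "read_frame",
    "write_frame",
    "read_dataset",
    "write_dataset",
    "read_features",
    "write_features",
]


def write_frame(frame: PressureFrame, path) -> None:
    """Write one frame as 32x32 CSV at full precision."""
    rows, cols = frame.shape
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for r in range(rows):
            writer.writerow([repr(float(v)) for v in frame.values[r]])


def read_frame(path, rows: int = 32, cols: int = 32) -> PressureFrame:
    """Read one frame, validating shape and non-negativity cell by cell."""
    path = Path(path)
    data = []
    with open(path, newline="") as fh:
        for r, row in enumerate(csv.reader(fh)):
            if not row:
                continue
            if len(row) != cols:
                raise ValueError(
                    f"{path}: row {r} has {len(row)} fields, expected {cols}")
            parsed = []
            for c, cell in enumerate(row):
                try:
                    v = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell at (row {r}, col {c}): {cell!r}"
                    ) from None
                if v < 0:
                    raise ValueError(
                        f"{path}: negative pressure at (row {r}, col {c}): {v}")
                parsed.append(v)
            data.append(parsed)
    if len(data) != rows:
        raise ValueError(f"{path}: expected {rows} rows, found {len(data)}")
    return PressureFrame(np.asarray(data, dtype=float))


def write_dataset(frames: Sequence[PressureFrame], out_dir) -> None:
    """Write frames plus a ``manifest.csv`` sidecar into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file", "label", "subject_id", "weight_kg"])
        for i, frame in enumerate(frames):
            name = f"frame_{i:05d}.csv"
            write_frame(frame, out_dir / name)
            writer.writerow([
                name,
                frame.label or "",
                frame.subject_id or "",
                repr(frame.weight_kg) if frame.weight_kg is not None else "",
            ])


def read_dataset(in_dir) -> list[PressureFrame]:
    """Read a dataset directory written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    manifest = in_dir / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv in {in_dir}")
    frames = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            frame = read_frame(in_dir / row["file"])
            label = row.get("label") or None
            if label is not None and label not in POSTURE_CLASSES:
                raise ValueError(f"{manifest}: unknown label {label!r}")
            frame.label = label
            frame.subject_id = row.get("subject_id") or None
            weight = row.get("weight_kg") or None
            frame.weight_kg = float(weight) if weight else None
            frames.append(frame)
    return frames


def write_features(features: np.ndarray, path,
                   labels: Optional[Sequence[str]] = None) -> None:
    """Write feature vectors (one CSV row each); labels go in a sidecar
    ``<path>.labels.csv`` when given."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for row in features:
            writer.writerow([repr(float(v)) for v in row])
    if labels is not None:
        with open(str(path) + ".labels.csv", "w", newline="") as fh:
            csv.writer(fh).writerows([[lab] for lab in labels])


def read_features(path) -> np.ndarray:
    """Read a feature-vector CSV back into an ``(n, dim)`` array."""
    with open(path, newline="") as fh:
        rows = [[float(c) for c in row] for row in csv.reader(fh) if row]
    if not rows:
        raise ValueError(f"{path}: no feature rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: inconsistent row lengths {sorted(widths)}")
    return np.asarray(rows, dtype=float)
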