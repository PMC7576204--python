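"""Reading, writing and highlight export of trajectory datasets.

A dataset is a directory of per-trajectory CSV files (columns ``t,x,y`` plus
any extra sensor channels, comma-separated, UTF-8, '.' decimal) described by a
YAML manifest::

    coordinates: planar          # or geographic (x = lon, y = lat)
    channels: [speed, angular_speed]   # feature channels selected for training
    trajectories:
      - {file: A0000.csv, id: A0000, label: A}
      - ...

Highlight export colors each point by its attention value with a linear
yellow (255,255,0) -> red (255,0,0) map over that trajectory's own attention
range; a trajectory with constant attention renders entirely yellow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError

__all__ = [
    "Trajectory",
    "DatasetManifest",
    "read_dataset",
    "write_dataset",
    "attention_colors",
    "export_highlight",
]


@dataclass
class Trajectory:
    """A timestamped planar track with optional extra sensor channels."""

    id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    extras: dict = field(default_factory=dict)
    label: str = ""

    def __len__(self) -> int:
        return len(self.t)

    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def validate(self) -> None:
        n = len(self.t)
        if n < 2:
            raise ValidationError(f"trajectory {self.id}: needs at least 2 points")
        for name, arr in (("x", self.x), ("y", self.y), *self.extras.items()):
            if len(arr) != n:
                raise ValidationError(f"trajectory {self.id}: channel {name!r} length mismatch")
        if not np.all(np.diff(self.t) > 0):
            raise ValidationError(f"trajectory {self.id}: timestamps not strictly increasing")


@dataclass
class DatasetManifest:
    path: Path
    coordinates: str  # "planar" | "geographic"
    channels: list
    entries: list  # of dicts {file, id, label}

    def validate(self) -> None:
        if self.coordinates not in ("planar", "geographic"):
            raise ValidationError(f"unknown coordinate kind {self.coordinates!r}")
        labels = {e["label"] for e in self.entries}
        if len(labels) != 2:
            raise ValidationError(f"dataset must contain exactly two class labels, got {sorted(labels)}")


def load_manifest(manifest_path: str | Path) -> DatasetManifest:
    manifest_path = Path(manifest_path)
    with open(manifest_path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    man = DatasetManifest(
        path=manifest_path,
        coordinates=doc.get("coordinates", "planar"),
        channels=doc.get("channels", []),
        entries=doc["trajectories"],
    )
    man.validate()
    return man


def read_dataset(manifest_path: str | Path) -> list[Trajectory]:
    """Load and validate all trajectories listed in a manifest.

    Rows with non-numeric coordinates are dropped; non-monotone timestamps or
    fewer than two classes raise :class:`ValidationError`.
    """
    man = load_manifest(manifest_path)
    base = man.path.parent
    out: list[Trajectory] = []
    for entry in man.entries:
        fp = base / entry["file"]
        if not fp.exists():
            raise FileNotFoundError(f"trajectory file missing: {fp}")
        df = pd.read_csv(fp)
        for col in ("t", "x", "y"):
            if col not in df.columns:
                raise ValidationError(f"{fp}: required column {col!r} missing")
            df[col] = pd.to_numeric(df[col], errors="coerce")
        df = df.dropna(subset=["t", "x", "y"])
        extras = {c: df[c].to_numpy(dtype=float) for c in df.columns if c not in ("t", "x", "y")}
        traj = Trajectory(
            id=str(entry.get("id", fp.stem)),
            t=df["t"].to_numpy(dtype=float),
            x=df["x"].to_numpy(dtype=float),
            y=df["y"].to_numpy(dtype=float),
            extras=extras,
            label=str(entry["label"]),
        )
        traj.validate()
        out.append(traj)
    return out


def write_dataset(trajectories: list[Trajectory], out_dir: str | Path,
                  coordinates: str = "planar", channels: list | None = None) -> Path:
    """Write one CSV per trajectory plus ``manifest.yaml``; returns its path."""
    labels = {tr.label for tr in trajectories}
    if len(labels) != 2:
        raise ValidationError(f"dataset must contain exactly two class labels, got {sorted(labels)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for traj in trajectories:
        traj.validate()
        fname = f"{traj.id}.csv"
        cols = {"t": traj.t, "x": traj.x, "y": traj.y, **traj.extras}
        pd.DataFrame(cols).to_csv(out_dir / fname, index=False, float_format="%.12g")
        entries.append({"file": fname, "id": traj.id, "label": traj.label})
    doc = {
        "coordinates": coordinates,
        "channels": channels or [],
        "trajectories": entries,
    }
    manifest = out_dir / "manifest.yaml"
    with open(manifest, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return manifest


def attention_colors(attention: np.ndarray) -> np.ndarray:
    """Map attention to 8-bit RGB, yellow (low) -> red (high), per trajectory.

    Normalization is min-max over this trajectory's attention; a constant
    vector maps to yellow.  Only the green channel varies (affine in the
    normalized attention).
    """
    a = np.asarray(attention, dtype=float)
    lo, hi = a.min(), a.max()
    norm = np.zeros_like(a) if hi == lo else (a - lo) / (hi - lo)
    rgb = np.empty((len(a), 3), dtype=int)
    rgb[:, 0] = 255
    rgb[:, 1] = np.rint(255 * (1.0 - norm)).astype(int)
    rgb[:, 2] = 0
    return rgb


def export_highlight(traj: Trajectory, attention: np.ndarray, out_path: str | Path,
                     out_format: str = "csv", coordinates: str = "planar",
                     predicted_class: str | None = None) -> Path:
    """Export a trajectory colored by attention as CSV or GeoJSON.

    ``attention`` must have one value per trajectory point.  GeoJSON output
    (one LineString feature per consecutive point pair, RFC 7946 lon/lat
    order) is only valid for geographic coordinates.
    """
    attention = np.asarray(attention, dtype=float)
    if len(attention) != len(traj):
        raise ValidationError(
            f"attention length {len(attention)} != trajectory length {len(traj)}")
    out_path = Path(out_path)
    rgb = attention_colors(attention)
    if out_format == "csv":
        df = pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y, **traj.extras})
        df["attention"] = attention
        df["r"], df["g"], df["b"] = rgb[:, 0], rgb[:, 1], rgb[:, 2]
        if predicted_class is not None:
            df["predicted_class"] = predicted_class
        df.to_csv(out_path, index=False, float_format="%.12g")
        return out_path
    if out_format == "geojson":
        if coordinates != "geographic":
            raise ValidationError("GeoJSON export requires geographic coordinates (x=lon, y=lat)")
        features = []
        for i in range(len(traj) - 1):
            color = "#{:02x}{:02x}{:02x}".format(*rgb[i + 1])
            props = {"attention": float(attention[i + 1]), "stroke": color, "t": float(traj.t[i + 1])}
            if predicted_class is not None:
                props["predicted_class"] = predicted_class
            features.append({
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[float(traj.x[i]), float(traj.y[i])],
                                    [float(traj.x[i + 1]), float(traj.y[i + 1])]],
                },
                "properties": props,
            })
        doc = {"type": "FeatureCollection", "features": features}
        with open(out_path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
        return out_path
    raise ValidationError(f"unknown export format {out_format!r}")
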