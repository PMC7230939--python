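"""Readers, writers and run configuration for the μOS pipeline.

The native track table is a CSV with columns
``track_id,frame,t_h,x_um,y_um,size`` (and an optional ``parent_id``
for fission children); units are hours and µm as the column names say.
Exports from the ImageJ Manual Tracking plugin (``Track n°``,
``Slice n°``, ``X``, ``Y`` in pixels and frames) can be imported by
passing the pixel size and frame interval explicitly — the recordings
carry no calibration of their own.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .geometry import DeviceGeometry
from .metrics import ClusterTrack, MigrationSummary
from .disaggregation import FissionEvent, TimelineBin
from .transport import AxialProfile, ConcentrationField

__all__ = [
    "TrackSchemaError",
    "read_tracks",
    "write_tracks",
    "tracks_to_frame",
    "tracks_from_frame",
    "write_summary",
    "write_timeline",
    "write_events",
    "write_profile",
    "read_profile",
    "write_field",
    "write_geometry_config",
    "read_geometry_config",
    "RunConfig",
    "file_sha256",
    "write_manifest",
]

NATIVE_COLUMNS = ["track_id", "frame", "t_h", "x_um", "y_um", "size"]
FLOAT_FORMAT = "%.6f"


class TrackSchemaError(ValueError):
    """A track table does not match the expected schema."""


# ----------------------------------------------------------------------
# track tables
# ----------------------------------------------------------------------

def tracks_to_frame(tracks: Sequence[ClusterTrack],
                    frame_interval_h: float = 1.0) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for k in range(tr.n_points):
            rows.append({
                "track_id": tr.track_id,
                "frame": int(round(tr.t[k] / frame_interval_h)),
                "t_h": float(tr.t[k]),
                "x_um": float(tr.x[k]),
                "y_um": float(tr.y[k]),
                "size": int(tr.size[k]),
                "parent_id": tr.parent_id if tr.parent_id is not None else "",
            })
    return pd.DataFrame(rows, columns=NATIVE_COLUMNS + ["parent_id"])


def tracks_from_frame(df: pd.DataFrame) -> list[ClusterTrack]:
    tracks = []
    has_parent = "parent_id" in df.columns
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("t_h")
        parent = None
        if has_parent:
            raw = g["parent_id"].iloc[0]
            if pd.notna(raw) and str(raw) != "":
                parent = str(raw)
        tracks.append(ClusterTrack(
            track_id=str(tid),
            t=g["t_h"].to_numpy(dtype=float),
            x=g["x_um"].to_numpy(dtype=float),
            y=g["y_um"].to_numpy(dtype=float),
            size=g["size"].to_numpy(dtype=int),
            parent_id=parent,
        ))
    return tracks


def write_tracks(tracks: Sequence[ClusterTrack], path: str | Path) -> None:
    """Write tracks as the native CSV dialect (units in the header names)."""
    df = tracks_to_frame(tracks)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _validate_numeric(df: pd.DataFrame, columns: Sequence[str], path: str | Path) -> pd.DataFrame:
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
            raise TrackSchemaError(
                f"{path}: malformed value {df[col][bad].iloc[0]!r} in column "
                f"{col!r} at line {line}"
            )
        if converted.isna().any():
            line = int(np.flatnonzero(converted.isna().to_numpy())[0]) + 2
            raise TrackSchemaError(f"{path}: missing value in column {col!r} at line {line}")
        df[col] = converted
    return df


def read_tracks(path: str | Path, dialect: str = "native",
                pixel_size_um: Optional[float] = None,
                frame_interval_h: Optional[float] = None,
                default_size: int = 1) -> list[ClusterTrack]:
    """Read a track table.

    ``dialect="native"`` expects the package's own schema.
    ``dialect="imagej"`` maps Manual Tracking exports and requires
    explicit ``pixel_size_um`` and ``frame_interval_h`` (the plugin
    writes uncalibrated pixels and frame numbers); cluster sizes are
    not recorded there, so ``default_size`` is assigned.
    """
    path = Path(path)
    if dialect == "native":
        df = pd.read_csv(path, dtype={"track_id": str, "parent_id": str})
        missing = [c for c in NATIVE_COLUMNS if c not in df.columns]
        if missing:
            raise TrackSchemaError(f"{path}: missing required column(s) {missing}")
        df = _validate_numeric(df, ["frame", "t_h", "x_um", "y_um", "size"], path)
        return tracks_from_frame(df)
    if dialect == "imagej":
        if pixel_size_um is None or frame_interval_h is None:
            raise ValueError(
                "ImageJ import needs explicit pixel_size_um and frame_interval_h"
            )
        df = pd.read_csv(path)
        colmap = {}
        for want, keys in (("track_id", ("track",)), ("frame", ("slice",)),
                           ("x_px", ("x",)), ("y_px", ("y",))):
            match = [c for c in df.columns if str(c).strip().lower().startswith(keys)]
            if not match:
                raise TrackSchemaError(f"{path}: no column matching {keys[0]!r}")
            colmap[want] = match[0]
        out = pd.DataFrame({
            "track_id": df[colmap["track_id"]].astype(str),
            "frame": df[colmap["frame"]],
            "x_um": df[colmap["x_px"]] * pixel_size_um,
            "y_um": df[colmap["y_px"]] * pixel_size_um,
        })
        out = _validate_numeric(out, ["frame", "x_um", "y_um"], path)
        out["t_h"] = (out["frame"] - out["frame"].min()) * frame_interval_h
        out["size"] = int(default_size)
        return tracks_from_frame(out)
    raise ValueError(f"unknown dialect {dialect!r}")


# ----------------------------------------------------------------------
# analysis outputs
# ----------------------------------------------------------------------

def write_summary(summary: MigrationSummary, path: str | Path) -> None:
    """Per-class migration summary CSV (lengths in µm, DR dimensionless)."""
    summary.to_csv(path, index_label="size_class", float_format=FLOAT_FORMAT)


def write_timeline(bins: Sequence[TimelineBin], path: str | Path) -> None:
    df = pd.DataFrame({
        "t_h": [b.t for b in bins],
        "fraction_small": [b.fraction_small for b in bins],
        "n_motile": [b.n_motile for b in bins],
    })
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_events(events: Sequence[FissionEvent], path: str | Path) -> None:
    df = pd.DataFrame({
        "parent_id": [e.parent_track_id for e in events],
        "t_h": [e.t for e in events],
        "x_um": [e.position[0] for e in events],
        "y_um": [e.position[1] for e in events],
        "parent_size": [e.parent_size for e in events],
        "child_sizes": ["+".join(str(s) for s in e.child_sizes) for e in events],
    })
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_profile(profile: AxialProfile, path: str | Path) -> None:
    pd.DataFrame({"x_um": profile.x, "c_norm": profile.c}).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


def read_profile(path: str | Path) -> AxialProfile:
    df = pd.read_csv(path)
    return AxialProfile(x=df["x_um"].to_numpy(), c=df["c_norm"].to_numpy())


def write_field(field: ConcentrationField, path: str | Path) -> None:
    """Plain-matrix text raster plus a JSON sidecar with grid metadata."""
    path = Path(path)
    np.savetxt(path, field.values, fmt="%.8e")
    meta = {
        "dx_um": field.mask.dx,
        "shape": list(field.mask.shape),
        "origin": "EID outer wall, cell-centered",
        "normalization": "C/C0",
        "params": {
            "D_um2_per_s": field.params.D,
            "C0_ng_per_mL": field.params.C0,
            "QL_uL_per_min": field.params.QL,
            "QR_uL_per_min": field.params.QR,
            "flow_ratio_R": field.params.R,
            "pe_alpha": field.params.pe_alpha,
            "bc_mode": field.params.bc_mode,
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True))


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

def write_geometry_config(geometry: DeviceGeometry, path: str | Path) -> None:
    """Flat key:value YAML of the device dimensions, all lengths in µm."""
    Path(path).write_text(yaml.safe_dump(geometry.to_dict(), sort_keys=True))


def read_geometry_config(path: str | Path) -> DeviceGeometry:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return DeviceGeometry.from_dict(data)


@dataclass
class RunConfig:
    """Top-level pipeline configuration.

    Sections mirror the pipeline stages; missing sections fall back to
    the study-condition defaults.  The seed feeds every random stage.
    """

    geometry: dict = dc_field(default_factory=dict)
    transport: dict = dc_field(default_factory=dict)
    generator: dict = dc_field(default_factory=dict)
    analysis: dict = dc_field(default_factory=dict)
    seed: int = 0
    dx_um: float = 1.0
    out_dir: str = "muos_run"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(paths: Sequence[str | Path], out_path: str | Path,
                   extra: Optional[dict] = None) -> dict:
    """Checksum manifest of run artifacts; identical runs give identical manifests."""
    manifest = {
        "artifacts": {Path(p).name: file_sha256(p) for p in sorted(map(str, paths))},
    }
    if extra:
        manifest.update(extra)
    Path(out_path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
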