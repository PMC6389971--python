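"""Recording readers/writers and run configuration.

The canonical interchange format is a plain CSV with columns
``t, ax, ay, az, gx, gy, gz, ecg, lvp, seg_len`` plus a JSON sidecar
(``<file>.json``) holding the sampling rate, labels and, for synthetic
recordings, ground-truth end-systolic values.  A bit-compatible binary
container (``.npz``) with identical field names is offered for speed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .simulate import (
    DEFAULT_PROTOCOL,
    Geometry,
    NoiseConfig,
    SubjectRecording,
)

__all__ = [
    "CSV_COLUMNS",
    "RunConfig",
    "GeometrySpec",
    "NoiseSpec",
    "load_config",
    "write_recording",
    "read_recording",
    "write_r_peaks",
    "read_r_peaks",
]

CSV_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "ecg", "lvp", "seg_len"]
_MANDATORY = ["t", "ax", "ay", "az", "ecg"]


# ---------------------------------------------------------------------------
# configuration schema (unknown keys rejected)
# ---------------------------------------------------------------------------

class GeometrySpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    inclination_deg: float = 90.0
    gravity_mag: float = 9.81
    artifact_sign: int = 1

    def build(self) -> Geometry:
        return Geometry(**self.model_dump())


class NoiseSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    acc_sd: float = 0.05
    gyro_sd: float = 0.005
    gyro_bias: float = 0.002
    ecg_sd: float = 0.0
    lvp_sd: float = 0.2
    seg_len_sd: float = 0.002

    def build(self) -> NoiseConfig:
        return NoiseConfig(**self.model_dump())


class RunConfig(BaseModel):
    """Validated end-to-end pipeline configuration."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "cardimu_out"
    # simulation protocol (used when no input recordings are given)
    n_subjects: int = Field(default=11, ge=1)
    n_cycles: int = Field(default=10, ge=3)
    fs: float = Field(default=700.0, gt=0)
    protocol: Optional[dict[str, int]] = None
    re_sd_scale: float = Field(default=1.0, ge=0)
    geometry: GeometrySpec = GeometrySpec()
    noise: NoiseSpec = NoiseSpec()
    # analysis switches
    methods: list[Literal["STAc", "DYNc", "ROT"]] = ["STAc", "DYNc", "ROT"]
    projections: list[Literal["circumferential", "3D"]] = ["circumferential", "3D"]
    spec_target: float = Field(default=0.8, gt=0, lt=1)
    # analyse existing recordings instead of simulating
    input_paths: Optional[list[str]] = None

    def protocol_counts(self) -> dict[str, int]:
        return dict(self.protocol) if self.protocol is not None else dict(DEFAULT_PROTOCOL)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_recording(rec: SubjectRecording, path: str | Path, sidecar: bool = True) -> Path:
    """Write a recording as CSV (or ``.npz`` binary) plus a JSON sidecar."""
    path = Path(path)
    n = rec.n_samples
    t = np.arange(n) / rec.fs
    nan = np.full(n, np.nan)
    gyro = rec.gyro if rec.gyro is not None else np.full((3, n), np.nan)
    cols = {
        "t": t,
        "ax": rec.acc[0], "ay": rec.acc[1], "az": rec.acc[2],
        "gx": gyro[0], "gy": gyro[1], "gz": gyro[2],
        "ecg": rec.ecg,
        "lvp": rec.lvp if rec.lvp is not None else nan,
        "seg_len": rec.seg_len if rec.seg_len is not None else nan,
    }
    if path.suffix == ".npz":
        np.savez_compressed(path, **cols)
    else:
        # 17 significant digits: float64 round-trips exactly through text
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    if sidecar:
        meta = {
            "fs": rec.fs,
            "subject_id": rec.subject_id,
            "intervention": rec.intervention,
            "r_peaks": None if rec.r_peaks is None else [int(i) for i in rec.r_peaks],
        }
        if rec.ground_truth is not None:
            gt = rec.ground_truth
            meta["ground_truth"] = {
                "rot_esm_deg": gt.rot_esm_deg,
                "disp_esm_mm": [float(v) for v in gt.disp_esm_mm],
                "es_time_s": gt.es_time_s,
                "es_sample_offset": int(gt.es_sample_offset),
            }
        with open(_sidecar_path(path), "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
    return path


def _columns_from_file(path: Path) -> dict[str, np.ndarray]:
    if path.suffix == ".npz":
        with np.load(path) as z:
            return {k: np.asarray(z[k], dtype=float) for k in z.files}
    df = pd.read_csv(path)
    return {c: df[c].to_numpy(dtype=float) for c in df.columns}


def read_recording(path: str | Path, fs: float | None = None) -> SubjectRecording:
    """Read a recording written by :func:`write_recording` (CSV or npz).

    Columns are matched by name, so column order is irrelevant.  Optional
    channels (gyro, lvp, seg_len) may be absent or all-NaN; the sampling
    rate comes from the sidecar, the ``fs`` argument, or the time column,
    in that order of precedence.
    """
    path = Path(path)
    cols = _columns_from_file(path)
    missing = [c for c in _MANDATORY if c not in cols]
    if missing:
        raise ValueError(f"recording {path} lacks mandatory columns: {missing}")
    t = cols["t"]
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("time column must be strictly increasing")

    meta = {}
    sc = _sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            meta = json.load(fh)
    if "fs" in meta:
        fs_val = float(meta["fs"])
    elif fs is not None:
        fs_val = float(fs)
    elif t.size > 1:
        fs_val = float(1.0 / np.median(np.diff(t)))
    else:
        raise ValueError("cannot determine sampling rate")

    def optional(name_triplet):
        arrs = [cols.get(c) for c in name_triplet]
        if any(a is None for a in arrs):
            return None
        stacked = np.vstack(arrs)
        return None if np.all(np.isnan(stacked)) else stacked

    def optional1(name):
        a = cols.get(name)
        return None if a is None or np.all(np.isnan(a)) else a

    r_peaks = meta.get("r_peaks")
    return SubjectRecording(
        subject_id=meta.get("subject_id", path.stem),
        intervention=meta.get("intervention", "unknown"),
        fs=fs_val,
        acc=np.vstack([cols["ax"], cols["ay"], cols["az"]]),
        gyro=optional(("gx", "gy", "gz")),
        ecg=cols["ecg"],
        lvp=optional1("lvp"),
        seg_len=optional1("seg_len"),
        r_peaks=None if r_peaks is None else np.asarray(r_peaks, dtype=int),
        ground_truth=None,
    )


def write_r_peaks(r_peaks: np.ndarray, path: str | Path) -> Path:
    """Export R-peak indices as a single-column integer CSV."""
    path = Path(path)
    pd.DataFrame({"r_peak": np.asarray(r_peaks, dtype=int)}).to_csv(path, index=False)
    return path


def read_r_peaks(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    if "r_peak" not in df.columns:
        raise ValueError("r-peak CSV must have a 'r_peak' column")
    return df["r_peak"].to_numpy(dtype=int)
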