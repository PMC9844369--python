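"""Recording container and plain-text IO for the stepping pipeline.

A recording is one block of the stepping exercise: 7 joint-angle channels
(degrees, relative to the static anatomical position), the vertical foot
and hip positions (metres), and the metadata that places the block in the
experimental design.  Recordings travel as a TSV with a fixed header plus a
YAML (or JSON) metadata file; the schema is deliberately plain text so the
whole pipeline is testable without proprietary motion-capture exports.

TSV columns::

    time_s, hip_flex, hip_abd, hip_rot, knee_flex, ankle_dorsi, ankle_inv,
    ankle_rot, foot_z, hip_z

Metadata keys::

    participant, step_height_m, block, fs_hz, thigh_l_m, shank_l_m
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

ANGLE_COLUMNS = [
    "hip_flex",
    "hip_abd",
    "hip_rot",
    "knee_flex",
    "ankle_dorsi",
    "ankle_inv",
    "ankle_rot",
]
TSV_COLUMNS = ["time_s", *ANGLE_COLUMNS, "foot_z", "hip_z"]
METADATA_KEYS = ["participant", "step_height_m", "block", "fs_hz", "thigh_l_m", "shank_l_m"]

MEASURES_KEY = ["participant", "step_height", "block", "analysis", "measure"]


class IngestError(ValueError):
    """Raised when a recording file fails validation; names the offending field."""


@dataclass
class Recording:
    """One block of raw stepping kinematics plus metadata."""

    participant_id: str
    step_height_m: float
    block: int  # 1-based within step-height condition
    fs_hz: float
    angles_deg: np.ndarray  # frames x 7, ANGLE_COLUMNS order
    foot_z_m: np.ndarray
    hip_z_m: np.ndarray
    thigh_l_m: float
    shank_l_m: float

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.foot_z_m = np.asarray(self.foot_z_m, dtype=float)
        self.hip_z_m = np.asarray(self.hip_z_m, dtype=float)
        n = self.angles_deg.shape[0]
        if self.angles_deg.ndim != 2 or self.angles_deg.shape[1] != len(ANGLE_COLUMNS):
            raise IngestError("angles_deg must be frames x 7")
        if self.foot_z_m.shape != (n,) or self.hip_z_m.shape != (n,):
            raise IngestError("channel length mismatch: foot_z/hip_z vs angles")
        if self.fs_hz <= 0:
            raise IngestError("fs_hz must be > 0")
        if self.step_height_m < 0:
            raise IngestError("step_height_m must be >= 0")
        for name in ("thigh_l_m", "shank_l_m"):
            if getattr(self, name) <= 0:
                raise IngestError(f"{name} must be > 0")
        if np.isnan(self.angles_deg).any() or np.isnan(self.foot_z_m).any() or np.isnan(self.hip_z_m).any():
            raise IngestError("missing frames present after ingest")

    @property
    def n_frames(self) -> int:
        return self.angles_deg.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.angles_deg[:, ANGLE_COLUMNS.index(name)]


def write_recording(rec: Recording, path: str | Path, metadata_path: str | Path) -> None:
    """Write a recording to the TSV + metadata schema (lossless to ~1e-9)."""
    path = Path(path)
    t = np.arange(rec.n_frames) / rec.fs_hz
    df = pd.DataFrame(
        np.column_stack([t, rec.angles_deg, rec.foot_z_m, rec.hip_z_m]), columns=TSV_COLUMNS
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    meta = {
        "participant": rec.participant_id,
        "step_height_m": float(rec.step_height_m),
        "block": int(rec.block),
        "fs_hz": float(rec.fs_hz),
        "thigh_l_m": float(rec.thigh_l_m),
        "shank_l_m": float(rec.shank_l_m),
    }
    mp = Path(metadata_path)
    if mp.suffix == ".json":
        mp.write_text(json.dumps(meta, indent=1))
    else:
        mp.write_text(yaml.safe_dump(meta))


def read_recording(path: str | Path, metadata_path: str | Path) -> Recording:
    """Read and validate a recording from the TSV + metadata schema."""
    path = Path(path)
    mp = Path(metadata_path)
    if not path.exists():
        raise IngestError(f"recording file not found: {path}")
    if not mp.exists():
        raise IngestError(f"metadata file not found: {mp}")
    meta = json.loads(mp.read_text()) if mp.suffix == ".json" else yaml.safe_load(mp.read_text())
    missing_meta = [k for k in METADATA_KEYS if k not in meta]
    if missing_meta:
        raise IngestError(f"metadata missing fields: {', '.join(missing_meta)}")

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise IngestError(f"recording missing columns: {', '.join(missing)}")
    bad = df[TSV_COLUMNS].isna().any(axis=1)
    if bad.any():
        raise IngestError(
            f"recording has {int(bad.sum())} frames with missing values "
            f"(first at row {int(np.flatnonzero(bad.to_numpy())[0])})"
        )
    return Recording(
        participant_id=str(meta["participant"]),
        step_height_m=float(meta["step_height_m"]),
        block=int(meta["block"]),
        fs_hz=float(meta["fs_hz"]),
        angles_deg=df[ANGLE_COLUMNS].to_numpy(float),
        foot_z_m=df["foot_z"].to_numpy(float),
        hip_z_m=df["hip_z"].to_numpy(float),
        thigh_l_m=float(meta["thigh_l_m"]),
        shank_l_m=float(meta["shank_l_m"]),
    )


def write_measures_table(rows: list[dict], path: str | Path | None = None) -> pd.DataFrame:
    """Assemble a tidy long-format measures table.

    Each row is keyed by (participant, step_height, block, analysis,
    measure) and carries a numeric ``value``.  Duplicate keys are an error.
    Returns the DataFrame; writes CSV when ``path`` is given.
    """
    df = pd.DataFrame(rows, columns=[*MEASURES_KEY, "value"])
    if len(df):
        dup = df.duplicated(subset=MEASURES_KEY)
        if dup.any():
            first = df.loc[dup.idxmax(), MEASURES_KEY].tolist()
            raise ValueError(f"duplicate measure key: {first}")
        df = df.sort_values(MEASURES_KEY, kind="stable").reset_index(drop=True)
    if path is not None:
        df.to_csv(path, index=False, float_format="%.12g")
    return df


def read_measures_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Every tunable of the pipeline, serialisable to/from YAML."""

    # filtering
    filter_cutoff_hz: float = 6.0
    filter_order: int = 4
    # segmentation
    peak_window_frames: int = 200
    onset_baseline_frames: int = 10
    onset_sd_multiplier: float = 10.0
    # RQA
    rqa_radius_frac: float = 0.10
    rqa_lmin: int = 2
    rqa_max_delay: int = 40
    rqa_max_dim: int = 12
    # task space
    ellipse_coverage: float = 0.85
    tnc_half_width_deg: float = 40.0
    tnc_step_deg: float = 0.5
    # trial dynamics
    trialdyn_alpha: float = 0.05
    trialdyn_min_segment: int = 5
    trialdyn_permutations: int = 199
    # stats
    stats_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.filter_cutoff_hz:
            raise ValueError("filter_cutoff_hz must be > 0")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if not 0 < self.rqa_radius_frac <= 1:
            raise ValueError("rqa_radius_frac must be in (0, 1]")
        if self.rqa_lmin < 2:
            raise ValueError("rqa_lmin must be >= 2")
        if not 0 < self.ellipse_coverage < 1:
            raise ValueError("ellipse_coverage must be in (0, 1)")
        for a in (self.trialdyn_alpha, self.stats_alpha):
            if not 0 < a < 1:
                raise ValueError("alpha values must be in (0, 1)")
        if self.trialdyn_min_segment < 2:
            raise ValueError("trialdyn_min_segment must be >= 2")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
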