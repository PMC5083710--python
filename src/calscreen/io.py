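"""Readers and writers binding the pipeline stages together.

Conventions: comma-separated UTF-8 CSV with a header row and '.'
decimals; multi-page 16-bit grayscale TIFF with the page index as the
time axis; models and reports as JSON; run configuration as YAML.
Every text artifact opens with '#'-prefixed provenance lines (package
version, seed, config hash) so outputs can be traced to the
configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .classify import DecisionTreeModel
from .synth import PhenotypeClass
from .traces import TraceSeries

__all__ = [
    "RunConfig",
    "config_hash",
    "load_config",
    "save_config",
    "write_traces_csv",
    "read_traces_csv",
    "write_labels_csv",
    "read_labels_csv",
    "write_features_csv",
    "read_features_csv",
    "write_stack",
    "read_stack",
    "write_model",
    "read_model",
    "write_rois_csv",
    "write_json_report",
]


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Configuration of a pipeline run; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "calscreen-out"
    log_level: str = "INFO"
    # generator
    n_wells_per_dose: int = 4
    atp_doses: list[float] = field(default_factory=lambda: [0.0, 1.0, 10.0, 100.0, 1000.0])
    cells_per_well: list[int] = field(default_factory=lambda: [100, 500])
    noise_frac: float = 0.05
    jitter: float = 0.10
    write_images: bool = False
    # segmentation
    min_area: int = 30
    max_area: int = 2000
    initial_threshold_quantile: float = 0.85
    threshold_step: float = 10.0
    max_iterations: int = 25
    # features
    sampling_rate: float = 2.0
    # classifier
    k_folds: int = 10
    min_leaf: int = 2
    train_per_class: list[int] = field(default_factory=lambda: [333, 536, 840])

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**d)


def config_hash(config: RunConfig) -> str:
    """Short stable hash of a configuration (for provenance headers)."""
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must hold a YAML mapping")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Provenance-aware CSV


def _provenance_lines(seed: int | None, cfg_hash: str | None) -> str:
    parts = [f"# calscreen {__version__}"]
    if seed is not None:
        parts.append(f"# seed: {seed}")
    if cfg_hash is not None:
        parts.append(f"# config: {cfg_hash}")
    return "\n".join(parts) + "\n"


def _write_csv(df: pd.DataFrame, path: str | Path, seed=None, cfg_hash=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance_lines(seed, cfg_hash))
        df.to_csv(fh, index=False)


def _read_csv(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps written float64 values bit-identical
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_traces_csv(traces: list[TraceSeries], path: str | Path, *, seed=None, cfg_hash=None) -> None:
    """Long-format trace table: well_id, cell_id, frame_index, time_s,
    fluorescence."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "well_id": tr.well_id,
                    "cell_id": tr.cell_id,
                    "frame_index": np.arange(tr.n_frames),
                    "time_s": tr.time,
                    "fluorescence": tr.values,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["well_id", "cell_id", "frame_index", "time_s", "fluorescence"]
    )
    _write_csv(df, path, seed, cfg_hash)


def read_traces_csv(path: str | Path, sampling_rate: float | None = None) -> list[TraceSeries]:
    df = _read_csv(path)
    out: list[TraceSeries] = []
    for (well, cell), grp in df.groupby(["well_id", "cell_id"], sort=True):
        grp = grp.sort_values("frame_index")
        if sampling_rate is None:
            dt = np.diff(grp["time_s"].to_numpy())
            rate = 1.0 / float(np.median(dt)) if dt.size and np.median(dt) > 0 else 2.0
        else:
            rate = sampling_rate
        out.append(TraceSeries(str(well), int(cell), grp["fluorescence"].to_numpy(), rate))
    return out


def write_labels_csv(rows: list[tuple[str, int, PhenotypeClass | str]], path, *, seed=None, cfg_hash=None) -> None:
    df = pd.DataFrame(
        [
            (w, c, l.value if isinstance(l, PhenotypeClass) else str(l))
            for w, c, l in rows
        ],
        columns=["well_id", "cell_id", "class"],
    )
    _write_csv(df, path, seed, cfg_hash)


def read_labels_csv(path: str | Path) -> pd.DataFrame:
    return _read_csv(path)


def write_features_csv(features: pd.DataFrame, path, *, seed=None, cfg_hash=None) -> None:
    _write_csv(features, path, seed, cfg_hash)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    return _read_csv(path)


def write_rois_csv(rois, well_id: str, path, *, seed=None, cfg_hash=None) -> None:
    df = pd.DataFrame(
        [
            {
                "well_id": well_id,
                "cell_id": r.cell_id,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "area_px": r.area,
                "elongation": r.elongation_factor,
            }
            for r in rois
        ]
    )
    _write_csv(df, path, seed, cfg_hash)


# ---------------------------------------------------------------------------
# TIFF stacks


def write_stack(stack: np.ndarray, path: str | Path, *, cfg_hash: str | None = None) -> None:
    """Multi-page grayscale 16-bit TIFF; page index = frame/time index."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(stack)
    if data.dtype != np.uint16:
        data = np.clip(np.rint(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    desc = json.dumps({"software": f"calscreen {__version__}", "config": cfg_hash})
    tifffile.imwrite(path, data, photometric="minisblack", description=desc)


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


# ---------------------------------------------------------------------------
# Models and reports


def write_model(model: DecisionTreeModel, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(model.to_json(), encoding="utf-8")


def read_model(path: str | Path) -> DecisionTreeModel:
    return DecisionTreeModel.from_json(Path(path).read_text(encoding="utf-8"))


def write_json_report(payload: dict, path: str | Path, *, seed=None, cfg_hash=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {"_provenance": {"package": f"calscreen {__version__}", "seed": seed, "config": cfg_hash}}
    doc.update(payload)
    path.write_text(json.dumps(doc, indent=1, default=float), encoding="utf-8")
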