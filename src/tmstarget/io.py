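"""NIfTI-1 readers/writers, run configuration, and target tables.

Volumes travel as NIfTI-1 (3D scalar/label/mask, 4D time series) via
nibabel, with affines taken from headers verbatim. Targets and metrics are
tab-separated tables with a JSON sidecar carrying the exact run
configuration and its hash, so every emitted number is traceable to the
settings that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
import pandas as pd

from .baseline_targets import ClusterSettings, ConeKernel
from .connectivity import TimeSeriesVolume
from .evaluation import IntensityModel
from .tree_target import ThresholdGrid
from .volumes import LabelMap, Mask, ScalarMap, TargetPoint, VolumeGrid

ExpectedKind = Literal["scalar", "label", "timeseries", "mask"]


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------


def _grid_from_img(img: nib.Nifti1Image) -> VolumeGrid:
    shape = img.shape[:3]
    return VolumeGrid(tuple(int(s) for s in shape), np.asarray(img.affine))


def load_volume(path: str | Path, expected: ExpectedKind,
                reference: VolumeGrid | None = None):
    """Load a NIfTI volume as the requested typed container.

    ``label`` volumes must be integer-valued (float-stored labels are
    accepted only when exactly integral); ``mask`` volumes are nonzero-tested.
    A ``reference`` grid, when given, must match the file's shape.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    grid = _grid_from_img(img)
    if reference is not None and grid.shape != reference.shape:
        raise ValueError(
            f"{path}: shape {grid.shape} does not match reference "
            f"{reference.shape}"
        )
    if expected == "timeseries":
        if data.ndim != 4:
            raise ValueError(f"{path}: expected a 4D time series, got {data.ndim}D")
        return TimeSeriesVolume(grid, data)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    if expected == "scalar":
        return ScalarMap(grid, data.astype(float))
    if expected == "label":
        return LabelMap(grid, data)  # integer exactness enforced by LabelMap
    if expected == "mask":
        return Mask(grid, data != 0)
    raise ValueError(f"unknown expected kind {expected!r}")


def save_volume(obj, path: str | Path) -> None:
    """Write a Mask / ScalarMap / LabelMap / TimeSeriesVolume as NIfTI-1."""
    if isinstance(obj, Mask):
        data, grid = obj.member.astype(np.uint8), obj.grid
    elif isinstance(obj, LabelMap):
        data, grid = obj.label.astype(np.int32), obj.grid
    elif isinstance(obj, ScalarMap):
        data, grid = obj.value.astype(np.float32), obj.grid
    elif isinstance(obj, TimeSeriesVolume):
        data, grid = obj.series.astype(np.float32), obj.grid
    else:
        raise TypeError(f"cannot save object of type {type(obj).__name__}")
    nib.save(nib.Nifti1Image(data, grid.affine), str(path))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Everything a targeting/evaluation run depends on, serialisable.

    The settings hash accompanies every emitted target row, so tables can be
    traced back to the exact configuration.
    """

    algorithms: tuple[str, ...] = ("tree", "cluster", "cone")
    threshold_grid: ThresholdGrid = field(default_factory=ThresholdGrid)
    cluster: ClusterSettings = field(default_factory=ClusterSettings)
    cone_radii_mm: tuple[float, ...] = (2.0, 4.0, 7.0, 9.0, 12.0)
    cone_seed_spacing_mm: float = 4.0
    intensity: IntensityModel = field(default_factory=IntensityModel)
    eval_radius_mm: float = 5.0        # target seed-region radius for FC metrics
    connectivity: int = 26
    reference_algorithm: str = "cluster"  # baseline for intensity reduction

    def __post_init__(self) -> None:
        if not self.algorithms:
            raise ValueError("at least one algorithm must be enabled")
        unknown = set(self.algorithms) - {"tree", "cluster", "cone"}
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")

    def cone_kernel(self) -> ConeKernel:
        return ConeKernel(self.cone_radii_mm)

    def to_dict(self) -> dict:
        def enc(x):
            if dataclasses.is_dataclass(x) and not isinstance(x, type):
                return {k: enc(v) for k, v in dataclasses.asdict(x).items()}
            if isinstance(x, (tuple, list)):
                return [enc(v) for v in x]
            if isinstance(x, np.generic):
                return x.item()
            return x

        return {f.name: enc(getattr(self, f.name))
                for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "threshold_grid" in d and isinstance(d["threshold_grid"], dict):
            tg = d["threshold_grid"]
            d["threshold_grid"] = ThresholdGrid(
                tuple(tg["depth_percents"]), tuple(tg["fc_percents"]),
                tg.get("fc_direction", "negative"))
        if "cluster" in d and isinstance(d["cluster"], dict):
            d["cluster"] = ClusterSettings(**d["cluster"])
        if "intensity" in d and isinstance(d["intensity"], dict):
            d["intensity"] = IntensityModel(**d["intensity"])
        if "algorithms" in d:
            d["algorithms"] = tuple(d["algorithms"])
        if "cone_radii_mm" in d:
            d["cone_radii_mm"] = tuple(d["cone_radii_mm"])
        return cls(**d)

    @property
    def settings_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Target tables
# ---------------------------------------------------------------------------

TARGET_COLUMNS = ["subject", "session", "algorithm",
                  "x_mm", "y_mm", "z_mm", "n_candidates", "settings_hash"]


def targets_to_frame(rows: list[dict]) -> pd.DataFrame:
    """Normalise target rows into the shared TSV schema."""
    df = pd.DataFrame(rows)
    for col in TARGET_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    if not np.isfinite(df[["x_mm", "y_mm", "z_mm"]].to_numpy(float)).all():
        raise ValueError("target table contains non-finite coordinates")
    return df[TARGET_COLUMNS]


def target_row(subject: str, session: str, target: TargetPoint,
               settings_hash: str) -> dict:
    return {
        "subject": subject, "session": session,
        "algorithm": target.meta.get("algorithm", "unknown"),
        "x_mm": float(target.world_mm[0]),
        "y_mm": float(target.world_mm[1]),
        "z_mm": float(target.world_mm[2]),
        "n_candidates": target.meta.get("n_candidates", 1),
        "settings_hash": settings_hash,
    }


def write_table(df: pd.DataFrame, path: str | Path,
                config: RunConfig | None = None) -> None:
    """Write a TSV with an optional JSON config sidecar for provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    if config is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(
            {"settings_hash": config.settings_hash, "config": config.to_dict()},
            indent=2))


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
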