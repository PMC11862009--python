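"""Image and table I/O plus run configuration.

Axis order for volumetric data is fixed as (t, z, y, x); single-timepoint
stacks drop the leading axis and are (z, y, x).  Voxel sizes are physical
edge lengths in micrometers, ordered (z, y, x).  Physical coordinates are
voxel centers: ``index * voxel_size``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class MetadataError(ValueError):
    """Raised when required physical metadata is absent."""


class SchemaError(ValueError):
    """Raised when a table does not match the expected column schema."""


@dataclass
class VoxelImage:
    """A 3D (z,y,x) or 4D (t,z,y,x) intensity grid with physical voxel sizes."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]  # (z, y, x) in um
    channel: str = ""
    time_interval_min: float | None = None  # only meaningful for 4D stacks

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"expected 3D or 4D data, got ndim={self.data.ndim}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {vs}")
        self.voxel_size = vs

    @property
    def is_timeseries(self) -> bool:
        return self.data.ndim == 4

    @property
    def n_frames(self) -> int:
        return self.data.shape[0] if self.is_timeseries else 1

    def frame(self, t: int) -> "VoxelImage":
        if not self.is_timeseries:
            raise ValueError("not a time series")
        return VoxelImage(self.data[t], self.voxel_size, channel=self.channel)

    def physical_coords(self, indices: np.ndarray) -> np.ndarray:
        """Map (n,3) voxel indices (z,y,x) to physical um coordinates."""
        return np.asarray(indices, dtype=float) * np.asarray(self.voxel_size)


def write_stack(img: VoxelImage, path: str | Path) -> Path:
    """Write an OME-TIFF carrying voxel sizes (and frame interval for 4D)."""
    path = Path(path)
    vz, vy, vx = img.voxel_size
    meta = {
        "axes": "TZYX" if img.is_timeseries else "ZYX",
        "PhysicalSizeX": vx,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": vy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZ": vz,
        "PhysicalSizeZUnit": "µm",
    }
    if img.is_timeseries and img.time_interval_min is not None:
        meta["TimeIncrement"] = img.time_interval_min
        meta["TimeIncrementUnit"] = "min"
    tifffile.imwrite(path, img.data, ome=True, metadata=meta)
    return path


def read_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] | None = None,
) -> VoxelImage:
    """Read a TIFF/OME-TIFF stack.

    Voxel sizes are taken from OME metadata; a plain TIFF without metadata
    requires an explicit ``voxel_size`` override, otherwise a
    :class:`MetadataError` is raised rather than silently defaulting.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta_vs, interval = _parse_ome_voxel_size(tf)
    if voxel_size is None:
        if meta_vs is None:
            raise MetadataError(
                f"{path} carries no voxel-size metadata; pass voxel_size explicitly"
            )
        voxel_size = meta_vs
    data = np.squeeze(data)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected 3D/4D stack, got shape {data.shape}")
    return VoxelImage(data, voxel_size, time_interval_min=interval)


def _parse_ome_voxel_size(tf: tifffile.TiffFile):
    if not tf.is_ome or tf.ome_metadata is None:
        return None, None
    import xml.etree.ElementTree as ET

    root = ET.fromstring(tf.ome_metadata)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    if pixels is None:
        return None, None
    try:
        vs = (
            float(pixels.attrib["PhysicalSizeZ"]),
            float(pixels.attrib["PhysicalSizeY"]),
            float(pixels.attrib["PhysicalSizeX"]),
        )
    except KeyError:
        vs = None
    interval = pixels.attrib.get("TimeIncrement")
    return vs, (float(interval) if interval is not None else None)


# ---------------------------------------------------------------------------
# tables


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write records to CSV with full float precision (lossless round-trip)."""
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")
    return path


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> Path:
    """Write (chrom, start, end, value) intervals; 0-based half-open starts."""
    for col in ("chrom", "start", "end", "value"):
        if col not in df.columns:
            raise SchemaError(f"bedGraph output missing column {col!r}")
    path = Path(path)
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.17g"
    )
    return path


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
    )
    return df


def write_xyz(frames: list[np.ndarray], path: str | Path, comment: str = "") -> Path:
    """Write an XYZ trajectory, one block per frame, coordinates in sigma units."""
    path = Path(path)
    with open(path, "w") as fh:
        for pos in frames:
            fh.write(f"{len(pos)}\n{comment}\n")
            for i, (x, y, z) in enumerate(pos):
                fh.write(f"{i} {x:.9g} {y:.9g} {z:.9g}\n")
    return path


def read_xyz(path: str | Path) -> list[np.ndarray]:
    frames: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i])
        block = lines[i + 2 : i + 2 + n]
        coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        frames.append(coords)
        i += 2 + n
    return frames


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Every tunable of the pipeline; defaults follow the printed protocol
    values where such values exist."""

    seed: int = 0
    # segmentation / morphometry
    blur_sigma_um: float = 0.1
    threshold_method: str = "otsu"
    trim_fraction: float = 0.001
    area_method: str = "mesh"
    # condensates
    condensate_blur_sigma_um: float = 0.08
    n_erosions: int = 2
    min_voxels: int = 5
    periphery_fraction: float = 0.05
    diameter_definition: str = "equivalent_sphere"  # or "major_axis"
    # tracking / MSD
    cost_cutoff: float = 16900.0
    split_cutoff: float = 100.0
    msd_fit_window_hours: float = 7.0
    time_averaged_msd: bool = False
    # FRAP
    frap_interval_s: float = 0.002101
    # polymer simulation
    fene_k: float = 30.0
    fene_r0: float = 1.5
    bend_k: float = 1.0
    lj_cutoff: float = 2.5
    phi: float = 0.10
    level_scales: dict = field(
        default_factory=lambda: {"E1": 0.5, "E2": 1.0, "E3": 1.5, "E4": 2.0}
    )
    dt: float = 0.01
    gamma: float = 1.0
    equilibration_steps: int = 200_000
    # clustering
    cluster_min_size: int = 3

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def with_overrides(self, **kwargs) -> "RunConfig":
        clean = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **clean)
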