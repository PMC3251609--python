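"""Volume and configuration I/O.

NIfTI is the sole volume format; world coordinates are mm through the image
affine (RAS convention).  ``.nii.gz`` files are written with a zeroed gzip
timestamp so that re-running a pipeline with the same configuration produces
bit-identical files (and therefore identical manifest checksums).
"""

from __future__ import annotations

import gzip
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import VoxelGrid
from .tracking import TrackingConfig

log = logging.getLogger("thalatract.io")


class VolumeFormatError(ValueError):
    """A volume file could not be read."""


def read_volume(path) -> VoxelGrid:
    """Load a 3D NIfTI volume as a VoxelGrid."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    try:
        img = nib.load(path)
        data = np.asarray(img.dataobj)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise VolumeFormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return VoxelGrid(data, img.affine)


def write_volume(grid: VoxelGrid, path) -> Path:
    """Write a VoxelGrid as NIfTI (deterministic bytes for .nii.gz)."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    data = grid.data
    if data.dtype == np.int64:  # NIfTI-1 has no int64; counts fit in int32
        data = data.astype(np.int32)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, grid.affine)
    img.header.set_data_dtype(data.dtype)
    if path.name.endswith(".nii.gz"):
        payload = gzip.compress(img.to_bytes(), compresslevel=6, mtime=0)
        path.write_bytes(payload)
    else:
        nib.save(img, path)
    return path


def read_mask(path) -> VoxelGrid:
    """Load a volume that must be a 0/1 mask."""
    grid = read_volume(path)
    vals = np.unique(grid.data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{path}: mask contains values outside {{0,1}}: {vals[:10]}")
    return grid


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class PipelineConfig:
    """End-to-end run configuration (simulate -> track -> ... -> report)."""

    n_subjects: int = 9
    peak_sd_mm: float = 2.0
    landmark_jitter_deg: float = 0.0
    landmark_jitter_mm: float = 0.0
    dispersion_deg: float = 0.0
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    threshold_fraction: float = 0.10
    #: name -> [x, y, z] template-space reference points for distance read-outs
    references: dict[str, list[float]] = field(default_factory=dict)
    out_dir: str = "thalatract_out"
    seed: int = 0
    log_level: str = "INFO"
    #: optional phantom spec file; the stock two-bundle phantom if None
    phantom_spec: str | None = None

    def validate(self) -> None:
        if not (0 < self.threshold_fraction <= 1):
            raise ValueError("threshold_fraction must lie in (0, 1]")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.peak_sd_mm < 0:
            raise ValueError("peak_sd_mm must be >= 0")
        for name, v in self.references.items():
            if len(v) != 3:
                raise ValueError(f"reference '{name}' must be a 3-vector")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["tracking"] = dict(self.tracking.__dict__)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "tracking" in d and isinstance(d["tracking"], dict):
            d["tracking"] = TrackingConfig(**d["tracking"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def setup_logging(level: str = "INFO", log_file=None) -> None:
    """Console (+ optional file) logging for pipeline runs."""
    root = logging.getLogger("thalatract")
    root.setLevel(level.upper())
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    have_console = any(
        isinstance(h, logging.StreamHandler) and not isinstance(h, logging.FileHandler)
        for h in root.handlers
    )
    if not have_console:
        h = logging.StreamHandler()
        h.setFormatter(fmt)
        root.addHandler(h)
    if log_file is not None:
        fh = logging.FileHandler(log_file)
        fh.setFormatter(fmt)
        root.addHandler(fh)
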