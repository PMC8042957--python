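"""Core data containers, volume I/O and configuration.

The pipeline's unit of data is a reconstructed micro-CT :class:`Volume`: a 3D
grayscale image with an isotropic voxel size, stored on disk as a multi-page
TIFF with a JSON sidecar carrying the voxel size.  Axis order is fixed to
``(z, y, x)`` — ``z`` is the scanner slice index, ``y`` the row, ``x`` the
column.  Voxel indices are 0-based and a voxel's centre sits at
``index * voxel_size``; all geometry downstream is computed in voxel-centre
space.

Intensities are canonically 8-bit (0–255): the bone threshold window the
pipeline defaults to (60–90) lives on that scale.  16-bit input is accepted
and linearly rescaled to 0–255 (the mapping is logged).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

logger = logging.getLogger("microbic")

#: Label codes of the tri-class ("halftone") segmentation.
LABEL_BACKGROUND = 0  #: air and soft tissue
LABEL_BONE = 1
LABEL_IMPLANT = 2


@dataclass
class Volume:
    """3D grayscale micro-CT volume with isotropic voxel size.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Grayscale intensities, nominal 0–255 range.
    voxel_size_um : float
        Isotropic voxel edge length in micrometres (20 µm for the scans this
        pipeline models).
    """

    voxels: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(f"volume must be 3D with all dims >= 1, got shape {self.voxels.shape}")
        if not (self.voxel_size_um > 0):
            raise ValueError(f"voxel_size_um must be positive, got {self.voxel_size_um}")
        if np.issubdtype(self.voxels.dtype, np.floating) and not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class SliceImage:
    """A 2D grayscale longitudinal slice extracted from a :class:`Volume`.

    Rows run along the implant axis (row 0 = implant top), columns along the
    radial direction of the extraction plane.  ``origin`` and ``basis`` record
    where the slice lives in volume coordinates: pixel ``(i, j)`` sits at
    ``origin + i * basis[0] + j * basis[1]`` (voxel units).
    """

    pixels: np.ndarray
    pixel_size_um: float
    angle_deg: float
    origin: np.ndarray
    basis: np.ndarray  # shape (2, 3): (axial direction, radial direction)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.origin = np.asarray(self.origin, dtype=float)
        self.basis = np.asarray(self.basis, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("slice pixels must be 2D")
        if not (0.0 <= self.angle_deg < 360.0):
            raise ValueError(f"angle_deg must lie in [0, 360), got {self.angle_deg}")
        if self.basis.shape != (2, 3):
            raise ValueError("basis must be two 3-vectors")
        gram = self.basis @ self.basis.T
        if not np.allclose(gram, np.eye(2), atol=1e-9):
            raise ValueError("slice basis vectors must be orthonormal")


@dataclass
class LabelImage:
    """Tri-class label image (background / bone / implant) of one slice.

    Carries the geometry metadata of the :class:`SliceImage` it was derived
    from, so measurements can be reported against the extraction plane.
    """

    labels: np.ndarray
    pixel_size_um: float
    angle_deg: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    basis: np.ndarray = field(default_factory=lambda: np.array([[1.0, 0, 0], [0, 0, 1.0]]))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2D")
        bad = ~np.isin(self.labels, (LABEL_BACKGROUND, LABEL_BONE, LABEL_IMPLANT))
        if bad.any():
            raise ValueError("labels must partition pixels into {background, bone, implant}")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_volume(path: str | Path, sidecar: str | Path | None = None) -> Volume:
    """Read a multi-page TIFF stack plus its JSON sidecar into a :class:`Volume`.

    The sidecar must provide ``voxel_size_um``; it defaults to ``<path>.json``
    next to the stack.  16-bit stacks are rescaled to the canonical 0–255
    range; 8-bit and float stacks are passed through unmodified.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    voxel_size = meta.get("voxel_size_um")
    if voxel_size is None or not (float(voxel_size) > 0):
        raise ValueError(f"sidecar {sidecar} must give a positive voxel_size_um, got {voxel_size!r}")

    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"TIFF pages of unequal shape: {sorted(shapes)}")
    voxels = np.stack(pages, axis=0) if pages[0].ndim == 2 else pages[0]
    if voxels.ndim != 3:
        raise ValueError(f"expected a 3D stack, got shape {voxels.shape}")
    if voxels.dtype == np.uint16:
        logger.info("rescaling 16-bit volume %s to 0-255 (factor 255/65535)", path)
        voxels = voxels.astype(np.float32) * (255.0 / 65535.0)
    logger.info("read volume %s shape=%s voxel=%.3g um", path, voxels.shape, float(voxel_size))
    return Volume(voxels=voxels, voxel_size_um=float(voxel_size))


def write_volume(v: Volume, path: str | Path) -> Path:
    """Write a :class:`Volume` as a multi-page TIFF plus JSON sidecar.

    Round-trips exactly: ``read_volume(write_volume(v)) == v`` on voxel data
    and voxel size.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"target directory {path.parent} does not exist")
    tifffile.imwrite(path, v.voxels)
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "voxel_size_um": v.voxel_size_um,
                "shape": list(v.voxels.shape),
                "dtype": str(v.voxels.dtype),
            },
            indent=2,
        )
    )
    logger.info("wrote volume %s shape=%s", path, v.voxels.shape)
    return path


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with the protocol defaults filled in.

    Defaults mirror the measurement protocol: bone window [60, 90] on the
    8-bit scale, one excluded interface voxel layer, longitudinal slices at
    0/45/90/135 degrees, upper four grooves per side.
    """

    bone_min: float = 60.0
    bone_max: float = 90.0
    implant_min: float = 200.0
    exclusion_layers: int = 1
    angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    angle_offset_deg: float = 0.0
    grooves_per_side: int = 4
    pooling: str = "pooled"
    invert_top: bool = False

    def __post_init__(self) -> None:
        if not (self.bone_min <= self.bone_max):
            raise ValueError(f"bone window must be ordered: min {self.bone_min} > max {self.bone_max}")
        if not (self.bone_max < self.implant_min):
            raise ValueError("implant_min must exceed bone_max")
        if self.exclusion_layers < 0:
            raise ValueError("exclusion_layers must be >= 0")
        if self.grooves_per_side < 1:
            raise ValueError("grooves_per_side must be >= 1")
        angles = tuple(float(a) for a in self.angles_deg)
        if any(not (0.0 <= a < 360.0) for a in angles):
            raise ValueError("angles must lie in [0, 360)")
        self.angles_deg = angles

    def segmentation(self):
        from .segment import SegmentationConfig

        return SegmentationConfig(
            bone_min=self.bone_min, bone_max=self.bone_max, implant_min=self.implant_min
        )

    def measurement(self):
        from .bic import MeasurementConfig

        return MeasurementConfig(
            exclusion_layers=self.exclusion_layers,
            grooves_per_side=self.grooves_per_side,
            pooling=self.pooling,
            invert_top=self.invert_top,
        )


_CONFIG_KEYS = {
    "bone_min",
    "bone_max",
    "implant_min",
    "exclusion_layers",
    "angles_deg",
    "angle_offset_deg",
    "grooves_per_side",
    "pooling",
    "invert_top",
}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML/JSON config file, filling protocol defaults.

    Unknown keys produce a logged warning; type- or range-invalid values raise
    ``ValueError``.  An empty file yields all defaults.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(raw).__name__}")
    known = {}
    for key, value in raw.items():
        if key not in _CONFIG_KEYS:
            logger.warning("config %s: ignoring unknown key %r", path, key)
            continue
        known[key] = value
    try:
        cfg = PipelineConfig(**known)
    except TypeError as exc:  # e.g. non-iterable angles
        raise ValueError(f"invalid config {path}: {exc}") from exc
    return cfg
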