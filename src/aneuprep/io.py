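"""Volumetric data model, NIfTI I/O, configuration and logging.

The toolkit works on 3D time-of-flight MR angiography (TOF-MRA) volumes.
All geometry is expressed through per-axis voxel spacing in millimetres;
world orientation (affine direction cosines) is carried along as opaque
metadata but never used in computation.

Conventions
-----------
* 0-based voxel indices; bounding boxes are half-open ``[lo, hi)``.
* Binary masks binarize at value > 0 on load (tolerant of 1/255 labels).
* Axis order on disk equals axis order in memory: voxel ``(i, j, k)``
  written is voxel ``(i, j, k)`` read.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger("aneuprep")

__all__ = [
    "Volume3D",
    "BinaryMask3D",
    "BoundingBox3D",
    "read_nifti",
    "write_nifti",
    "load_config",
    "configure_logging",
    "AneuprepError",
    "ParameterError",
    "DimensionalityError",
    "GridMismatchError",
    "DegenerateHistogramError",
    "EmptyRoiError",
]


# ---------------------------------------------------------------------------
# Errors


class AneuprepError(Exception):
    """Base class for toolkit errors."""


class ParameterError(AneuprepError, ValueError):
    """An argument is outside its documented domain."""


class DimensionalityError(AneuprepError, ValueError):
    """A volume on disk is not 3D."""


class GridMismatchError(AneuprepError, ValueError):
    """Two volumes expected to share a grid do not."""


class DegenerateHistogramError(AneuprepError, ValueError):
    """Thresholding was asked of a constant volume."""


class EmptyRoiError(AneuprepError, ValueError):
    """No vessel voxels survive to define a region of interest."""


# ---------------------------------------------------------------------------
# Core types


def _as_triple(x, name: str) -> tuple:
    t = tuple(x)
    if len(t) != 3:
        raise ParameterError(f"{name} must have length 3, got {len(t)}")
    return t


@dataclass
class Volume3D:
    """A 3D scalar image with voxel spacing in mm.

    ``origin_offset`` holds the index offset of this volume relative to the
    parent it was cropped from (all zeros for a freshly loaded volume), so
    original coordinates stay recoverable after cropping.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin_offset: tuple = (0, 0, 0)
    affine: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected 3D data, got {self.data.ndim}D with shape {self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise ParameterError("all three dimensions must be >= 1")
        self.spacing = tuple(float(s) for s in _as_triple(self.spacing, "spacing"))
        if any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin_offset = tuple(int(o) for o in _as_triple(self.origin_offset, "origin_offset"))
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ParameterError("volume contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def same_grid(self, other: "Volume3D") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """Same grid metadata, new voxel values."""
        return replace(self, data=data)


@dataclass
class BinaryMask3D(Volume3D):
    """A 3D boolean volume sharing a :class:`Volume3D` grid."""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.dtype != bool:
            self.data = self.data > 0
        super().__post_init__()

    @property
    def n_true(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class BoundingBox3D:
    """Axis-aligned index box, half-open ``[lo, hi)``, 0-based."""

    lo: tuple
    hi: tuple

    def __post_init__(self):
        object.__setattr__(self, "lo", tuple(int(v) for v in _as_triple(self.lo, "lo")))
        object.__setattr__(self, "hi", tuple(int(v) for v in _as_triple(self.hi, "hi")))
        if not all(l < h for l, h in zip(self.lo, self.hi)):
            raise ParameterError(f"box must satisfy lo < hi componentwise: lo={self.lo} hi={self.hi}")

    @property
    def shape(self) -> tuple:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def slices(self) -> tuple:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    def clamped(self, shape: tuple) -> "BoundingBox3D":
        """Intersect with a volume of the given shape."""
        lo = tuple(max(0, l) for l in self.lo)
        hi = tuple(min(int(n), h) for n, h in zip(shape, self.hi))
        if not all(l < h for l, h in zip(lo, hi)):
            raise ParameterError(f"box {self.lo}-{self.hi} lies outside volume of shape {shape}")
        return BoundingBox3D(lo, hi)

    def contains_point(self, idx) -> bool:
        return all(l <= i < h for l, i, h in zip(self.lo, idx, self.hi))


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_nifti(path, as_mask: bool = False):
    """Read a 3D NIfTI-1/2 file into a :class:`Volume3D` or :class:`BinaryMask3D`.

    Parameters
    ----------
    path : str or Path
        NIfTI file (``.nii`` or ``.nii.gz``).
    as_mask : bool
        If True, binarize at value > 0 and return a :class:`BinaryMask3D`.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    DimensionalityError
        If the data block is not 3D.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path.name}: expected a 3D data block, got {data.ndim}D {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    affine = np.asarray(img.affine) if img.affine is not None else None
    if as_mask:
        return BinaryMask3D(data=data, spacing=spacing, affine=affine)
    data = np.asarray(data, dtype=np.float64)
    if not np.isfinite(data).all():
        raise ParameterError(f"{path.name}: volume contains non-finite values")
    return Volume3D(data=data, spacing=spacing, affine=affine)


def write_nifti(vol: Volume3D, path) -> None:
    """Write a volume or mask to NIfTI; masks are stored as uint8 in {0, 1}.

    The stored affine is the volume's opaque affine metadata if present,
    else a diagonal affine built from the spacing.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if vol.affine is not None:
        affine = vol.affine
    else:
        affine = np.diag(list(vol.spacing) + [1.0])
    if isinstance(vol, BinaryMask3D):
        data = vol.data.astype(np.uint8)
    else:
        data = np.asarray(vol.data, dtype=np.float32)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing)
    try:
        nib.save(img, str(path))
    except OSError as exc:  # unwritable path
        raise OSError(f"cannot write NIfTI to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Configuration and logging


def load_config(path) -> dict:
    """Load a TOML configuration file into a plain nested dict.

    Sections mirror the pipeline stages (``[vessel]``, ``[roi]``, ``[vea]``,
    ``[losses]``, ``[phantom]``); every tunable documented on the stage
    functions may appear under its section.
    """
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def configure_logging(level: str = "INFO") -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    logger.setLevel(level.upper())
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
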