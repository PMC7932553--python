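"""Reading and writing RCM z-stacks, and the depth/coordinate conventions.

A stack is stored on disk as a multi-page grayscale TIFF (one en-face slice
per page, acquisition order = page order, shallowest first) together with a
JSON metadata sidecar holding the acquisition geometry (lateral pixel size
and axial step, both in micrometres) and free-form subject/session metadata.

Depth convention
----------------
Slices are numbered 1-based and ``depth(k) = k * step_um``: the first slice
sits one axial step below the contact surface.  With the standard 2.8 um
step this places slice 15 at 42 um and slice 50 at 140 um, the band of the
papillary dermis used throughout the quantification layer.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: Fallback geometry used when no sidecar is present.
DEFAULT_PIXEL_SIZE_UM = 0.5
DEFAULT_STEP_UM = 2.8
DEFAULT_N_SLICES = 78
DEFAULT_FIELD_UM = 750.0

SIDECAR_SUFFIX = ".json"


class StackFormatError(ValueError):
    """Raised when a file on disk is not a supported grayscale z-stack."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Acquisition geometry of an RCM z-stack.

    Parameters
    ----------
    pixel_size_um : float
        Lateral size of one pixel (um).
    step_um : float
        Axial distance between consecutive slices (um).
    n_slices : int
        Number of slices in the stack.
    field_um : float
        Lateral field edge length (um).  The standard acquisition images a
        750 um square field.
    """

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    step_um: float = DEFAULT_STEP_UM
    n_slices: int = DEFAULT_N_SLICES
    field_um: float = DEFAULT_FIELD_UM

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.step_um <= 0:
            raise ValueError("step_um must be > 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.field_um <= 0:
            raise ValueError("field_um must be > 0")

    @property
    def voxel_volume_um3(self) -> float:
        """Volume of one voxel (um^3): pixel area times axial step."""
        return self.pixel_size_um**2 * self.step_um

    @property
    def field_area_um2(self) -> float:
        return self.field_um**2

    def depth_of_slice(self, index: int) -> float:
        """Depth (um) of the 1-based slice ``index`` below the surface."""
        return depth_of_slice(index, self)


def depth_of_slice(index: int, geometry: AcquisitionGeometry) -> float:
    """Map a 1-based slice index to its tissue depth in micrometres.

    ``depth = index * step_um``; strictly increasing in the index.  With the
    standard 2.8 um step, slice 15 lies at 42 um and slice 50 at 140 um.
    """
    if not 1 <= index <= geometry.n_slices:
        raise ValueError(
            f"slice index {index} out of range 1..{geometry.n_slices}"
        )
    return index * geometry.step_um


@dataclass
class ImageStack:
    """A 3D reflectance intensity volume plus its geometry and metadata.

    ``voxels`` has shape ``(n_slices, H, W)`` with the first axis in
    acquisition order (shallowest slice first).  Intensities are unitless
    reflectance counts; no absolute calibration is attempted.
    """

    voxels: np.ndarray
    geometry: AcquisitionGeometry
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D (n_slices, H, W) array")
        if self.voxels.shape[0] != self.geometry.n_slices:
            raise ValueError(
                f"voxels first axis ({self.voxels.shape[0]}) does not match "
                f"geometry.n_slices ({self.geometry.n_slices})"
            )
        if np.issubdtype(self.voxels.dtype, np.floating) and np.any(
            self.voxels < 0
        ):
            raise ValueError("voxels must be nonnegative")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def get_slice(self, index: int) -> np.ndarray:
        """Return the 2D slice at 1-based ``index``."""
        if not 1 <= index <= self.n_slices:
            raise ValueError(f"slice index {index} out of range 1..{self.n_slices}")
        return self.voxels[index - 1]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + SIDECAR_SUFFIX)


def read_stack(path, meta_path=None) -> ImageStack:
    """Read a multi-page grayscale TIFF z-stack and its JSON sidecar.

    Parameters
    ----------
    path
        Path to a multi-page grayscale TIFF; the first page is the
        shallowest slice.
    meta_path
        Optional explicit sidecar path.  By default ``<path>.json`` is used;
        when no sidecar exists, the documented defaults (0.5 um/px lateral,
        2.8 um axial step) are assumed and a warning is logged.

    Returns
    -------
    ImageStack
        Voxels preserved bit-exactly, in acquisition order.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            if any(page.samplesperpixel > 1 for page in tf.pages):
                raise StackFormatError(
                    f"{path} contains RGB/multichannel pages; convert the "
                    "stack to single-channel grayscale before reading"
                )
            shapes = {page.shape for page in tf.pages}
            if len(shapes) > 1:
                raise StackFormatError(
                    f"{path}: pages have inconsistent shapes {sorted(shapes)}"
                )
            arr = tf.asarray()
    except StackFormatError:
        raise
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        if path.exists() and not isinstance(exc, OSError):
            raise StackFormatError(f"cannot parse {path} as TIFF: {exc}") from exc
        raise OSError(f"cannot read stack {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise StackFormatError(
            f"{path}: expected 2D grayscale pages, got shape {arr.shape}"
        )

    meta_file = Path(meta_path) if meta_path is not None else _sidecar_path(path)
    meta: dict = {}
    if meta_file.exists():
        with open(meta_file) as fh:
            meta = json.load(fh)
        pixel = float(meta.pop("pixel_size_um"))
        step = float(meta.pop("step_um"))
    else:
        logger.warning(
            "no metadata sidecar for %s; assuming defaults %g um/px, %g um step",
            path, DEFAULT_PIXEL_SIZE_UM, DEFAULT_STEP_UM,
        )
        warnings.warn(
            f"no metadata sidecar for {path}; assuming default geometry",
            stacklevel=2,
        )
        pixel, step = DEFAULT_PIXEL_SIZE_UM, DEFAULT_STEP_UM

    n_slices, h, w = arr.shape
    geometry = AcquisitionGeometry(
        pixel_size_um=pixel,
        step_um=step,
        n_slices=n_slices,
        field_um=w * pixel,
    )
    return ImageStack(voxels=arr, geometry=geometry, meta=meta)


def write_stack(stack: ImageStack, path) -> None:
    """Write ``stack`` as multi-page TIFF plus JSON sidecar.

    ``read_stack(write_stack(stack))`` restores the stack voxel-for-voxel
    and metadata-for-metadata.
    """
    path = Path(path)
    arr = stack.voxels
    if arr.dtype not in (np.uint8, np.uint16):
        # TIFF pages are written in the array's own dtype; integer stacks
        # round-trip bit-exactly, which is all the pipeline relies on.
        arr = np.asarray(arr)
    try:
        tifffile.imwrite(path, arr, photometric="minisblack")
    except OSError as exc:
        raise OSError(f"cannot write stack to {path}: {exc}") from exc
    sidecar = {
        "pixel_size_um": stack.geometry.pixel_size_um,
        "step_um": stack.geometry.step_um,
        **stack.meta,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
        fh.write("\n")
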