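"""Depth-resolved crystal-area profiles, 3D reconstruction and nCCV.

The quantification layer runs the per-slice segmentation over a whole
z-stack and summarizes it two ways:

* an :class:`AreaProfile` — per slice, the summed isolated-crystal area
  normalized to the analyzed area (field minus skin structure), plotted
  against tissue depth;
* an :class:`NccvResult` — the normalized confocal crystal volume (nCCV),
  a single per-stack summary in um^3.  Isolated-crystal masks of the
  papillary-dermis band (slices 15-50 by default, 42-140 um at the
  standard 2.8 um step) are stacked, 3D connected components are labeled
  with 26-connectivity, and the summed crystal volume is normalized
  against the total region of analysis excluding skin structure.

Normalization convention
------------------------
``nccv_um3 = crystal_volume_um3 * (V_ref / analyzed_volume_um3)`` where
``V_ref = field_um^2 * band_depth`` is the nominal reference volume of a
standard, structure-free acquisition.  nCCV is therefore a
structure-corrected crystal volume in um^3: it equals the raw crystal
volume when no structure is present, and rescales stacks whose analyzable
volume was reduced by papillae so that different stacks stay comparable.
The convention is isolated in :func:`compute_nccv`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .stack_io import AcquisitionGeometry, ImageStack, depth_of_slice
from .segmentation import (
    SegmentationParams,
    detect_crystal_candidates,
    detect_skin_structure,
    exclude_structure,
)

DEFAULT_FIRST_SLICE = 15
DEFAULT_LAST_SLICE = 50


@dataclass(frozen=True)
class BandSpec:
    """Inclusive 1-based slice band analyzed in 3D (papillary dermis)."""

    first_slice: int = DEFAULT_FIRST_SLICE
    last_slice: int = DEFAULT_LAST_SLICE

    def __post_init__(self) -> None:
        if not 1 <= self.first_slice <= self.last_slice:
            raise ValueError("need 1 <= first_slice <= last_slice")

    @property
    def n_slices(self) -> int:
        return self.last_slice - self.first_slice + 1

    def indices(self) -> range:
        return range(self.first_slice, self.last_slice + 1)

    def contains(self, index: int) -> bool:
        return self.first_slice <= index <= self.last_slice

    def validate_for(self, geometry: AcquisitionGeometry) -> None:
        if self.last_slice > geometry.n_slices:
            raise ValueError(
                f"band {self.first_slice}-{self.last_slice} exceeds stack "
                f"with {geometry.n_slices} slices"
            )


@dataclass
class SliceAreas:
    slice_index: int
    depth_um: float
    crystal_area_um2: float
    analyzed_area_um2: float
    normalized_area: float


@dataclass
class AreaProfile:
    """Per-slice normalized crystal areas over a full stack."""

    per_slice: List[SliceAreas]

    def __len__(self) -> int:
        return len(self.per_slice)

    @property
    def normalized(self) -> np.ndarray:
        return np.array([s.normalized_area for s in self.per_slice])

    @property
    def depths_um(self) -> np.ndarray:
        return np.array([s.depth_um for s in self.per_slice])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slice_index": [s.slice_index for s in self.per_slice],
                "depth_um": [s.depth_um for s in self.per_slice],
                "crystal_area_um2": [s.crystal_area_um2 for s in self.per_slice],
                "analyzed_area_um2": [s.analyzed_area_um2 for s in self.per_slice],
                "normalized_area": [s.normalized_area for s in self.per_slice],
            }
        )


@dataclass
class Component3D:
    component_id: int
    voxel_count: int
    volume_um3: float


@dataclass
class NccvResult:
    """Per-stack nCCV summary with all intermediate quantities."""

    band: BandSpec
    components: List[Component3D]
    crystal_volume_um3: float
    analyzed_volume_um3: float
    structure_volume_um3: float
    nccv_um3: float
    profile: AreaProfile
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "band": {
                "first_slice": self.band.first_slice,
                "last_slice": self.band.last_slice,
            },
            "components": [
                {
                    "component_id": c.component_id,
                    "voxel_count": c.voxel_count,
                    "volume_um3": c.volume_um3,
                }
                for c in self.components
            ],
            "crystal_volume_um3": self.crystal_volume_um3,
            "analyzed_volume_um3": self.analyzed_volume_um3,
            "structure_volume_um3": self.structure_volume_um3,
            "nccv_um3": self.nccv_um3,
            "meta": self.meta,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


def segment_slice(
    stack: ImageStack,
    index: int,
    params: SegmentationParams,
) -> tuple:
    """Run detect -> structure -> exclude on 1-based slice ``index``.

    Returns ``(isolated: RegionSet, structure: RegionSet)``.
    """
    img = stack.get_slice(index)
    candidates = detect_crystal_candidates(img, stack.geometry, params, index)
    structure = detect_skin_structure(img, stack.geometry, params, index)
    isolated = exclude_structure(candidates, structure, params)
    return isolated, structure


def _profile_and_masks(stack: ImageStack, params: SegmentationParams):
    """One segmentation pass over the stack.

    Returns the AreaProfile plus per-slice isolated/structure boolean masks
    (lists indexed by slice position) so 3D quantities reuse the exact same
    masks as the 2D profile.
    """
    geom = stack.geometry
    field_area = stack.voxels.shape[1] * stack.voxels.shape[2] * geom.pixel_size_um**2
    rows: List[SliceAreas] = []
    iso_masks: List[np.ndarray] = []
    struct_masks: List[np.ndarray] = []
    for k in range(1, geom.n_slices + 1):
        isolated, structure = segment_slice(stack, k, params)
        struct_area = structure.total_area_um2
        crystal_area = isolated.total_area_um2
        analyzed = field_area - struct_area
        rows.append(
            SliceAreas(
                slice_index=k,
                depth_um=depth_of_slice(k, geom),
                crystal_area_um2=crystal_area,
                analyzed_area_um2=analyzed,
                normalized_area=crystal_area / analyzed if analyzed > 0 else 0.0,
            )
        )
        iso_masks.append(isolated.mask)
        struct_masks.append(structure.mask)
    return AreaProfile(per_slice=rows), iso_masks, struct_masks


def area_profile(stack: ImageStack, params: Optional[SegmentationParams] = None) -> AreaProfile:
    """Depth-resolved normalized crystal-area profile of a stack.

    For each slice the isolated-crystal area (after structure exclusion) is
    normalized to the analyzed area, i.e. the imaged field minus the skin
    structure detected on that slice.  Empty detections yield zeros.
    """
    params = params or SegmentationParams()
    profile, _, _ = _profile_and_masks(stack, params)
    return profile


def _label_3d(iso_band: np.ndarray) -> np.ndarray:
    """26-connected 3D labeling of a (band, H, W) boolean mask."""
    return ndi.label(iso_band, structure=np.ones((3, 3, 3), dtype=bool))[0]


def reconstruct_3d(
    stack: ImageStack,
    band: Optional[BandSpec] = None,
    params: Optional[SegmentationParams] = None,
) -> np.ndarray:
    """3D label volume of isolated crystals within the band.

    Per-slice isolated-crystal binary masks of the band slices are stacked
    and labeled with 26-connectivity.  Voxel anisotropy (lateral pixel vs
    axial step) affects volume computation only, never connectivity: the
    2.8 um step exceeds the pixel size, so conservative diagonal linking
    avoids fragmenting single crystals across slices.
    """
    band = band or BandSpec()
    params = params or SegmentationParams()
    band.validate_for(stack.geometry)
    _, iso_masks, _ = _profile_and_masks(stack, params)
    iso_band = np.stack([iso_masks[k - 1] for k in band.indices()])
    return _label_3d(iso_band)


def compute_nccv(
    stack: ImageStack,
    band: Optional[BandSpec] = None,
    params: Optional[SegmentationParams] = None,
    geometry_ref: Optional[AcquisitionGeometry] = None,
) -> NccvResult:
    """Normalized confocal crystal volume (nCCV, um^3) of one z-stack.

    Runs the full per-slice pipeline, stacks the band's isolated-crystal
    masks into 3D components, and normalizes the summed crystal volume
    against the analyzed region:

    ``nccv = crystal_volume * V_ref / analyzed_volume``

    with ``V_ref = field^2 * band depth`` taken from ``geometry_ref``
    (default: the stack's own geometry).  With no structure present the
    normalization factor is 1 and nCCV equals the raw crystal volume.

    Raises
    ------
    ValueError
        If structure covers the entire band (analyzed volume is zero the
        statistic is undefined).
    """
    band = band or BandSpec()
    params = params or SegmentationParams()
    band.validate_for(stack.geometry)
    geom = stack.geometry
    geometry_ref = geometry_ref or geom

    profile, iso_masks, struct_masks = _profile_and_masks(stack, params)
    iso_band = np.stack([iso_masks[k - 1] for k in band.indices()])
    labels3d = _label_3d(iso_band)

    voxel_vol = geom.voxel_volume_um3
    counts = np.bincount(labels3d.ravel())
    components = [
        Component3D(component_id=i, voxel_count=int(c), volume_um3=float(c * voxel_vol))
        for i, c in enumerate(counts[1:], start=1)
        if c > 0
    ]
    crystal_volume = float(sum(c.volume_um3 for c in components))

    struct_vox = int(sum(struct_masks[k - 1].sum() for k in band.indices()))
    structure_volume = struct_vox * voxel_vol
    h, w = stack.voxels.shape[1:]
    gross_volume = h * w * band.n_slices * voxel_vol
    analyzed_volume = gross_volume - structure_volume
    if analyzed_volume <= 0:
        raise ValueError(
            "analyzed volume is zero: skin structure covers the whole band, "
            "nCCV is undefined for this stack"
        )

    v_ref = geometry_ref.field_area_um2 * band.n_slices * geometry_ref.step_um
    nccv = crystal_volume * v_ref / analyzed_volume
    return NccvResult(
        band=band,
        components=components,
        crystal_volume_um3=crystal_volume,
        analyzed_volume_um3=analyzed_volume,
        structure_volume_um3=structure_volume,
        nccv_um3=nccv,
        profile=profile,
        meta=dict(stack.meta),
    )


def max_intensity_projection(stack: ImageStack, band: Optional[BandSpec] = None) -> np.ndarray:
    """Maximum-intensity projection over the band slices (simple 3D view)."""
    band = band or BandSpec()
    band.validate_for(stack.geometry)
    sub = stack.voxels[band.first_slice - 1 : band.last_slice]
    return sub.max(axis=0)
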