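"""Synthetic RCM skin-stack generator with exact ground truth.

Emulates the standard intradermal acquisition (78 slices, 2.8 um axial
step, square lateral field) so that every pipeline stage can be validated
against known truth without patient data:

* **crystals** — small bright ellipsoids planted with a unimodal depth
  profile peaked inside the papillary-dermis band, at intensities above
  any other tissue signal (cystine crystals are the strongest reflectors
  in cystinotic skin);
* **dermal papillae** — bright annular tubes spanning the band, the
  structures whose cross-sections cause false-positive bright objects;
* **confounders** — a configurable fraction of crystals is planted inside
  papillae and must be excluded by the pipeline, and epidermal slices
  above the band carry unspecific bright speckle such as is occasionally
  seen in healthy controls;
* **degradations** — exponential intensity loss with depth and additive
  Gaussian detector noise, applied after ground truth is recorded.

Ground-truth volumes are voxel-exact: the generator voxelizes each
ellipsoid on the acquisition grid and the true volume is the voxel count
times the voxel volume, which is the same discretization the pipeline
measures.  All randomness flows from a single seed; output is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

from .stack_io import AcquisitionGeometry, ImageStack
from .quantify import BandSpec

#: Printed band of the standard 78-slice acquisition, kept proportional
#: for shorter synthetic stacks.
_BAND_FRACTIONS = (15 / 78, 50 / 78)


class GeometryError(ValueError):
    """A planted object cannot be placed inside the field."""


def default_band(n_slices: int) -> BandSpec:
    """Papillary-dermis band for a stack of ``n_slices`` slices.

    The standard 78-slice acquisition uses slices 15-50; shorter stacks
    get the proportionally scaled band.
    """
    if n_slices >= 50:
        return BandSpec(15, 50)
    first = max(1, int(round(_BAND_FRACTIONS[0] * n_slices)))
    last = max(first, min(n_slices, int(round(_BAND_FRACTIONS[1] * n_slices))))
    return BandSpec(first, last)


def default_depth_profile(n_slices: int, band: Optional[BandSpec] = None) -> np.ndarray:
    """Unimodal per-slice placement weights peaked mid-band, zero outside.

    Crystal accumulation is maximal in the papillary dermis; the default
    profile is a Gaussian over the band slices (sd = band width / 4).
    """
    band = band or default_band(n_slices)
    w = np.zeros(n_slices)
    ks = np.arange(band.first_slice, band.last_slice + 1)
    center = 0.5 * (band.first_slice + band.last_slice)
    sd = max(band.n_slices / 4.0, 1.0)
    w[ks - 1] = np.exp(-0.5 * ((ks - center) / sd) ** 2)
    return w / w.sum()


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic stack generator.

    Intensities are unitless reflectance counts on the 16-bit scale the
    pipeline reads from TIFF.  Defaults describe a patient-like stack at
    moderate signal-to-noise: crystal contrast ~140 counts against a
    detector noise sd of 4.
    """

    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    n_crystals: int = 40
    #: When set, isolated crystals are planted until their voxelized volume
    #: reaches this target (um^3); overrides ``n_crystals``.
    target_isolated_volume_um3: Optional[float] = None
    crystal_radius_mean_um: float = 1.5
    crystal_radius_sd_um: float = 0.5
    depth_profile: Optional[np.ndarray] = None
    band: Optional[BandSpec] = None
    n_papillae: int = 6
    papilla_radius_um: float = 30.0
    papilla_wall_um: float = 6.0
    fraction_in_structure: float = 0.2
    #: Bright epidermal speckles per mm^2 per slice above the band.
    epidermal_speckle_rate: float = 100.0
    background_level: float = 20.0
    noise_sd: float = 4.0
    structure_level: float = 80.0
    crystal_level: float = 160.0
    speckle_level: float = 150.0
    attenuation_per_um: float = 0.004
    #: Lateral clearance (um) between isolated crystals and papilla rims.
    clear_margin_um: float = 12.0
    #: Minimum 3D distance (um) between planted crystal centres.
    min_separation_um: float = 8.0
    seed: int = 0
    #: Separate seed for detector noise only; lets the same planted field
    #: be "re-acquired" with independent noise (repeatability studies).
    #: None draws noise from the main stream.
    noise_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_crystals < 0 or self.n_papillae < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.fraction_in_structure <= 1:
            raise ValueError("fraction_in_structure must be in [0, 1]")
        if self.noise_sd < 0 or self.epidermal_speckle_rate < 0:
            raise ValueError("noise_sd and speckle rate must be >= 0")
        if self.target_isolated_volume_um3 is not None and self.target_isolated_volume_um3 < 0:
            raise ValueError("target_isolated_volume_um3 must be >= 0")

    def resolved_band(self) -> BandSpec:
        return self.band or default_band(self.geometry.n_slices)

    def resolved_depth_profile(self) -> np.ndarray:
        if self.depth_profile is not None:
            w = np.asarray(self.depth_profile, dtype=float)
            if w.shape != (self.geometry.n_slices,) or w.sum() <= 0 or (w < 0).any():
                raise ValueError("depth_profile must be nonnegative per-slice weights")
            return w / w.sum()
        return default_depth_profile(self.geometry.n_slices, self.resolved_band())

    def with_overrides(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class PlantedCrystal:
    id: int
    centroid_um: tuple  # (z, y, x) in um
    voxel_count: int
    volume_um3: float
    inside_structure: bool


@dataclass
class GroundTruth:
    """Exact simulator output recorded before noise."""

    crystal_mask: np.ndarray  # all planted crystals, incl. confounders
    structure_mask: np.ndarray  # papillae as filled tubes
    true_crystal_volume_um3: float  # isolated (non-confounder) crystals only
    per_crystal: List[PlantedCrystal]
    band: BandSpec

    @property
    def n_isolated(self) -> int:
        return sum(not c.inside_structure for c in self.per_crystal)

    @property
    def n_confounders(self) -> int:
        return sum(c.inside_structure for c in self.per_crystal)


def _place_papillae(cfg: SimConfig, rng: np.random.Generator) -> List[tuple]:
    """Papilla axis positions (y_um, x_um), rejection-sampled for spacing."""
    field_um = cfg.geometry.field_um
    r = cfg.papilla_radius_um
    if cfg.n_papillae and 2 * (r + 2) > field_um:
        raise GeometryError(
            f"papilla radius {r} um does not fit the {field_um} um field"
        )
    centers: List[tuple] = []
    for _ in range(cfg.n_papillae):
        for _attempt in range(500):
            y = rng.uniform(r + 2, field_um - r - 2)
            x = rng.uniform(r + 2, field_um - r - 2)
            if all((y - yc) ** 2 + (x - xc) ** 2 >= (2.2 * r) ** 2 for yc, xc in centers):
                centers.append((y, x))
                break
        else:
            raise GeometryError(
                f"cannot place {cfg.n_papillae} papillae of radius {r} um "
                f"in a {field_um} um field"
            )
    return centers


def _voxelize_ellipsoid(cfg, center_um, r_lat, r_ax):
    """Voxel index arrays of an axis-aligned ellipsoid on the stack grid.

    Voxel centers sit at depth ``k * step`` axially and ``(i + 0.5) * px``
    laterally.  Returns (z_idx, y_idx, x_idx) arrays (possibly empty).
    """
    geom = cfg.geometry
    zc, yc, xc = center_um
    step, px = geom.step_um, geom.pixel_size_um
    npx = int(round(geom.field_um / px))
    k_lo = max(1, int(np.ceil((zc - r_ax) / step)))
    k_hi = min(geom.n_slices, int(np.floor((zc + r_ax) / step)))
    if k_hi < k_lo:
        return (np.array([], int),) * 3
    i_lo = max(0, int(np.floor((yc - r_lat) / px - 0.5)))
    i_hi = min(npx - 1, int(np.ceil((yc + r_lat) / px - 0.5)))
    j_lo = max(0, int(np.floor((xc - r_lat) / px - 0.5)))
    j_hi = min(npx - 1, int(np.ceil((xc + r_lat) / px - 0.5)))
    kk, ii, jj = np.meshgrid(
        np.arange(k_lo, k_hi + 1),
        np.arange(i_lo, i_hi + 1),
        np.arange(j_lo, j_hi + 1),
        indexing="ij",
    )
    z = kk * step
    y = (ii + 0.5) * px
    x = (jj + 0.5) * px
    inside = (
        ((z - zc) / r_ax) ** 2
        + ((y - yc) / r_lat) ** 2
        + ((x - xc) / r_lat) ** 2
    ) <= 1.0
    return kk[inside] - 1, ii[inside], jj[inside]


def _sample_crystal_center(
    cfg: SimConfig,
    rng: np.random.Generator,
    r_lat: float,
    papillae: List[tuple],
    placed: List[tuple],
    weights: np.ndarray,
    inside_structure: bool,
) -> tuple:
    """Rejection-sample a crystal center (z, y, x) in um."""
    geom = cfg.geometry
    field_um = geom.field_um
    lo = r_lat + 2 * geom.pixel_size_um
    hi = field_um - lo
    if hi <= lo:
        raise GeometryError("field too small for crystal placement")
    slice_ids = np.arange(1, geom.n_slices + 1)
    for _attempt in range(300):
        k = int(rng.choice(slice_ids, p=weights))
        z = k * geom.step_um + rng.uniform(-0.5, 0.5) * geom.step_um
        if inside_structure:
            yc, xc = papillae[int(rng.integers(len(papillae)))]
            rad = (0.6 * cfg.papilla_radius_um - r_lat) * np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            y = yc + rad * np.sin(ang)
            x = xc + rad * np.cos(ang)
            if not (lo <= y <= hi and lo <= x <= hi):
                continue
        else:
            y = rng.uniform(lo, hi)
            x = rng.uniform(lo, hi)
            clear = cfg.papilla_radius_um + cfg.clear_margin_um + r_lat
            if any((y - yc) ** 2 + (x - xc) ** 2 < clear**2 for yc, xc in papillae):
                continue
        if all(
            (z - z0) ** 2 + (y - y0) ** 2 + (x - x0) ** 2 >= cfg.min_separation_um**2
            for z0, y0, x0 in placed
        ):
            return z, y, x
    raise GeometryError("cannot place crystal: field too crowded")


def simulate_stack(config: SimConfig, meta: Optional[dict] = None):
    """Generate one synthetic z-stack with exact ground truth.

    Returns ``(ImageStack, GroundTruth)``.  Deterministic given
    ``config.seed``; ground truth (masks, per-crystal volumes) is recorded
    before attenuation and noise are applied; voxels are quantized to
    uint16 as a detector would.
    """
    cfg = config
    geom = cfg.geometry
    rng = np.random.default_rng(cfg.seed)
    npx = int(round(geom.field_um / geom.pixel_size_um))
    band = cfg.resolved_band()
    band.validate_for(geom)
    weights = cfg.resolved_depth_profile()

    img = np.full((geom.n_slices, npx, npx), cfg.background_level, dtype=np.float32)
    structure_mask = np.zeros(img.shape, dtype=bool)
    crystal_mask = np.zeros(img.shape, dtype=bool)

    # --- papillae: bright annular tubes spanning the band ---------------
    papillae = _place_papillae(cfg, rng)
    if papillae:
        px = geom.pixel_size_um
        coords = (np.arange(npx) + 0.5) * px
        yy, xx = np.meshgrid(coords, coords, indexing="ij")
        ring = np.zeros((npx, npx), dtype=bool)
        disk_mask = np.zeros((npx, npx), dtype=bool)
        for yc, xc in papillae:
            d2 = (yy - yc) ** 2 + (xx - xc) ** 2
            disk_mask |= d2 <= cfg.papilla_radius_um**2
            ring |= (d2 <= cfg.papilla_radius_um**2) & (
                d2 >= (cfg.papilla_radius_um - cfg.papilla_wall_um) ** 2
            )
        for k in band.indices():
            img[k - 1][ring] = np.maximum(img[k - 1][ring], cfg.structure_level)
            structure_mask[k - 1] |= disk_mask

    # --- crystals --------------------------------------------------------
    per_crystal: List[PlantedCrystal] = []
    placed_centers: List[tuple] = []
    voxel_vol = geom.voxel_volume_um3

    def plant(inside_structure: bool, crystal_id: int) -> PlantedCrystal:
        r_lat = float(
            np.clip(
                rng.normal(cfg.crystal_radius_mean_um, cfg.crystal_radius_sd_um),
                0.4,
                4.0,
            )
        )
        r_ax = r_lat * rng.uniform(0.8, 1.2)
        center = _sample_crystal_center(
            cfg, rng, r_lat, papillae, placed_centers, weights, inside_structure
        )
        placed_centers.append(center)
        zi, yi, xi = _voxelize_ellipsoid(cfg, center, r_lat, r_ax)
        img[zi, yi, xi] = np.maximum(img[zi, yi, xi], cfg.crystal_level)
        crystal_mask[zi, yi, xi] = True
        return PlantedCrystal(
            id=crystal_id,
            centroid_um=center,
            voxel_count=len(zi),
            volume_um3=len(zi) * voxel_vol,
            inside_structure=inside_structure,
        )

    next_id = 1
    if cfg.target_isolated_volume_um3 is not None:
        total = 0.0
        while total < cfg.target_isolated_volume_um3:
            c = plant(False, next_id)
            per_crystal.append(c)
            total += c.volume_um3
            next_id += 1
        n_iso = len(per_crystal)
        f = cfg.fraction_in_structure
        n_conf = int(round(f / (1 - f) * n_iso)) if (f < 1 and cfg.n_papillae) else 0
    else:
        n_conf = int(round(cfg.fraction_in_structure * cfg.n_crystals))
        if cfg.n_papillae == 0:
            n_conf = 0
        n_iso = cfg.n_crystals - n_conf
        for _ in range(n_iso):
            per_crystal.append(plant(False, next_id))
            next_id += 1
    for _ in range(n_conf):
        per_crystal.append(plant(True, next_id))
        next_id += 1

    # --- epidermal speckle above the band -------------------------------
    field_mm2 = (geom.field_um / 1000.0) ** 2
    px = geom.pixel_size_um
    for k in range(1, band.first_slice):
        n_spk = rng.poisson(cfg.epidermal_speckle_rate * field_mm2)
        for _ in range(n_spk):
            r = rng.uniform(0.8, 1.8)
            yc = rng.uniform(r, geom.field_um - r)
            xc = rng.uniform(r, geom.field_um - r)
            i_lo = max(0, int((yc - r) / px - 0.5))
            i_hi = min(npx - 1, int((yc + r) / px + 0.5))
            j_lo = max(0, int((xc - r) / px - 0.5))
            j_hi = min(npx - 1, int((xc + r) / px + 0.5))
            ii, jj = np.meshgrid(
                np.arange(i_lo, i_hi + 1), np.arange(j_lo, j_hi + 1), indexing="ij"
            )
            m = ((ii + 0.5) * px - yc) ** 2 + ((jj + 0.5) * px - xc) ** 2 <= r**2
            img[k - 1, ii[m], jj[m]] = np.maximum(
                img[k - 1, ii[m], jj[m]], cfg.speckle_level
            )

    # --- depth attenuation, detector noise, quantization ----------------
    depths = np.arange(1, geom.n_slices + 1) * geom.step_um
    img *= np.exp(-cfg.attenuation_per_um * depths)[:, None, None].astype(np.float32)
    if cfg.noise_sd > 0:
        noise_rng = (
            rng if cfg.noise_seed is None else np.random.default_rng(cfg.noise_seed)
        )
        img += cfg.noise_sd * noise_rng.standard_normal(img.shape, dtype=np.float32)
    voxels = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    true_volume = float(
        sum(c.volume_um3 for c in per_crystal if not c.inside_structure)
    )
    stack_meta = {"seed": cfg.seed}
    if meta:
        stack_meta.update(meta)
    stack = ImageStack(
        voxels=voxels,
        geometry=AcquisitionGeometry(
            pixel_size_um=geom.pixel_size_um,
            step_um=geom.step_um,
            n_slices=geom.n_slices,
            field_um=npx * geom.pixel_size_um,
        ),
        meta=stack_meta,
    )
    truth = GroundTruth(
        crystal_mask=crystal_mask,
        structure_mask=structure_mask,
        true_crystal_volume_um3=true_volume,
        per_crystal=per_crystal,
        band=band,
    )
    return stack, truth


#: Cohort volume targets (um^3) for patient-like and control-like stacks.
PATIENT_LOAD = (1934.0, 1169.1)
CONTROL_LOAD = (363.1, 194.3)


@dataclass
class CohortSubject:
    subject_id: str
    group: str  # "patient" | "control"
    stack: ImageStack
    ground_truth: GroundTruth
    target_volume_um3: float


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw from N(mean, sd) truncated to (0, inf) by rejection."""
    for _ in range(10000):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    raise RuntimeError("truncated-normal rejection failed; check mean/sd")


def simulate_cohort(
    n_patients: int,
    n_controls: int,
    patient_load: tuple = PATIENT_LOAD,
    control_load: tuple = CONTROL_LOAD,
    base: Optional[SimConfig] = None,
    seed: int = 0,
) -> List[CohortSubject]:
    """Simulate a patient/control cohort with group-specific crystal loads.

    Each subject's true isolated crystal volume target is drawn from a
    normal distribution truncated at zero (printed cohort spreads would
    otherwise allow negative volumes for controls), and crystals are
    planted until the target is met.  Deterministic given ``seed``.
    """
    if n_patients < 0 or n_controls < 0 or n_patients + n_controls == 0:
        raise ValueError("need nonnegative group sizes with at least one subject")
    for name, (m, s) in (("patient_load", patient_load), ("control_load", control_load)):
        if m <= 0 or s <= 0:
            raise ValueError(f"{name} mean and sd must be positive")
    base = base or SimConfig()
    rng = np.random.default_rng(seed)
    subjects: List[CohortSubject] = []
    groups = [("patient", patient_load, f"P{i + 1:02d}") for i in range(n_patients)]
    groups += [("control", control_load, f"C{i + 1:02d}") for i in range(n_controls)]
    for group, (mean, sd), sid in groups:
        target = _truncated_normal(rng, mean, sd)
        sub_seed = int(rng.integers(2**31))
        cfg = base.with_overrides(
            target_isolated_volume_um3=target, seed=sub_seed
        )
        stack, truth = simulate_stack(
            cfg, meta={"subject_id": sid, "group": group}
        )
        subjects.append(
            CohortSubject(
                subject_id=sid,
                group=group,
                stack=stack,
                ground_truth=truth,
                target_volume_um3=target,
            )
        )
    return subjects
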