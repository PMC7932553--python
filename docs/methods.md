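# Methods

## Coordinate and depth conventions

Slices are numbered 1-based in acquisition order (shallowest first) and
`depth(k) = k × step_um`: the first slice lies one axial step below the
contact surface. With the standard 2.8 µm step this is the only affine
convention that places slice 15 at 42 µm and slice 50 at 140 µm, the
papillary-dermis band quoted for the method. The lateral field is a
750 µm square by default; pixel size is an acquisition-setup parameter
(0.5 µm/px assumed when no sidecar metadata is present) and is never
inferred from image content. Intensities are unitless reflectance counts;
no absolute calibration is attempted.

## Segmentation model

Crystals appear as small, locally bright objects; dermal papillae as
large bright annuli around a dark capillary lumen. Detection is therefore
two-scale:

* **Candidates.** Each slice is background-flattened with a white top-hat
  whose structuring element matches the upper crystal size scale
  (radius `sqrt(crystal_area_max / π)`). The element is a square applied
  as separable min/max filters — equivalent to a disk for this purpose
  (flat fields map to zero, sub-element objects are preserved) and an
  order of magnitude faster. Pixels are kept where their robust z-score —
  against the slice median and MAD — exceeds `bright_z_min`; this makes
  detection invariant to session-to-session gain. Components
  (8-connected) are formed on the **union** of the flattened and raw
  brightness masks: the union keeps the top-hat rim of any object larger
  than the structuring element attached to its parent region, so oversized
  bright structures are removed whole by the area gate
  (`crystal_area_min ≤ area ≤ crystal_area_max`) instead of leaking rim
  fragments as spurious "small" objects. When the MAD is zero (noiseless
  synthetic input) the threshold degrades to "strictly brighter than the
  median", and an empty slice yields an empty region set, not an error.
* **Structure.** The slice is Gaussian-smoothed at
  `structure_smooth_sigma_um`, thresholded by Otsu, morphologically
  closed, hole-filled (papilla cross-sections are rings; the structure is
  the whole papilla, lumen included, which is essential for excluding
  crystals planted in the lumen), and size-gated at
  `structure_area_min_um2`. Otsu always finds *some* split, so a
  **contrast gate** declares a slice structure-free when the foreground /
  background contrast of the split is below `structure_contrast_min`
  robust sigmas of the raw slice. The default of 2.0 sits between the
  ~1–2 sigma contrast Otsu extracts from pure noise and the ≥ ~4 sigma
  contrast of a papilla ring at the deep end of the band under the default
  attenuation.
* **Exclusion.** A candidate overlapping any structure pixel is removed
  (`any_pixel` rule; `centroid_inside` and `fraction` variants are
  available). Exclusion can only remove candidates, never add area.

All thresholds are configuration values. The exact cut-offs used by the
original commercial-software macro are not public; the defaults here
(`bright_z_min = 4`, areas 1–150 µm², smoothing 5 µm, structure
≥ 500 µm²) were fixed on the bundled simulator and are expected to be
overridden per acquisition setup from config/CLI.

## Quantification and the nCCV convention

The per-slice profile reports summed isolated-crystal area normalized to
the analyzed area (field minus detected structure) at every slice —
structure is subtracted in 2D for consistency with the 3D normalization.
For nCCV, the band's isolated-crystal masks are stacked and labeled with
26-connectivity: the axial step (2.8 µm) exceeds the pixel size, so
conservative diagonal linking avoids fragmenting single crystals across
slices. Voxel anisotropy enters only the volume (`pixel² × step`), never
the connectivity. Volume identities hold exactly by construction: the 3D
crystal volume equals the summed band crystal areas × step.

Several normalizations are compatible with a µm³-valued statistic; the
one implemented is

    nCCV = V_crystal × V_ref / V_analyzed,   V_ref = field² × band depth,

isolated in `compute_nccv`. It preserves the µm³ unit, reduces to the raw
crystal volume for a structure-free standard acquisition, and makes
stacks with different papilla content comparable (a stack whose analyzed
volume is halved by structure gets its density extrapolated to the full
reference volume). Slices outside the band contribute to the 2D profile
but never to nCCV — the epidermis carries high unspecific background and
the deep dermis low clarity, which is the rationale for the 15–50 band.
If structure covers the entire band the statistic is undefined and an
error is raised.

## Simulator

The generator emulates the standard acquisition: 78 slices, 2.8 µm step,
square field. Planted objects:

* **Crystals** — ellipsoids (lateral radius ~ N(1.5, 0.5²) µm clipped to
  [0.4, 4], axial radius ×U(0.8, 1.2)), voxelized on the acquisition grid;
  ground-truth volume is the voxel count × voxel volume, exactly the
  discretization the pipeline measures. Real cystine crystals are
  irregular; ellipsoids are used because the volume ground truth must be
  exact and the pipeline uses no shape prior. Depth placement follows a
  unimodal profile peaked mid-band and zero outside it (crystal
  accumulation is maximal in the papillary dermis). Crystal intensity
  (160) sits above structure (80) and background (20); detector noise is
  Gaussian (sd 4) and intensity decays exponentially with depth
  (0.004/µm), both applied after ground truth is recorded; voxels are
  quantized to uint16.
* **Papillae** — bright annular tubes (radius 30 µm, wall 6 µm) spanning
  the band. A configurable fraction of crystals (default 0.2) is planted
  *inside* papillae (within 0.6 of the radius) as confounders the
  exclusion rule must remove. Isolated crystals keep a 12 µm lateral
  clearance from papilla rims — the detected structure boundary extends
  roughly one smoothing sigma plus the closing radius beyond the planted
  rim, so this margin is what makes "isolated" in the ground-truth sense
  match "isolated" in the pipeline sense. Crystal centres keep a minimum
  3D separation of 8 µm so planted objects never merge.
* **Epidermal speckle** — unspecific bright dots (as occasionally seen in
  healthy skin) confined to the slices above the band, at a default
  density of 100/mm² per slice. At desk-scale fields this deliberately
  rivals or exceeds the in-band per-slice crystal signal, giving the band
  restriction a real failure mode to defend against: profiles may peak in
  the epidermis, but flagged group differences and nCCV must stay
  band-confined.

Cohorts draw per-subject target volumes from normal distributions
truncated at zero (patients 1934 ± 1169 µm³, controls 363 ± 194 µm³ —
the spreads would otherwise allow negative volumes) and plant isolated
crystals until the voxelized volume meets the target, so a subject's true
volume overshoots its target by at most one crystal. A separate
`noise_seed` re-acquires the same planted field with independent detector
noise for repeatability studies. Everything is bit-reproducible given the
seed.

What the simulator does **not** model: physical RCM speckle statistics
and optics, collagen texture, irregular crystal shapes, motion between
slices, and pigmentation differences. Passing tests therefore demonstrate
correctness of the measurement and statistics machinery under controlled
conditions, not segmentation robustness on real dermatological imagery —
thresholds will need per-device calibration there.

## Statistics

* Per-slice comparison: two-sample Welch test at every slice with Šidák
  familywise control (`α' = 1 − (1−α)^(1/m)`), rather than a literal
  two-factor ANOVA decomposition — the target quantity is the mean
  patient/control difference at each slice, and the repeated-measures
  factorial structure is not identified in this design. Zero-variance
  slices with equal means are treated as p = 1.
* Group test: Welch by default (pooled-variance optional); patient and
  control nCCV spreads differ severalfold, where pooled variance is
  inappropriate. The all-constant degenerate case is flagged with the
  p = 1 / p = 0 convention.
* ROC: AUC as Mann–Whitney U / (n₁n₀) with tied pairs counting ½; CI by
  seeded stratified bootstrap (2000 resamples), since no analytic CI
  method is canonical here.
* Associations: logistic (binary) or OLS (continuous) with nCCV z-scored
  within the analyzed subset, effects reported per 1 SD with Wald 95% CI
  and chi-square. CKD stage is modeled linear-in-stage by OLS (matching a
  slope-style estimate; ordinal regression is the alternative not taken).
  Pre-specified covariate sets: CKD adjusted for age + eGFR among
  transplant-free subjects; hypothyroidism adjusted for sex, ages ≥ 9.
  Missing data are handled by listwise deletion per model with the
  analyzed n reported; no correction is applied across the outcome panel.
  Complete (quasi-)separation is detected (failed fit or exploding
  standard error) and flagged rather than raised.
* Repeatability: CV = 100 × sample SD / mean. Clinical helpers: granulocyte
  cystine = 1.95 × leukocyte cystine; bedside Schwartz
  eGFR = 0.413 × height[cm] / creatinine[mg/dL] (the constant comes from
  the Schwartz reference publication).

## Problem sizes in the test suite

Synthetic stacks in the suite keep the full axial sampling (78 slices,
2.8 µm) but reduced lateral fields: 240 µm for volume-accuracy and
cohort-discrimination work, 120 µm for profile/cohort and repeatability
work, with one papilla per stack (structure area fraction ~5%, close to
the ~3% of a standard 6-papillae/750 µm scene). The desk-scale pixel size
is 0.75 µm/px rather than the acquisition default 0.5 µm/px; it was
chosen so the 1 µm² candidate area gate still spans ≥ 2 pixels, which
preserves the single-pixel noise immunity the defaults have at full
resolution. Volume-recovery runs use 20 stacks (seeds 0–19), exclusion
and repeatability runs 10 seeds, band-defense runs 10 cohorts of 15 + 15,
discrimination one 25 + 25 cohort, and the association coverage check 500
simulated datasets of n = 200.

## Known limitations

* The nCCV normalization convention is one of several compatible with the
  printed unit; cross-study comparisons require using the same convention
  (it is isolated in one function for that reason).
* Sub-resolution crystals (single-voxel, below the area gate) are
  invisible to the pipeline; they carry negligible volume but cap
  detection recall below 100%.
* Structure detection assumes papillae are the dominant coarse-scale
  bright structure; heavily pigmented skin (excluded from the original
  study design) is not modeled or corrected.
* Under the calibrated group loads the true patient/control AUC is ≈ 0.95;
  an empirical 25 + 25 cohort AUC fluctuates around that value by ±0.03,
  so single-cohort AUC thresholds near 0.95 are seed-sensitive.
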