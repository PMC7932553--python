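# nccv — automated intradermal crystal quantification from RCM z-stacks

Cystinosis is a lysosomal storage disorder in which cystine crystallizes
inside tissues. Crystals accumulate in the skin over years, and in-vivo
reflectance confocal microscopy (RCM) can see them without a biopsy: a
handheld device acquires en-face slices at successive depths (a z-stack,
typically 78 slices at a 2.8 µm axial step over a 750 µm square field),
from the epidermis down through the papillary dermis.

This package implements the full automated quantification pipeline on such
stacks, for imaging scientists and clinical researchers who want a
reproducible crystal burden readout:

1. **Bright-object detection** — per slice, all small bright objects are
   selected (white top-hat background flattening, robust median/MAD
   z-score threshold, in-plane area gate).
2. **Skin-structure exclusion** — dermal papillae, the bright ring-like
   structures that cause false positives, are detected at a coarser scale
   (Gaussian smoothing, Otsu threshold, closing + hole filling, size gate)
   and any candidate overlapping them is eliminated, leaving isolated
   crystals.
3. **Depth-resolved profiling** — per slice, summed isolated-crystal area
   normalized to the analyzed area (field minus structure), as a function
   of tissue depth (`depth = slice_index × step`; slices 15–50 span
   42–140 µm, the papillary dermis).
4. **3D reconstruction and nCCV** — band masks are stacked, 3D connected
   components (26-connectivity) give the summed crystal volume, and the
   **normalized confocal crystal volume** is

   `nCCV = V_crystal × V_ref / V_analyzed`  [µm³]

   where `V_analyzed` is the band volume excluding skin structure and
   `V_ref = field² × band depth` is the nominal reference volume, so nCCV
   is a structure-corrected crystal volume that reduces to the raw crystal
   volume on a structure-free acquisition.
5. **Statistics** — per-slice patient/control comparison with Šidák
   familywise control, Welch t-test on nCCV, ROC/AUC with stratified
   bootstrap CI, Pearson/Spearman correlation, logistic/linear association
   models per 1 SD of nCCV, repeatability CV, and clinical helpers
   (leukocyte→granulocyte cystine ×1.95, bedside Schwartz eGFR).
6. **Simulator** — synthetic stacks with voxel-exact ground truth:
   ellipsoidal crystals planted with a band-peaked depth profile, annular
   papillae, in-papilla confounder crystals, epidermal speckle, depth
   attenuation and detector noise. Every pipeline stage is validated
   against it.

## Worked example

Simulate a patient-like and a control-like stack (full 78-slice axial
sampling on a reduced 240 µm desk-scale field) and quantify them:

```python
from nccv import AcquisitionGeometry, SimConfig, simulate_stack, compute_nccv

geom = AcquisitionGeometry(pixel_size_um=0.75, step_um=2.8,
                           n_slices=78, field_um=240.0)
for name, load, seed in [("patient", 1934.0, 1), ("control", 363.1, 2)]:
    cfg = SimConfig(geometry=geom, target_isolated_volume_um3=load,
                    n_papillae=1, seed=seed)
    stack, truth = simulate_stack(cfg)
    res = compute_nccv(stack)
    print(name, round(truth.true_crystal_volume_um3, 1), round(res.nccv_um3, 1),
          len(res.components))
```

prints

```
patient 1967.2 2087.7 98
control 370.1 391.6 21
```

i.e. the planted patient stack (true isolated crystal volume 1967 µm³)
yields nCCV ≈ 2088 µm³ in 98 3D components, the control stack
(370 µm³) yields ≈ 392 µm³ in 21 components — recovery within the ~6%
upward rescaling expected from the papilla volume excluded from
`V_analyzed`. The 2D depth profile of the same stacks peaks in the
epidermal slices, where unspecific bright speckle dominates; that signal
never enters nCCV because only slices 15–50 are reconstructed in 3D —
that is the point of the band restriction.

Unit conversions behave as a clinician would expect:

```python
>>> from nccv import granulocyte_from_leukocyte, egfr_schwartz
>>> granulocyte_from_leukocyte(1.14)
2.223
>>> round(egfr_schwartz(140, 0.9), 1)
64.2
```

## Command line

```
nccv simulate --out sim/ --n-patients 25 --n-controls 25 --seed 1
nccv quantify sim/*.tif --out quant/
nccv stats quant/summary.csv --out stats/
```

`simulate` writes per-subject TIFF+sidecar pairs, ground-truth JSON, a
cohort CSV and a content-hash manifest; `quantify` writes per-stack nCCV
JSON, per-slice profile CSVs and a summary CSV; `stats` writes group
t-test/ROC results and association-model tables. Every command records
its effective configuration next to its outputs and is deterministic
given `--seed`.

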