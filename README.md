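# cortmag

Cortical magnification and contrast-sensitivity asymmetries around the
visual field, on fully synthetic data.

Human visual performance is not uniform around fixation: at a fixed
eccentricity, contrast sensitivity is higher on the horizontal than the
vertical meridian (the horizontal-vertical anisotropy, HVA) and higher on
the lower than the upper vertical meridian (the vertical-meridian
asymmetry, VMA).  Primary visual cortex shows matching asymmetries in how
much surface area it devotes to each part of the visual field (cortical
magnification).  `cortmag` is a tested, reusable implementation of the
analysis chain that links the two:

- **Synthetic cortices** — triangulated V1 hemisphere meshes whose local
  areal expansion follows `M0·(A/(ecc+e2))²·(1 + α·cos2θ − γ·sinθ)`, with
  planted, analytically exact HVA/VMA asymmetries and per-vertex ground
  truth retinotopy.
- **pRF mapping** — the sweeping-bar aperture stimulus, a 2-D Gaussian
  population-receptive-field forward model with a difference-of-gammas
  HRF, BOLD simulation, and coarse-to-fine estimation of (x, y, σ) with an
  R² > 10% inclusion gate.
- **Wedge-ROIs** — cortical distance maps from meridian line-ROIs,
  log-spaced eccentricity bands, iso-angle boundary estimation by pooled
  pRF angles, and surface-area summation for ±15°, 1–8° wedges at a chosen
  cortical depth.
- **Psychophysics** — Weibull 2AFC observers measured with four randomly
  interleaved 3-down-1-up PEST staircases (50 trials per location, five
  blocks), thresholds averaged across blocks, sensitivity = 1/threshold.
- **Statistics** — HVA/VMA percentage indices (difference over mean,
  ×100), pooled one-tailed Spearman correlations between sensitivity and
  local surface area, two quadruple-shuffle null distributions with their
  95th percentiles (x₀.₉₅), observer/location centering, V1-size
  normalization, and paired t-tests.

Everything runs from a single seed with no external downloads; an
interchange CSV schema also accepts real per-observer tables.

## Worked example

```python
import cortmag as cm

model = cm.MagnificationModel.from_asymmetries(hva=60.0, vma=25.0)
per_hemi = {}
for hemi in ("left", "right"):
    mesh = cm.make_synthetic_hemisphere(model, hemisphere=hemi)
    per_hemi[hemi], _ = cm.measure_wedge_areas(mesh)

combined = cm.combine_meridian_areas(per_hemi["left"], per_hemi["right"])
print(round(cm.hva_index(combined["HM"], combined["VM"]), 1))
print(round(cm.vma_index(combined["LVM"], combined["UVM"]), 1))
```

prints

```
60.0
25.0
```

— the full wedge-ROI measurement chain (meridian line-ROIs → geodesic
distance maps → per-band iso-angle boundaries → mask union → area
summation, across both hemispheres) recovers the planted 60% HVA and 25%
VMA surface-area asymmetries.  The `examples/` directory has one short
script per capability:

| script | shows |
| --- | --- |
| `01_bar_stimulus_and_prf_fit.py` | forward model + coarse-to-fine pRF recovery |
| `02_wedge_roi_magnification.py` | wedge-ROI areas vs planted asymmetries |
| `03_staircase_contrast_sensitivity.py` | staircase thresholds vs planted thresholds |
| `04_cohort_asymmetry_statistics.py` | indices, pooled ρ, shuffle nulls |
| `05_full_pipeline.py` | end-to-end run with recovery diagnostics |

A thin CLI mirrors the pipeline stages
(`cortmag synth-cortex | synth-cohort | staircase-sim | stats | run-all`).

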