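# srsquant

Quantitative analysis of **two-band stimulated Raman scattering (SRS)
images** and companion **flow-cytometry data** for detecting
radiation-induced lipid changes in cultured cancer cells.

SRS microscopy images the C–H stretch region label-free: at 2850 cm⁻¹ the
lipid CH₂ stretch dominates, at 2926 cm⁻¹ protein contributes strongly.
Because SRS signal is linear in concentration, a two-band image pair can be
decomposed into lipid and protein maps, lipid droplets segmented, and
per-cell morphometrics compared between irradiated (30 Gy) and control
(0 Gy) dishes over a post-irradiation time course. The package implements
that whole chain, plus the flow-cytometry lipid-peroxidation statistic,
for imaging scientists and radiobiology labs who want the analysis to be
reproducible and testable — every stage can be exercised against synthetic
phantoms with known ground truth, no microscope required.

## The pipeline

1. **Calibration** — the delay-line position of a spectral-focusing SRS
   system is mapped to Raman shift by a linear fit through calibrant peaks
   (DMSO: 2914/2998 cm⁻¹; polystyrene: 2852/2904 cm⁻¹), with
   multi-Lorentzian sub-sample peak refinement.
2. **Unmixing (MCR)** — frames are averaged per band and each pixel solved
   by exact nonnegative least squares against min-max-normalised
   pure-component reference spectra (oleic acid ≙ lipid, BSA ≙ protein):
   `c(x) = argmin_{c≥0} ‖I(x) − Sᵀc‖²`. A free-spectra MCR-ALS mode exists
   for >2 bands.
3. **Segmentation** — lipid droplets via *iterative* Otsu thresholding
   (each pass re-thresholds the pixels above the current threshold,
   climbing background → cytoplasm → droplets, with a mode-separation
   criterion deciding when to stop); cell area via single Otsu on the
   protein map.
4. **Quantification** — per region: LD area/cell, total lipid and protein
   intensity/cell, cell area/cell (area = mask pixels × 22.5 μm²/pixel by
   default, divided by the region's cell count).
5. **Statistics** — two-sided Wilcoxon rank-sum per timepoint (exact
   enumeration for pooled n ≤ 12 without ties, tie-corrected normal
   approximation otherwise), annotated ns/*/**/***/****.
6. **Flow cytometry** — polygon gating (cells, then singlets on
   SSC-H vs SSC-A), MFI, and the relative peroxidation increase
   `|MFI₃₀ − MFI₀| / MFI₀ × 100`.

Scientific details, defaults and limitations: [docs/methods.md](docs/methods.md).

## Worked example

Generate a synthetic imaging batch — 10 regions per arm, with a 1.5× lipid
-droplet-area effect programmed into the 30 Gy arm — and run the full
analysis:

```bash
srsquant simulate --outdir demo --seed 1 --regions-per-arm 10
srsquant run --config demo/config.yaml --outdir demo/results
```

which prints:

```
wrote 20 phantom regions under demo
20 regions processed, 0 skipped
  ld_area_per_cell @ 72.0 h: p=0.0001827 (***)
  lipid_intensity_per_cell @ 72.0 h: p=0.007285 (**)
  protein_intensity_per_cell @ 72.0 h: p=0.5708 (ns)
  cell_area_per_cell @ 72.0 h: p=0.5708 (ns)
```

The programmed droplet effect is detected (LD area ***; total lipid
intensity ** — droplets carry lipid signal), while protein intensity and
cell area, which carry no programmed effect, stay non-significant.
`demo/results/` holds the per-region measurements
(`measurements.csv`, first rows below), the per-metric test tables, the
unmixed maps and masks as TIFF, and a JSON run log recording every applied
threshold, iteration count and band assignment:

```
region_id,condition,timepoint,n_cells,ld_area_per_cell,lipid_intensity_per_cell,...
0Gy_r00,0 Gy,72.0,8,1909.6875,1151.6875402682717,...
0Gy_r01,0 Gy,72.0,8,1971.5625,1096.9250973784729,...
```

(LD area/cell here is ~1900 μm² on the default 22.5 μm²/pixel scale.)

The same stages are available as library functions:

```python
from srsquant import (PhantomSpec, generate_srs_stack, average_frames,
                      default_pure_spectra, mcr_als_unmix,
                      iterative_otsu_ld_mask, ld_area_per_cell)

stacks, truth = generate_srs_stack(PhantomSpec(seed=1))
maps = mcr_als_unmix([average_frames(s) for s in stacks],
                     default_pure_spectra())
mask = iterative_otsu_ld_mask(maps.component("lipid"))
print(ld_area_per_cell(mask, 22.5, truth.n_cells_true))  # μm² per cell
```

The flow-cytometry side works the same way (`simulate-flow`, `flow` verbs,
or `srsquant.flow` functions).

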