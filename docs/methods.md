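# Methods

`srsquant` implements the quantitative analysis chain for detecting
radiation-induced lipid changes in cultured cells from two-band stimulated
Raman scattering (SRS) imaging, together with the companion flow-cytometry
lipid-peroxidation statistic. This note documents the models, the defaults
and why they were chosen, the numerical choices, and what the synthetic
phantoms do and do not establish.

## Imaging model and unmixing

SRS signal is linear in molecular concentration, so a pixel imaged at band
*b* (cm⁻¹) is modelled as

    I(x, b) = Σ_k C_k(x) · S_k(b) + ε,    k ∈ {lipid, protein}

where `C_k ≥ 0` are the per-component concentration maps and `S_k(b)` are
pure-component reference intensities — oleic acid standing in for cellular
lipid and BSA for protein — read off min-max-normalised spectra at the two
acquisition bands, 2850 cm⁻¹ (lipid CH₂ stretch) and 2926 cm⁻¹ (mixed
CH₂/CH₃ with strong protein contribution). The built-in reference matrix is

    S = [[1.00, 0.55],   # oleic acid at (2850, 2926)
         [0.30, 1.00]]   # BSA

on the normalised [0, 1] scale; these values reflect the qualitative shape
of the two spectra in the C–H stretch region (oleic acid peaking at 2850
with roughly half intensity at 2926; BSA peaking near 2930 with a weak CH₂
shoulder) and can be replaced by measured spectra via `PureSpectra`.

Ten frames per band are averaged before unmixing. Unmixing solves, per
pixel, the nonnegative least-squares problem `min_{c≥0} ‖I(x) − Sᵀc‖²`.
With two bands and two components there is no spectral freedom, so the
default `fixed_spectra` mode holds S at the references; this is exact
active-set enumeration (all supports of the K components are tried and the
feasible minimum taken), vectorised over pixels. A `free_spectra` mode is
provided for acquisitions with more bands than components: classical
MCR-ALS alternation between nonnegative C and S updates, initialised at the
references, with each component spectrum rescaled to unit maximum per
iteration (the scale is absorbed into C, so the rescaling cannot increase
the residual and the total squared residual is non-increasing across
iterations). Convergence: relative residual change < 1e-8 or 500
iterations; an exactly fitting (noise-free) solution also terminates.
Negative raw intensities from lock-in noise are accepted as-is — NNLS clips
at zero; there is no pre-clipping, which would bias the background.

Band labels on images are matched to reference bands by nearest wavenumber
within ±5 cm⁻¹, absorbing day-to-day calibration drift.

## Raman-axis calibration

Spectral focusing selects the probed Raman shift via the pump–Stokes delay,
so delay-line position must be mapped to wavenumbers. The map is linear and
is fitted by ordinary least squares through (peak position, known shift)
pairs from calibrant scans: DMSO (2914, 2998 cm⁻¹) and polystyrene (2852,
2904 cm⁻¹). Points from both substances may be pooled into one four-point
fit. Peak positions are found as prominent local maxima and refined below
sample resolution; two refinements are available:

* **quadratic** (default for `detect_peaks`): parabola through the maximum
  and its neighbours — adequate for isolated peaks;
* **lorentzian** (used by `calibrate_from_scans`): a joint least-squares
  fit of a sum of Lorentzians plus a constant baseline, initialised at the
  quadratic estimates. With ~28 cm⁻¹ FWHM peaks spaced 52–84 cm⁻¹ apart,
  each peak's tail pulls the other's local maximum inward by ~0.06 cm⁻¹,
  biasing the fitted slope by ~1.5×10⁻³ relative; the joint fit removes
  this bias (recovery to ~1e-11 relative on noiseless scans).

## Lipid-droplet and cell segmentation

The droplet mask comes from Otsu thresholding applied iteratively to the
lipid map. Otsu's threshold maximises between-class variance over a
256-bin histogram spanning [min, max]; the returned threshold is a bin
edge, ties broken toward the lowest edge, foreground is strictly above the
threshold — fully deterministic. Iteration 1 thresholds the whole map
(splitting background from cells); each later pass re-runs Otsu on only the
pixels above the current threshold, climbing the intensity modes toward the
droplets. Successive masks are nested by construction (each new threshold
exceeds the previous one).

Stopping was a genuinely open design point: visual comparison against the
unmixed images is not reproducible, and a pure relative-change/max-iteration
rule keeps climbing into the droplet mode itself once all real modes are
exhausted, splitting droplet noise and destroying the mask (measured Dice
≈ 0.08 on 3:1-contrast phantoms). The package therefore accepts a pass only
if it is a genuine mode separation, measured by Otsu's effectiveness

    η = between-class variance / total variance of the restricted pixels.

Splitting a single Gaussian noise mode at its optimum yields η ≈ 2/π ≈
0.64, while separating distinct intensity modes on these images yields
η ≳ 0.9; the default cutoff is 0.75. Remaining stops: relative threshold
change < 1% (configurable), max 5 passes, mask emptying or a degenerate
restricted histogram (previous mask returned with a warning). The full
threshold trace is recorded on the mask and in the run log so any choice
can be audited or reproduced by eye.

The cell-area mask is a single Otsu pass on the protein map, with the same
η ≥ 0.75 guard as a negative control: an image with no real contrast (pure
noise) returns an empty mask with a warning rather than marking ~half of
its pixels. No morphological post-processing is applied by default; an
optional minimum-droplet-size filter (connected components, pixels) exists
for noisy data.

## Per-cell metrics

All metrics are region-level totals divided by the region's cell count:
LD area per cell = droplet-mask pixels × pixel area / n_cells; cell area
per cell likewise on the protein mask; total lipid and protein intensity
per cell = concentration-map sums / n_cells. The pixel area defaults to
22.5 μm² per pixel, the pipeline-wide constant used for all published-style
area figures. **Caveat:** 22.5 μm²/pixel is difficult to reconcile with a
40×/0.8 NA objective at 512×512 sampling (a ~0.2 μm² value would be more
typical); the constant is configurable everywhere and only rescales area
units — it affects no comparison or p-value. Cell counts are supplied per
region in the manifest (phantoms supply the true count); a
connected-component fallback estimator exists but is never used silently.

## Statistics

Irradiated (30 Gy) and control (0 Gy) region metrics are compared per
timepoint with the two-sided Wilcoxon rank-sum test on pooled ranks
(average ranks for ties). With pooled n ≤ 12 and no ties the null
distribution of the rank sum is enumerated exactly (all C(n_x+n_y, n_x)
assignments); otherwise a normal approximation is used with tie-corrected
variance and a 0.5 continuity correction; two-sided p = min(1, 2 × smaller
tail). At the workflow's typical n = 10 regions per arm the approximate
path is operative; the exact path doubles as an oracle-verifiable surface.
Identical pooled values give p = 1 with a warning. P-values map to the
conventional stars (* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001,
strict inequalities). No multiplicity adjustment is applied by default,
matching the single-comparison-per-timepoint design; Bonferroni and
Benjamini–Hochberg options are available.

## Flow cytometry

Gating is the standard two-step scheme, applied with identical stored
polygons across every table in a batch: a polygon on FSC-A/SSC-A isolates
cells from debris, then a polygon on SSC-A/SSC-H keeps singlets (doublets
carry ~2× the area at the same pulse height). Events exactly on a polygon
edge are retained — a deterministic, documented choice. MFI is the
arithmetic mean of the green-fluorescence channel (a geometric-mean option
exists but is not the headline statistic), and the peroxidation readout is

    relative MFI increase (%) = |MFI_30Gy − MFI_0Gy| / MFI_0Gy × 100.

The default phantom gates are calibrated to the generator's population
geometry; real instruments need their own vertex lists (config).
Histograms are reported as "% of max" on linear or log10-spaced bins.

## Synthetic phantoms: what they emulate, and what they don't

The SRS phantom places non-overlapping disc cells (concentric disc nuclei,
small disc droplets confined to the cytoplasmic annulus) and renders the
two bands through exactly the linear mixing model above, adding i.i.d.
Gaussian noise per frame (lock-in detection noise is approximately
Gaussian). Nuclei carry no lipid signal — they image dark in the lipid
channel — and elevated protein. Defaults mirror the acquisition geometry:
512×512 pixels, 10 frames per band, ~25 cells of radius 25–35 px, 3–8
droplets of radius 2–4 px per cell, lipid levels 1 (cytoplasm) / 5
(droplet), protein 2 (cytoplasm) / 3 (nucleus), per-frame noise sd 0.25
(≈ SNR 22 against the brightest noiseless pixel). Test-scale phantoms use
128×128 with proportionally scaled cells so loops over many seeds stay
fast; the per-cell statistics are unchanged by this scaling.

The calibration phantom renders Lorentzian peaks (FWHM 28 cm⁻¹, the
instrument's spectral resolution, mapped through the true slope) at the
positions a known linear map sends the calibrant shifts to. The flow
phantom draws lognormal scatter/fluorescence populations — singlets on the
SSC-H ≈ SSC-A diagonal, doublets at double area, debris at low scatter —
with the singlet fluorescence mean set to `singlet_mfi × mfi_shift_factor`
and a programmed CV.

Phantoms deliberately omit: spatially correlated noise and etaloning,
out-of-focus background, cell-to-cell intensity variation, non-disc
morphology, touching/overlapping cells, photobleaching drift, spectral
overlap with water, and spillover/compensation in flow. Passing recovery
tests therefore demonstrates the *algorithms* are correct under the stated
model, not that the pipeline is robust to every real-data artifact; the
configurable thresholds (η cutoff, droplet-size filter, gates) are the
knobs real data would exercise.

## Problem sizes used in the shipped benchmarks

Recovery and power figures reported by `scripts/acceptance.py` use:
10⁴ random pixels for the NNLS oracle comparison; full 512×512 phantoms for
unmixing recovery (noiseless and SNR 20) and droplet-mask Dice (20 seeds at
3:1 LD contrast, SNR 10); 100 cohorts of 10 regions per arm (128×128
phantoms, per-frame noise 0.25) for the 1.5× LD-area power curve and its
null; 10⁵-event tables (20 seed pairs) for the 1.53× MFI-shift recovery.
These sizes give Monte-Carlo error comfortably below the tolerances they
are compared against.

## Known limitations

* Fixed-spectra unmixing is exact enumeration over component supports —
  ideal for K = 2–3; for many components an iterative NNLS would be
  preferable.
* The free-spectra mode is unconstrained beyond nonnegativity and unit-max
  normalisation; with B = K it can drift from the references and is not
  the default.
* The η stopping cutoff (0.75) sits between the Gaussian-splitting value
  (≈0.64) and observed genuine-mode values (≳0.9); extremely low-contrast
  droplets could stop one pass early. The threshold trace makes this
  visible.
* Cell counting is an input, not an inference; the connected-component
  estimator merges touching cells.
* No FCS parser: flow events are consumed as CSV tables.
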