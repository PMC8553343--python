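# Methods

## Photophysical calibration

The viscosity response of a fluorescent molecular rotor is modelled by the
Förster–Hoffmann power law, fitted as ordinary least squares of log10 I on
log10 η. Base-10 logarithms are used throughout because rotor calibration
plots are conventionally drawn as lg I vs lg η. The reported correlation is
the Pearson r of the log–log pairs (not r²). Nitroreductase sensitivity is
an unweighted linear OLS fit of intensity on concentration over the 0–9.0
μg/mL working range; no robust or weighted regression is used, matching the
simplicity of routine spectroscopic calibration. The blank spread σ is the
n−1 sample standard deviation; because a reported σ may equally be a fit
residual SD, `compute_lod` also accepts an externally supplied σ. The
detection limit is LOD = 3σ/k, held at full precision internally and
rounded to one decimal (ng/mL) only for display. `compute_lod` is
homogeneous of degree zero in (σ, k): scaling both by the same factor
leaves the LOD unchanged, which the tests verify.

Degenerate inputs are rejected rather than patched: fewer than two points,
non-positive viscosities or intensities on the log scale, and zero variance
in the predictor all raise `ValueError`.

## Image quantification

Specimen footprints are found by thresholding the per-pixel **maximum**
over the two channels (a specimen bright in only one channel must still be
detected, or the `+` group would be invisible to segmentation), labelling
connected components under 8-connectivity (configurable to 4), and
discarding components below `min_area`. Defaults `bg_threshold=30`,
`min_area=50` px suit the synthetic images and are exposed because real
instruments differ. Regions are ordered by bounding-box (min_row, min_col)
and numbered from 1, making segmentation deterministic and idempotent.

The per-specimen statistic is the **maximum** gray-scale per channel over
the region — not a mean or percentile, and with no background subtraction —
because that is the statistic the screening thresholds are defined on.
Colocalization is the plain pixelwise Pearson correlation over an optional
mask, with constant channels rejected as degenerate.

## Threshold derivation and triage

Lloyd's K-means (k-means++-style seeding, empty clusters re-seeded to the
worst-fit point, convergence when the maximal centroid shift < 1e−9) is
authored in-package; scikit-learn serves only as an independent cross-check
in the tests. The default k = 1 makes the threshold the grand centroid —
the componentwise mean of the pooled training scatter (cancerous and
noncancerous points together). This is the only reading consistent with a
single printed (x, y) threshold per cancer type; k is configurable for
sensitivity analysis, in which case the centroid of the largest cluster is
used. Thresholds are quoted to one decimal.

The triage rule partitions the 256×256 intensity grid into three quadrant
regions. A value **exactly at** the threshold counts as "high" (≥): a
pre-screen should err toward flagging tumor, so boundary ties resolve
toward the positive call. The rule is monotone — raising either intensity
never moves a call toward `-` under the order `-` < `+` < `++` — which is
property-tested. Thresholds are cancer-type- and instrument-specific and
are therefore always inputs (fixed or derived), never constants.

## Evaluation

H&E pathology is ground truth; screen-positive = {`++`, `+`}. Specificity
TN/(TN+FP) is the headline rate, and NPV is always reported alongside it
because the clinical safety claim of a pre-screen ("a negative cohort can
close the case") is an NPV statement. Zero-denominator rates are reported
as explicit nulls. The 3×2 call-vs-label crosstab must agree with the
confusion counts on every input; this cross-module identity is fuzz-tested.

## Synthetic data

The generator emulates the study conditions end to end:

* **Viscosity series** — 8 points geometrically spaced over the
  ethanol→glycerol range (1.2–945 cP, handbook values at ~20 °C, override
  via config). The default slope x = log10(18)/log10(945/1.2) ≈ 0.4334 is
  *derived* from the probe's 18-fold ethanol→glycerol contrast rather than
  invented, so the noise-free default series has exactly an 18-fold
  endpoint ratio. Noise is multiplicative Gaussian (`rel_noise`).
* **Titration** — defaults k = 11166.424 intensity units per μg/mL,
  intercept 0, additive Gaussian noise and blanks with σ = 77.883 over ten
  concentrations in 0.5–9.0 μg/mL, 11 blank replicates.
* **Tissue images** — Gaussian background (mean 15, SD 4) with
  non-overlapping axis-aligned elliptical blobs whose per-pixel intensities
  are Normal(class mean, class SD), cycled through the configured classes;
  everything rounded and clipped to the 8-bit range. The truth table
  records each blob's mask and planted per-channel maximum read back from
  the final image, so recovery can be asserted exactly.
* **Margin cohorts** — paired training records and a labelled test set;
  defaults mimic the liver design (9 training pairs; 9 P + 26 N test
  margins) with class means (200, 200) vs (120, 120) and SD 10 gray levels,
  placing each class about 4 SD from the ≈160 threshold. Intensities are
  rounded to integers at this level only (8-bit cameras); spectra stay
  real-valued.

Gaussian noise everywhere is the simplest model consistent with a single
blank SD. The generator does **not** simulate optics (PSF, bleaching,
spectral overlap), spatial intensity gradients, or correlated within-
specimen texture; passing tests therefore demonstrate the correctness of
the analysis logic under the assumed statistical structure, not instrument-
level robustness on real images.

## Pipeline and reproducibility

A run is a pure function of (config, seed). The global seed is fanned out
to per-stage sub-seeds by fixed offsets (spectra +101, image +202, cohort
+303, k-means +404, mod 2³¹), so toggling one stage never shifts another's
random stream; two runs with the same config are byte-identical. Every
stage writes its artifact (CSV/TIFF/JSON) so stages can be re-run or
replaced with external instrument data. The cohort verdict mirrors the
intended use: all calls `-` → `cohort_negative`; any `++`/`+` →
`priority_review`. Stage failures abort after writing a report naming the
failing stage; the CLI maps validation errors to exit code 2 and stage
failures to 3.

Default problem sizes (35-specimen cohorts, 160×256² images, ≤10⁴-draw
Monte-Carlo checks) keep a full run and the complete test suite in the
seconds range while leaving the statistical checks well-powered.

## Known limitations

* The k = 1 centroid reading of the threshold is the documented default;
  other clusterings of the training scatter are possible and configurable
  but not validated against published thresholds.
* Whether the published blank σ is a replicate SD or a residual SD is not
  determinable; both routes are supported.
* Real-image effects (illumination fields, specimen touching, RGB exports)
  are out of scope; the reader converts to single-channel 8-bit on load and
  assumes separable specimens.
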