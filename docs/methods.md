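# Methods

This note documents the measurement model, the synthetic-cohort generator,
the numerical conventions, and the design decisions taken where the
procedure being implemented left choices open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Measurement model

### Channels and acquisition

Four fluorescence channels, identified by marker and emission wavelength:
TH (405 nm), CI-20/NDUFB8 (488 nm), CIV-1/COX1 (546 nm), porin/VDAC1
(647 nm). In-memory arrays use the fixed marker order (TH, CI20, CIV1,
porin); the recorded acquisition order is longest wavelength first (index
0 = 647 nm), the standard tactic for limiting bleed-through during imaging.
A single exposure/gain is assumed across all sections of a cohort, so raw
intensities are comparable between sections; the ratiometric normalization
below additionally removes any residual per-run gain differences.

### Background and thresholds

For each individual, the per-channel background is estimated from a
non-stained region of one section: mean μ_b, sample SD σ_b (ddof = 1), and
detection threshold t = μ_b + k·σ_b. Default k = 2 — the conventional
conservative choice for "adjusted according to the background signal"; it is
a `PipelineConfig` knob. The model is estimated once per individual (from
their first section in manifest order) and applied unchanged to all of that
individual's sections; the audit log records which section it came from and
how many sections reused it.

### Segmentation and measurement

Somata are delineated on the TH channel only (TH never enters any
ratio): binarize at the TH threshold, fill holes, label 8-connected
components, drop components below `min_area` (default 100 px) or touching
the image border — partial somata at the field edge would bias mean
intensities. ROIs are sorted by centroid (row, col) so the per-section cap
is deterministic.

For each ROI (up to `cap` = 100 per section) the mean of *all* ROI pixels is
taken in each channel simultaneously, and corrected as
max(0, mean − μ_b). Two deliberate choices:

* **Background is subtracted from the ROI mean rather than thresholding
  pixels inside the ROI.** Subtraction preserves linearity (corrected means
  scale exactly with channel gain, so ratios behave predictably) and keeps
  the measurement well-defined for arbitrarily dim cells. Excluding
  sub-threshold pixels from the mean is a plausible alternative reading of
  the protocol; it is not the default because it breaks gain invariance and
  biases dim cells upward. The ambiguity is real and flagged here.
* **No cell is excluded for low CI-20, CIV-1 or porin signal** — deficiency
  is the quantity of interest.

### Bleed-through

Crosstalk is modelled as linear mixing: α[i, j] is the fraction of channel
j's true signal observed in channel i (diagonal 1, off-diagonal in [0, 1)).
It is estimated from single-label controls: over the pixels of the j-only
control that exceed the control's own-channel threshold,
α[i, j] = corrected mean of channel i / corrected mean of channel j.
Correction (`correct_crosstalk`) inverts the mixing per pixel,
true = A⁻¹(obs − μ_b) + μ_b, leaving the background level in place so
downstream subtraction is unaffected. Correction is **off by default**: the
protocol being modelled minimizes crosstalk optically (fluorophore choice,
acquisition order, acquisition-side threshold adjustment), so computational
unmixing is an extension, not a re-implementation of a published step.

### Ratios, normalization, pooling

Per cell: CI-20:porin, CIV-1:porin, CI-20:CIV-1 from corrected means.
Ratios are computed per cell and medians taken over cells — never
ratio-of-medians. A cell whose denominator (or numerator) corrected mean is
≤ ε (default 10⁻⁶ of the 16-bit ceiling, ≈ 0.066 counts) is marked excluded
with a reason naming the channel; excluded cells stay in the tables and are
counted, never silently dropped.

Within each run, the median of each ratio over non-excluded control cells
defines 100 %, and every cell's normalized value is 100 · raw/median. The
median convention is the midpoint of the two central order statistics for
even n (numpy's default); consequently the re-computed control median is 100
exactly up to two IEEE-754 roundings (tests assert |median − 100| < 1e-9).
Normalization is strictly per run — pooling concatenates the runs'
normalized records and never recomputes a global control median — so the
control serves as an internal standard per run and between-run gain drift
cancels. The number of runs is taken from the manifest; nothing assumes
four.

### Statistics

Patient-versus-control comparisons use the two-sided Mann–Whitney U test on
the pooled normalized per-cell ratios (densitometric single-cell data are
right-skewed; normality is not assumed). The implementation is in-repo so
its behaviour is pinned by tests: midranks for ties; exact p by full
enumeration of rank assignments when both samples have ≤ 8 observations and
no ties; otherwise the normal approximation with tie-corrected variance and
a 0.5 continuity correction; U is reported as min(U_x, U_y). Sidedness is
not dictated by the procedure being modelled; two-sided is the conservative
default. Stars follow the usual figure convention (* p < 0.05, ** p < 0.01,
*** p < 0.001; ** is included for completeness). No multiple-testing
correction is applied across the three ratios or three patients, matching
the modelled analysis; nor is within-run correlation modelled — cells are
treated as independent, a known simplification.

## Synthetic cohorts

### Intensity model

Per cell, with baseline control medians B (TH 12000, CI-20 6000, CIV-1
6000, porin 8000 counts on a 16-bit scale — chosen to sit well above
background and below the ceiling even for elevated-porin subjects):

    porin = B_porin · porin_factor · exp(σ Z_p)
    CI-20 = porin · (B_CI/B_porin) · m'_CI · exp(σ_sh Z_s + σ_un Z_CI)
    CIV-1 = porin · (B_CIV/B_porin) · m'_CIV · exp(σ_sh Z_s + σ_un Z_CIV)
    TH    = B_TH · exp(σ_TH Z_TH)          (independent of the others)

σ = √log(1 + CV²) with per-cell dispersion CV = 0.35 by default (medians and
scatter, not distributions, are what the assay reports; lognormal is the
standard model for positive, right-skewed fluorescence intensities). TH has
its own CV = 0.25.

The ratio-noise log-variance σ² is split into a component shared by the two
complex-subunit channels (σ_sh² = 0.65 σ²) and channel-specific parts
(σ_un² = 0.35 σ²). The shared component represents per-cell effects that act
on both inner-membrane targets alike — fixation quality, antigen retrieval,
epitope accessibility, section thickness. The 65/35 split was fixed once
from the model's quantile arithmetic: it keeps the per-cell CI:CIV
distribution consistent with the CI:porin and CIV:porin calibrations in
heavily CI-deficient cohorts (with fully independent channel noise, the
large deficient fraction of the deletion subject drags the CI:CIV population
median several points below what the two porin-ratios imply).

With probability `frac_ci_deficient` a cell's CI-20 level is replaced by a
"completely deficient" level — 5 % of the *control* median channel level,
with the same lognormal noise — and analogously for CIV-1 (independent
draws; the available data are marginal fractions only). Deficient cells are
visibly dark but nonzero, keeping thresholds and ratios well-posed.

### Median calibration

The population median of CI:porin must equal the profile's configured
multiplier × the control baseline. The ratio distribution is a two-component
lognormal mixture: the deficient branch (median d = 0.05/porin_factor in
multiplier units, log-SD σ√2, numerator and denominator independent) and the
non-deficient branch (median m', log-SD σ). The closed-form solution is

    m' = target / exp(σ Φ⁻¹(p)),   p = (½ − f·F_d(target)) / (1 − f)

where F_d is the deficient branch's CDF at the target. The F_d term matters:
for the deletion profile (f = 0.44) the naive assumption F_d ≡ 1 leaves a
≈ +1 % bias in the population median, which the exact form removes
(verified by Monte-Carlo at n = 100 000 within 1 % relative error).
Calibration requires f < ½; larger fractions put the population median
inside the deficient mass, and the generator refuses them.

### Default cohort

`make_default_profiles()` returns four subjects whose true multipliers are
the pooled combined-run medians of the four-subject study design this
package emulates: control 1.00/1.00, single large-scale mtDNA deletion
0.19/0.60, m.8344A>G MERRF 0.33/0.32, PD 0.32/0.42 (CI:porin/CIV:porin);
deficient fractions 0.44/0.01 (deletion) and 0.22/0.23 (MERRF) from the
prior population-level chromogen study of the same cases. Porin elevation in
MERRF neurons is reported only qualitatively; the default factor 1.5 is a
documented placeholder, not a claim (PD 1.1 — "only a slight increase";
control and deletion 1.0). Study-design defaults: 100 cells per section, one
section per run, four runs per subject.

### Rendering

Cells are hard-edged disks (radius uniform 8–15 px) placed by rejection
sampling without overlap (≥ 3 px gap, 4 px border margin, 10 000 tries per
cell before `PlacementError`) on a 1024 × 1024 16-bit field. Effects, in
order: Gaussian background field (mean 300, SD 30 counts per channel);
sparse broadband autofluorescence grains (30 per field, radius 1–2.5 px,
amplitude 2000–8000 counts, equal in all channels — residual lipofuscin
after Sudan-black quenching); optional linear crosstalk mixing; Poisson shot
noise; Gaussian read noise (SD 10); clipping to bit depth (with a warning if
any pre-clip value exceeded the ceiling). The label mask marks exactly the
painted disk pixels, and expected intensities are rounded to whole camera
counts at generation time, so a noiseless rendering reproduces the
ground-truth intensities exactly — the rendering-fidelity oracle used by the
tests.

Each section records a deterministic "non-stained area": the first (in
row-major scan) cell-free window, 64 px falling back to 16 px on crowded
fields; speckle is kept out of it, as an analyst would choose a visually
clean region. The default cohort is rendered with identity crosstalk — the
emulated acquisition minimizes bleed-through optically — and nonzero
crosstalk is exercised by the unmixing tests.

Determinism: all randomness flows from `numpy.random.default_rng`; cohort
simulation derives per-section seeds from the master seed via
`SeedSequence`, so identical calls produce byte-identical datasets.

### What the simulator does not emulate

No point-spread-function blur, no 3-D structure or section-thickness
effects, no photobleaching, no neuromelanin/brightfield channel, no spatial
background gradients, no correlated (clustered) cell placement, no
non-linear detector response. Somata are disks, not irregular cell shapes.
Passing the cohort-recovery tests therefore shows that the *analysis* is
correct and calibrated under the stated statistical structure — not that
segmentation or background estimation would perform identically on real
tissue, where outlining is typically manual and autofluorescence is more
structured.

## Problem sizes used by the tests and the acceptance script

The cohort-recovery experiment uses the full default design (4 subjects × 4
runs × 100 neurons on 1024² images — the size of the study being emulated).
Generator-calibration Monte-Carlo uses 100 000 cells; the type-I-error
calibration uses 200 replicate null comparisons of 100-cell cohorts at
α = 0.05 (band 5 % ± 4 %); unit and property tests use reduced cohorts
(2 runs × 50 cells on 512² fields). These sizes are the package's own
defaults for routine verification.

## Known limitations

* Per-cell measurements within a run share a section and are treated as
  independent by the Mann–Whitney test; a hierarchical model would be more
  faithful but is out of scope.
* The deficient-cell level (5 % of control median) and the MERRF porin
  factor (1.5) are generator conventions, not measured quantities.
* The automatic TH segmentation is a stand-in for manual outlining;
  real-data use should prefer imported manual ROIs where available.
* Polygon rasterization fixes one convention (even-odd, pixel centers,
  half-open, 0-based); ROIs drawn in other tools may differ by boundary
  pixels.
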