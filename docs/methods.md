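# Methods

## Scope and conventions

granulekit quantifies condensate micrographs and photobleaching experiments.
All images are carried as `(t, z, c, y, x)` arrays with 0-based indices and
pixel centers at integer coordinates; physical distances use the
`pixel_size_nm` calibration. Percentages are always carried on the 0–100
scale in outputs; fitting happens internally on the 0–1 scale. All random
generation flows through `numpy.random.default_rng(seed)`, and identical
configurations (including the seed) reproduce bit-identical outputs.

## FRAP model and fitting

A recovery trace has `n_pre` pre-bleach frames (default 5), an instantaneous
bleach pulse between frames `n_pre − 1` and `n_pre`, and post-bleach values

F(t) = F_bleach + a (F0 − F_bleach)(1 − exp(−b t)),

with acquisition bleaching exp(−k_img t) applied equally to the bleach ROI
and the reference ROI. Normalization is *double* (background-subtract,
divide ROI by reference — cancelling k_img exactly — and scale the pre-bleach
mean to 1) followed, in the default *full-scale* mode, by mapping the first
post-bleach value to exactly 0. Full-scale curves from sessions with
different bleach depths are directly comparable, and the fitted plateau *a*
is the mobile fraction.

The bleach frame is located as the minimum within `[n_pre, n_pre + 2]`; the
single-pulse protocol guarantees the true minimum immediately after the
pulse, and the window tolerates one-frame noise jitter. When averaging
curves, the earliest located index is used as the common bleach frame.
Averaging-then-fitting is the default; per-trace fitting remains available
by fitting each normalized curve separately.

The fit is nonlinear least squares of a(1 − exp(−bt)) on post-bleach times
re-zeroed at the bleach frame, initialized derivative-free: a₀ = mean of the
last 10% of the curve, b₀ = ln 2 over the first time the curve exceeds a₀/2.
Bounds keep a in [0, 1.5] (values above 1.1 are flagged as over-recovery)
and b positive; a non-positive plateau estimate or fitted rate raises a
"no recovery" error rather than returning a meaningless fit. t½ = ln 2 / b
is derived, never fitted independently, so t½·b = ln 2 holds exactly.
Standard errors come from the fit covariance and are labeled as fit SEs —
they describe the averaged curve, not the spread across ROIs.

## FLIP and photoconversion

Regions exchange mobile protein through a symmetric non-negative coupling
matrix k_ij (1/s); the immobile fraction is excluded from exchange but still
photobleached. The system is linear with constant coefficients, so each
frame is propagated with the exact matrix exponential exp(A·Δt) — this
conserves total fluorescence to machine precision when no bleaching acts,
and the tests cross-check it against an independent ODE solver and a
two-compartment closed form.

FLIP quantification normalizes each region to its raw time-0 value
(configurable to the pre-bleach mean) and reports percent fluorescence
remaining — deliberately with no reference-ROI normalization. Endpoint
depletion is 100 minus the final percent; the mean depletion of control
traces (a bleach target outside the specimen) estimates unintended
acquisition bleaching and is subtracted, flooring corrected redistribution
at 0 because depletion below the control is noise by construction (negative
corrections are logged, not reported).

Photoconversion starts the converted species at the full signal of the
targeted regions and lets both species redistribute through the same
coupling matrix. Targeted granules report retention (percent of their own
first post-conversion value); non-targeted granules report appearance
(percent of the mean initial targeted intensity).

## Synthetic data: what it emulates and what it does not

The generators emulate a point-scanning confocal at high zoom: 50 nm pixels,
1 s frame interval, a Gaussian PSF of σ = 1.6 px (≈ 80 nm, ≈ 190 nm lateral
FWHM, typical of a high-NA objective at ~510 nm emission), Poisson photon
noise followed by additive Gaussian read noise (SD = `gaussian_sigma` × the
signal level; 1% default, 2% in the trace-recovery studies). Granules render
as flat disks (or hollow shells whose interior is dimmed to a configurable
fraction of the shell excess) at `background × (1 + (enrichment − 1) ×
indicator)` before optics; rendering is exact at interior pixels when PSF
and noise are off. Overlapping granules are rejected by default because
overlap corrupts per-granule truth.

Not emulated: diffraction physics beyond a Gaussian PSF, camera-specific
noise calibration, spatial reaction–diffusion during recovery (compartment
model only), granule crowding/contact (placement enforces separation), and
axial PSF anisotropy beyond a fixed 2× smaller z-sigma in counting stacks.
Passing recovery tests therefore shows the estimators are correct for
well-separated, radially symmetric granules under shot + read noise — not
that they are robust to dense packing, drift, or structured background.

## Enrichment estimation under a finite PSF

Fold enrichment is the ratio of per-area granule intensity to per-area
reference intensity, each averaged across ROIs. Two granule measures are
provided. `mean` averages the segmented footprint — it matches manual ROI
practice but is biased low by edge dilution once the granule radius is only
a few PSF sigmas (for a 211 nm-radius granule at σ = 80 nm it underestimates
a 21-fold truth by ~3×). `peak` reads the brightest pixel of each granule,
estimating the interior concentration; its residual bias is the center
attenuation 1 − exp(−r²/2σ²) (≈ 3% at r = 2.6 σ, negligible for large
granules), partially offset by noise-maximum bias of comparable size. The
recovery analyses use `peak`; both are exposed and labeled.

Background statistics are estimated from pixels outside a 2-px dilation of
the supra-Otsu foreground (the ROI placement used for background is not
otherwise prescribed). Segmentation keeps connected components above
`background mean + k·SD` (default k = 3) with a minimum area; for 3-D input
each component is measured on its equatorial plane (z of maximal
cross-sectional area, where the granule is most in focus). Whether published
areas were equatorial or projected is not always stated; equatorial is
assumed and documented.

## Morphometry defaults

- Area→diameter: `paper` convention d = 2√A by default because it reproduces
  the published (area, diameter) pairs exactly; the circular convention
  d = 2√(A/π) differs by √π and is available, labeled. The discrepancy is
  documented, not silently corrected.
- Line-profile edges: first/last samples above background mean + 2 SD
  (configurable k); size = run length × pixel size; multiple disjoint runs
  are ambiguous unless the largest-run policy is enabled.
- Classification: hollow when central-disk mean (30% of the equivalent
  radius) falls below 0.7 × the peak shell-annulus mean; small vs big at a
  1.2 µm equivalent-diameter boundary; granules under 3 px across are
  unclassified. All thresholds are configurable — the underlying phenotype
  binning is visual in origin, with no published numeric criteria.
- Colocalization and tracking use greedy one-to-one nearest-centroid
  matching ordered by ascending distance (ties by lowest id): deterministic,
  testable, and adequate at the granule densities involved. A fusion event
  requires the merged granule's total intensity to match the predecessor sum
  within 20% (configurable); mismatches are logged, not recorded.
- Nucleus counting marks a nucleus associated when the germ-channel mean in
  its surrounding shell (dilation minus nuclei) exceeds background by
  k·SD (k = 2) — even a small amount of signal counts.

## Cell-cycle deconvolution

DNA-content histograms are fit by least squares to a Dean–Jett–Fox-style
mixture: a G1 Gaussian, a G2/M Gaussian constrained to exactly twice the G1
mean (ploidy constraint), and S phase as 10 evenly spaced Gaussian
sub-components between them, all sharing one relative CV (the standard DJF
assumption; it removes the G1/S/G2 degeneracy). Fractions are component
masses normalized to 100%; a G2/M mass under 0.1% warns that the histogram
looks unimodal. The generator draws S-phase cells from the same 10
sub-populations, so recovery tests probe the fit, not model mismatch.

## Statistical conventions

Group summaries report the sample SD (n − 1) and SEM = SD/√n; a single
observation reports SD 0 with a warning. The unpaired two-tailed t-test
defaults to the Welch variant (equal variances are not assumed anywhere);
the classical equal-variance variant is selectable. Two degenerate groups
with equal means return p = 1 by convention. Percent change is
100 (control − test)/control. Display rounding is 1 decimal place for
percents and nm sizes; CSV/JSON outputs retain full precision.

## Problem sizes

The recovery studies run at sizes a single workstation handles in seconds:
512×512 granule fields with 18–23 granules, 10 or fewer 240-frame traces
per kinetic regime, 14–16-plane counting stacks with up to 36 nuclei, and
20,000-cell histograms. These match the sample sizes of the quantities they
reproduce (e.g. 23 granules / 20 reference ROIs for cytoplasmic enrichment,
18 granules for the nuclear regime).

## Known limitations

- The FRAP model is reaction-limited (single exponential); diffusion-limited
  recovery profiles and two-component fits are out of scope by design.
- `mean`-mode enrichment under a finite PSF is biased low for granules
  smaller than ~5 PSF sigmas; use `peak` or report the bias.
- The compartment model has no spatial structure within a region; FLIP
  gradients across a contiguous germ plasm are approximated by the chain
  coupling topology.
- Trace CSV round-trips store times as decimal text (9 significant digits);
  exact binary equality of times is not guaranteed across round-trips,
  uniformity is revalidated on read.
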