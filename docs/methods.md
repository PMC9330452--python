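# Methods

## Signal model

A multi-spin-echo acquisition samples the transverse magnetisation at
echo times t_k = k·TE, k = 1..n (defaults TE = 6.5 ms, n = 256,
160×160 matrix). The noiseless signal of a pixel in tissue τ is

    S(t) = PD(τ, p) · Σ_j f_j(τ) · exp(−t / T2_j(τ)),   Σ_j f_j = 1,

a discrete mixture of relaxing water pools. Repetition time is treated
as infinite (full T1 recovery) and no B0/B1 inhomogeneity, slice
profile, stimulated echoes or diffusion weighting is modelled — the
phantom is a pure mono-/bi-exponential forward model plus magnitude
noise. Magnitude reconstruction of complex Gaussian noise gives Rician
statistics: each value v becomes sqrt((v+n1)² + n2²) with
n1, n2 ~ N(0, σ²); background pixels are then Rayleigh with mean
σ·sqrt(π/2), which is how the noise level is estimated downstream. A
plain additive-Gaussian option exists for analytic tests only.

## Phantom generator

The generator emulates the reference layout: eight elliptical tubers on
a 2×4 grid (two trays of four), with a small seeded jitter of centres
and semi-axes. Per tuber, concentric tissues are defined
*morphologically*: the skin is what one erosion with a
(2·s+1)-square kernel removes (s = 2 px), the cortex the next
c = 3 single-pixel erosion layers, the pith a central ellipse
(defaults: 60 %/64 % of the inner-region semi-axes), the flesh the
rest. Thickness-by-erosion (Chebyshev layers) rather than
ellipse-shrinking makes the generative ground truth commensurate with
any erosion-based segmentation — a discrete-geometry choice, since the
"thickness in pixels" of a raster region is exactly its erosion depth.

Default relaxation mixtures are the printed 32-DASE control values:
cortex (19 %, 64 ms) + (81 %, 268 ms); flesh (24 %, 61 ms) +
(76 %, 268 ms); pith (12 %, 52 ms) + (88 %, 353 ms). The flesh
slow-pool T2 is not printed separately in the source data and is set to
the cortex value, the two being statistically indistinguishable there.
The skin is a fast-relaxing, low-density stand-in for the suberised
periderm ((50 %, 25 ms) + (50 %, 150 ms), PD 70) — it only needs to be
visible to the background split, since the first erosion discards it.

Two generative choices matter for segmentation realism:

- **Proton densities.** Cortex and flesh share PD = 100; the pith gets
  PD = 110. The pith of a real tuber is watery and starch-poor and
  appears distinctly brighter; with equal PD the late-echo pith/flesh
  contrast from T2 alone (~25 %) under-represents what the reference
  images show.
- **Texture.** The flesh carries a multiplicative smooth Gaussian
  random field on PD (amplitude 10 %, correlation length 3 px, mean 1,
  seeded) reproducing its characteristically heterogeneous signal; T2
  values are untouched, so ROI-mean decay shapes stay exact. The pith
  carries a milder field (5 %): "homogeneous" tissue in an MR image is
  a visual statement, not literal constancy, and a literally constant
  pith makes its histogram a zero-entropy spike on which
  maximum-entropy thresholding is degenerate (the threshold collapses
  into the flesh mode).

An optional vascular ring — 1 erosion layer at the cortex–flesh
interface with the slow-pool T2 raised 30 % — reproduces the narrow
bright ring visible at late echoes. It is off by default (its pixels
belong to neither cortex nor flesh in the ground truth, and at these
tuber sizes even a 1-px ring is a sizeable fraction of the thin flesh
annulus) and enabled in the robustness tests and the analysis demo.

The long-table simulator draws Gaussian replicates per
(tissue, date, regime, variable) cell, defaulting to n = 4 per cell as
in the source design.

## Segmentation

1. **Background split**: Otsu's threshold on the first echo (maximum
   SNR); connected components above 200 px become tubers, numbered in
   reading order (bands top-to-bottom, then left-to-right of centroid).
2. **Skin removal**: one erosion with a 5×5 square kernel per tuber.
3. **Cortex**: the strip of 3 iterated 1-px (3×3) erosions from the
   skinless mask contour. Three 3×3 erosions are used rather than one
   5×5 erosion because a 5×5 square erosion removes 2 px, not the
   3 px the protocol specifies; both kernels are configurable.
4. **Pith**: Kapur's maximum-entropy threshold on the echo-20 frame
   (TE = 130 ms, where the long-T2 pith is brightest relative to the
   flesh) restricted to the sub-cortical interior; the bright connected
   component at the tuber centroid is the pith. One 3×3 binary opening
   cuts thin bright bridges before the component is picked and the
   boundary is restored by dilation within the thresholded mask — this
   automates, reproducibly, the manual removal of peripheral bright
   objects (e.g. the vascular ring) that an interactive protocol would
   perform. The threshold is computed per tuber.
5. **Flesh**: the remainder. Cortex ⊎ flesh ⊎ pith always tiles the
   skinless mask exactly.

Both threshold operators work on 256 equal-width bins over the in-mask
intensity range, maximise their objective over all splits, break ties
toward the lowest split (with a 1e-9 relative tolerance so that
algebraically tied splits are not decided by summation order), and
return the midpoint between the two flanking bins; pixels strictly
above the value are foreground. Both are verified against exhaustive
brute-force oracles, and Otsu additionally against scikit-image.

Known property: segmentation accuracy is not monotone in noise at very
low noise levels (σ ≲ 1 % of peak). Entropy thresholding benefits from
a little histogram spread, and added noise dithers the threshold mask;
Dice degrades monotonically from the default noise level (2 % of peak)
upward, which is what the robustness test asserts.

## Relaxometry

ROI curves are per-echo means over the tissue mask; the noise level σ
is estimated from a signal-free region as mean/sqrt(π/2). Echoes are
truncated by the prefix rule: keep the leading run with
signal/σ ≥ 7, drop everything from the first violation on (no interior
gaps) — after that point the magnitude noise floor makes residuals
non-zero-mean. SNR is defined against the *per-pixel* σ, the standard
convention for magnitude MRI, which the source protocol leaves
unstated. Kept echoes are not Rician-bias corrected: at SNR ≥ 7 the
magnitude bias is below 1 % of the signal. This is the dominant known
bias of the chain — it inflates the slow-pool T2 by ~1 % (≈ +2.5 ms at
268 ms) and shifts pool fractions by well under one point at the
default noise level.

Fitting minimises Σ_k (S_k − Σ_j I0_j e^{−t_k/T2_j})² by bounded
trust-region-reflective least squares (the bounded analogue of
Levenberg–Marquardt damping) with analytic Jacobian, I0_j ≥ 0 and
T2_j ∈ [TE/10, 10·t_max]. Initialisation is graphical peeling: a
log-linear fit of the curve tail (last third of kept echoes) seeds the
slow pool, its extrapolated contribution is subtracted, and a
log-linear fit of the positive head residuals seeds the fast pool, with
a fixed-ratio fallback when peeling fails — deterministic and robust
for well-separated T2. Fits are unweighted (ROI-mean curves have
approximately uniform noise). Standard errors come from the
Jacobian-based covariance scaled by the residual variance. Components
are reported sorted by ascending T2 with intensities as percentages of
the summed amplitudes (they always total 100).

**Model-order selection** fits n = 1, 2, 3 and accepts n+1 over n only
if, simultaneously, R² gains at least `r2_gain_min`, the global fitting
standard error (sqrt(SSR/dof)) decreases, every parameter's relative
standard error stays ≤ 0.5, the fit converged, and no two T2 lie
within 1 % of each other (a non-identifiable split). The default
`r2_gain_min` = 1e-3 was calibrated by separation: at the study noise
level (σ = 1 % of peak, SNR-7 truncation) mono-exponential inputs show
spurious 2-component gains of at most ~4×10⁻⁴ while genuinely
bi-exponential tissue curves gain ≥ 2.4×10⁻³, so 1e-3 sits mid-gap
with better than twofold margin on both sides. The selection thresholds
of the original TableCurve-based workflow are unknown; these are this
package's own operating points.

At the default conditions the chain is statistically efficient: the
fitted parameter scatter matches the Cramér–Rao bound for the
truncated-curve protocol (e.g. 9.7 ms per-curve bound on the cortex
fast-pool T2 at σ = 1 % of peak for a single-pixel curve — which is why
headline recoveries are computed from ROI-mean curves, where averaging
over hundreds of pixels makes the bound negligible against the
printed between-tuber SDs).

## Group statistics

Comparisons are gated on normality: Shapiro–Wilk at α = 0.05 on the
pooled within-group residuals (values minus their group mean);
degenerate residual sets (n < 3 or zero spread) pass the gate. Two
groups: Student's t-test, or Mann–Whitney (exact for small untied
samples) when the gate fails. Three or more: one-way ANOVA with Tukey
HSD pairwise p-values, or Kruskal–Wallis with Bonferroni-corrected
pairwise Mann–Whitney tests. Letter displays are built by
insert-and-absorb on the pairwise significance matrix: cells sharing a
letter are never significantly different, and cells never declared
different always share one; two-group outcomes use only letters a/b.
The Monte-Carlo calibration harness confirms both dispatchers hold
their nominal type-I error (within [0.03, 0.07] at n = 4, 2000 null
replicates). Note a discreteness floor: a *forced* Mann–Whitney branch
at n = 4 per group has an exact null rejection rate of 2/70 ≈ 0.029 —
no implementation can place that single branch inside [0.03, 0.07];
the gated dispatchers sit near 0.05 because Gaussian nulls rarely take
the non-parametric branch.

PCA standardises each variable (columns centred, unit variance,
ddof = 1) before a singular-value decomposition, i.e. it diagonalises
the sample correlation matrix — appropriate because the variables mix
units (%, ms, µmol/g). Explained variance percentages are the
eigenvalue shares, loadings are orthonormal, and constant variables are
dropped with a warning.

## What the phantom does and does not show

Passing tests demonstrate that the chain recovers known bi-exponential
parameters through segmentation, truncation, fitting and selection
under Rician noise, and that every deterministic primitive matches an
independent oracle. The phantom does *not* emulate partial-volume
boundary voxels, B1/B0 shading, stimulated-echo contamination of early
echoes, T2 spatial gradients within a tissue, star-shaped pith
morphology, or between-tuber biological variation in the relaxation
parameters themselves; recoveries on real acquisitions will be
correspondingly noisier, and the printed between-tuber SDs (±2 points,
±4–15 ms) should be read as the realistic uncertainty scale.

## Problem sizes

Defaults throughout: 160×160 matrix, 256 echoes, 8 tubers, 4 replicate
acquisitions for recovery summaries; 200 replicates for selection-rate
checks; 2000 replicates for type-I calibration; 1000 random histograms
for threshold oracles. These sizes give sub-minute module runtimes
while keeping Monte-Carlo standard errors well inside the asserted
bands.
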