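# Methods

`boneseg` segments the humeral head from single axial proton-density
(PD) weighted shoulder MR slices. PD-weighted images show bone edema
well but have low SNR, smooth bone/soft-tissue transitions, and
multiplicative intensity inhomogeneity (bias), which together defeat
naive thresholding and edge-based snakes. The pipeline runs in a fixed
order: speckle-reducing anisotropic diffusion (SRAD) denoising →
homomorphic bias attenuation → circular-Hough localization of the head
and construction of the region of interest (ROI) → a region-based
segmentation engine inside the ROI → anatomical postprocessing →
Sørensen–Dice evaluation against a reference mask.

## Denoising: SRAD with a foreground noise scale

SRAD evolves the image under `∂I/∂t = div(c(q)∇I)` with zero-flux
boundaries. The diffusion coefficient
`c(q) = 1 / (1 + (q² − q0²)/(q0²(1 + q0²)))` is driven by the
instantaneous coefficient of variation (ICOV)

    q = sqrt( (½|∇I/I|² − (1/16)(∇²I/I)²) / (1 + ¼ ∇²I/I)² ),

which is large at edges (inhibiting smoothing across them) and near
the noise level in homogeneous tissue. The speckle scale `q0` — the
coefficient of variation expected of pure noise — is re-estimated at
**every iteration from the image foreground** (Otsu threshold, largest
bright connected component) rather than from a homogeneous background
patch: in magnitude MR the dark air background follows a Rayleigh
distribution whose CV is a constant independent of the tissue noise
level, so a background estimate would mis-scale the filter, while the
bright humeral head is the relevant Rician-noise regime.

Discretization: the standard explicit 4-neighbor stencil with
replicated borders (one-sided differences for the four fluxes, the
coefficient taken at the downwind pixel for the south/east faces).
Defaults `dt = 0.05`, 50 iterations; the explicit scheme is stable for
`dt ≤ 0.25`. Intensities are floored at 1e−6 before the ICOV division,
and `q0` at 1e−6 before entering `c(q)`. A constant image is an exact
fixed point (all four differences vanish identically).

## Bias attenuation: scale-normalized homomorphic filtering

The slice is modelled as `f = i · r`, a smooth illumination field times
tissue reflectance. The filter is

    out = M · ( exp( IFFT( FFT( ln(f/M + δ) ) · H ) ) − δ ),
    H(u,v) = g_low + (g_high − g_low) · (1 − exp(−D²/(2σ²))),

with `M = max(f)`, `δ = 1e−3`, `D` in cycles/image, defaults
`g_low = 0.5`, `g_high = 1.0`, `σ = 30`. Dividing by `M` before the log
makes the operator invariant to the arbitrary MR unit scale; `δ`
guards `log(0)` on air.

The cutoff is the one genuinely delicate choice. The bias field lives
below ~2 cycles/image, but a 90-pixel bright head on a dark background
also concentrates spectral energy at a few cycles/image. Cutoffs in
the 5–20 cycles band attenuate the head's own body, producing halo
artifacts that *increase* the within-head coefficient of variation and
break the expected monotone response to `g_low`. Above ~25 cycles the
filter approaches a log-domain attenuation that scales all log-contrast
by ≈ `g_low`, halving within-head CV from the bias while leaving edge
topology intact; σ = 30 sits in this stable regime and was validated
on multiplicative-ramp phantoms (CV ratio ≤ 0.5 and monotone in
`g_low` across ramp orientations and phantom seeds). `g_low = 0.5`
attenuates rather than erases the illumination: full removal would
also destroy the bone/background contrast the region models need.

One known side effect: any concave log-domain compression shifts the
apparent mid-level edge of a bright object slightly outward (≈0.5 px
here). All threshold-like segmenters inherit this bias; it is visible
in the phantom results as a thin systematic over-segmentation ring.

## Localization: circular Hough transform

The humeral head is quasi-circular in axial slices. Canny edges
(σ = 2 on the min-max-normalized image) feed a circular Hough
accumulator over radii 0.1–0.4 of the short image side; the peak gives
center and radius. Detection runs on the **SRAD-denoised** image: the
homomorphic compression would shift Canny's relative thresholds, and
the Hough stage needs only edges, not homogeneous intensities. Ties
among equal peaks break deterministically (largest radius, then
smallest row, then smallest column); a peak supported by less than 25%
of its perimeter raises a detection failure (e.g. blank input). The ROI
is the detected disk enlarged by factor 1.2 — the smallest factor that
keeps non-circular head parts inside the ROI on notched phantoms — and
the initial level-set contour is a concentric circle at half the
detected radius, strictly inside bone, suiting both the global and the
local engine.

## Segmentation engines

Intensities are rescaled to `[0, 255]` over the ROI before the
level-set engines run: the published weight set (ν = 1, μ = 0.2,
λ₁ = 0.7, λ₂ = 1, ε = 1.5) balances unit-scale regularizers against
squared-intensity data terms only on an 8-bit-like scale; on unit-scale
data the area penalty would dominate and collapse the contour.

**ACWE (Chan–Vese).** Gradient descent on the two-phase energy
`μ·length + ν·area + λ₁∫_in(u0−c1)² + λ₂∫_out(u0−c2)²` with the smooth
Heaviside `H_ε(φ) = ½(1 + (2/π)arctan(φ/ε))`; `c1, c2` are recomputed
each step over the ROI only, pixels outside the ROI are frozen.
λ₁ < λ₂ tolerates the varied grayscale inside bone (edema) against a
uniform background; the model is *global* — every bright object in the
ROI is segmented, so scapula and tendon removal is deferred to
postprocessing. Explicit update, `dt = 0.5`, curvature by central
differences with |∇φ| floored at 1e−8, no signed-distance
reinitialization (unnecessary at these budgets). Budget 650 iterations
with early stop when `(c1, c2)` change relatively less than 1e−4 for 5
consecutive iterations.

**SPF (signed pressure force).** The selective binary variant: per
iteration `φ += dt·(spf·(κ + α)|∇φ| + ∇spf·∇φ)` with
`spf = (I − (c1+c2)/2)/max|I − (c1+c2)/2|`, then φ is re-binarized to
±1 and regularized by a Gaussian (kernel 5 px, σ = 2) — the smoothing
replaces curvature-penalty regularization and gives the model its
*local* property: a front grown from the interior seed cannot jump to
disconnected bright objects. α = 20 (balloon), `dt = 1`, 120
iterations. Because φ stays in [−1, 1], the ε-regularized region means
blend both sides, which raises the effective threshold; on phantoms
this lands the SPF front close to the true border.

**GMM (EM).** ROI intensities are fitted with a k = 2 Gaussian
mixture: K-means initialization (cluster means, within-cluster
variances floored at 1e−10 of the data variance, cluster fractions),
then exact E/M steps until the summed squared parameter change falls
below 1e−6. A collapsing component (weight < 1e−6 or variance pinned
at the floor for 5 iterations) triggers a re-seeded restart, at most 3.
Labels are max-posterior; the cluster with the higher mean is bone.

**FCM.** Fuzzy C-means with c = 2, fuzzifier m = 2, seeded random
center initialization, membership update
`u_ij = 1/Σ_k(d_ij/d_kj)^{2/(m−1)}` (a pixel exactly at a center gets
full membership), center update by `u^m`-weighted means, convergence
when the max center shift < 1e−5. Coincident centers are perturbed
apart; the objective J is monotone non-increasing.

Both clustering baselines receive the same preprocessed ROI as the
level-set engines, for a like-for-like comparison.

## Postprocessing

The raw mask usually contains the scapular edge and tendon tissue of
bone-like intensity at the ROI periphery on the shoulder side.
Postprocessing: (1) the shoulder side is the image half with the
larger intensity mass; (2) within the annulus [0.8, 1.0] of the
enlarged ROI radius intersected with a 90° sector toward that side,
the mask is eroded with a 3-px disk (the smallest element that cuts
the few-pixel bridges to scapula/tendon); (3) connected components are
labelled and the one overlapping the 0.9-radius Hough disk best is
kept (robust when a scapula fragment is larger than a head sliver);
(4) the kept component is re-dilated with the same element and
intersected with the input mask — an opening discipline, so the output
never gains pixels; (5) interior holes (bright bone edema split off by
two-phase engines) are flood-filled; (6) the final 8-connected
boundary is traced (Moore neighbor tracing of the largest component).
An emptied mask falls back to the largest pre-erosion component with a
warning.

## Evaluation

Sørensen–Dice `2|A∩B|/(|A|+|B|)`, defined as 1.0 for two empty masks
(identity of indiscernibles). Batch runs are tabulated as mean/min/max
per method × patient group × {pre, post} stage.

## The phantom generator

No public PD shoulder dataset exists, so tests run on a seeded
generator emulating what the pipeline faces in a real axial slice:

- a bright quasi-circular head (radius 45 px at 256², intensity 180 on
  background 20) — *quasi*-circular: low-order radial harmonics
  (k = 3, 5, 8; amplitudes 2/1.5/1%) because real heads are not exact
  circles;
- optional hyperintense edema (1.5× head intensity), placed
  peripherally (post-traumatic edema sits near the impact site) and
  locally smearing the adjacent border (extra Gaussian blur, σ = 4, in
  a margin around the blob);
- optional Hill-Sachs notch: a circular bite carved from the rim,
  filled with hyperintense fluid/reactive edema (1.3× head) and with a
  smeared fracture border — the compressed zone changes the intensity
  distribution rather than leaving a clean void;
- a scapula arc (intensity 170) across a 100° span on the shoulder
  side, separated by a 6-px joint space, optionally connected to the
  head by a narrow contact bridge (the case postprocessing must cut);
  and a tendon band (intensity 160) running from the head toward the
  shoulder-side border;
- partial-volume blur of the whole scene (σ = 2 px): PD slices show a
  smooth transition zone between bone and soft tissue, not step edges;
- a multiplicative bias field 1 + a·s(x, y) with a = 0.3, s a
  normalized sum of two seeded low-frequency cosine modes;
- Rician noise from its exact two-channel definition
  `out = sqrt((clean + g₁σ)² + (g₂σ)²)`, σ = 10% of the head intensity.

The cohort generator jitters radius ±15%, intensities ±10%, edema
size/position, and notch angle/depth per case, in three groups
(normal, edema, Hill-Sachs) mirroring a normal/edematous/deformity
case mix at reduced scale.

**What the phantoms do not emulate:** anatomy-conformal shapes, k-space
sampling artifacts, partial-volume fat/water mixtures, the full
soft-tissue context of a shoulder (muscle everywhere rather than dark
background), or expert manual-segmentation variability. Passing the
phantom suite therefore shows the pipeline's internal consistency and
its behavior under the modelled degradations — not clinical-grade
accuracy on real slices. On these phantoms all four engines score far
higher (Dice ≈ 0.95–0.99) than any method does on real data, and
sub-pixel boundary-placement systematics, rather than gross robustness
differences, can dominate the between-method ranking (see
Limitations).

## Problem sizes and runtime

Default test/acceptance sizes: 256×256 phantoms; a 12-slice cohort
(4 per group) for the between-method comparison; 20-iteration SRAD
runs for the denoising metrics; n = 2000 for the mixture-recovery
simulation. The full suite runs in well under a minute on one CPU; the
acceptance script in ≈30 s.

## Known limitations

- The between-method Dice ordering on phantoms does not fully
  reproduce the ordering reported on real patient data. ACWE and SPF
  differ here by fractions of a percent dominated by sub-pixel
  threshold placement (SPF's blended region means accidentally cancel
  the homomorphic edge shift), and the K-means-initialized GMM can
  converge to a local optimum that splits the bias-widened head
  distribution, scoring below FCM. These are properties of the
  methods on this synthetic data, reported as measured.
- Postprocessing assumes a single dominant head component and a
  shoulder-side scapula; bilateral or heavily off-center anatomy would
  defeat the side heuristic.
- The homomorphic filter cannot separate a bias field from anatomy of
  the same spatial frequency; its benefit is bounded by `g_low` and it
  slightly displaces edges outward.
- ACWE's printed weight set is interpreted on a 0–255 intensity scale;
  images preprocessed to other scales are rescaled internally, so
  absolute MR units never reach the engines.
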