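# Methods

`specreg` registers a vibrational-microspectroscopy region of interest (the
*template* or *fixed* image — FTIR or CARS, one spectrum per pixel) onto an
H&E-stained whole-slide RGB photograph (the *moving* image) of the same
section. The pipeline has four stages: preprocessing, presegmentation,
metric evaluation, and optimization. This note records the model behind
each stage, the parameters that matter, the numerical choices, and the
limitations of the synthetic evidence.

## Preprocessing

**Spectral side.** The cube is collapsed to an integral-absorption image
(trapezoid rule over the wavenumber axis, so values are in absorbance ·
cm⁻¹). A parameter-free Otsu threshold (256-bin histogram) splits that
image into substrate and sample; pixels strictly above the cutoff are
foreground. Otsu's scan returns the center of the last background bin; we
use that bin's *upper edge* as the effective cutoff so that a data value
quantized into the background bin can never end up in the foreground (this
matters for images with few distinct values). The rule is equivariant
under positive rescaling of the intensities. Intensity-cutoff background
identification presumes the field of view actually contains substrate:
Otsu always produces a split, so a template lying entirely on tissue would
have its lowest-absorbing class misread as background. The pipeline
therefore validates the split physically — bare substrate absorbs an order
of magnitude less than tissue, so if the background-class mean intensity
exceeds 30 % of the foreground-class mean (configurable), the split is
rejected and the whole template is treated as foreground. An externally
supplied mask file is also accepted.

**Stained side.** The slide is first resampled to the spectral pixel size
with anti-aliased area (box) averaging — exact area integration, so the
area-weighted mean intensity is preserved; a requested upscale falls back
to bicubic with a warning. The global stain/illumination cast is then
removed: subtracting the background color vector in optical-density space
(OD = −log₁₀ I/255) is identical to a per-channel division in intensity,
`out = round(255 · min(1, in/bg))`, which also avoids log(0). The
background color is estimated automatically: pixels at or above the 90th
luminance percentile (luminance = 0.299R + 0.587G + 0.114B) locate the
bright background mode; because averaging only that upper tail would bias
the estimate bright by about one noise standard deviation, the selection
is widened to all pixels within 3 robust standard deviations (1.4826·MAD)
below the candidates' median luminance before taking the mean color. If
the selected pixels are not actually bright (mean luminance < 128) the
image has no usable background and the color must be supplied manually.
After correction, colors within Euclidean RGB distance 15 of (255,255,255)
are snapped to pure white; exactly-white pixels define the histology
background mask. Both thresholds are exposed in the configuration because
no principled universal value exists.

## Presegmentation into index-color images

Each modality is reduced to an *index-color image*: background label 0,
foreground labels 1..k from k-means (k-means++ seeding, 5 restarts, best
inertia kept, tolerance 1e-4, ≤300 Lloyd iterations; scikit-learn backend).
Spectra are clustered as-is on Euclidean distance; the stained image is
clustered on its cast-corrected RGB vectors. Defaults follow standard
practice for this method: k = 10 for whole-slide images, k = 8 for the
smaller spectral ROIs. With k = 1 both sides degenerate to binary
foreground/background images, which is the "binary" variant of the method.
Labels are categorical; nothing downstream assumes any ordering.

## Metric: restricted mutual information

For a candidate transform the moving index image is resampled onto the
template grid (nearest label, see below) and the joint label histogram
over all m template pixels is formed. Plain mutual information
I = H(X) + H(Y) − H(X,Y) suffers from *background attraction* in template
matching: large empty slide regions produce high scores. Restricted mutual
information (RMI) injects the prior that label 0 means background in both
modalities. With p(x,y) the empirical joint distribution and α ∈ [0,1]:

    p_α(x,0) = (1−α) p(x,0)                        x ≠ 0
    p_α(0,y) = (1−α) p(0,y)                        y ≠ 0
    p_α(0,0) = (1−α) p(0,0) + α [P(X=0) + P(Y=0) − p(0,0)]

i.e. a fraction α of all background-mismatch probability is rerouted to
the background–background cell; foreground–foreground cells are untouched
and Σp_α = 1 identically. The score is

    I_α(X,Y) = H(X) + H(Y) − H_α(X,Y),   H_α = −Σ p(x,y) log₂ p_α(x,y),

a cross-entropy of the observed joint against the adjusted one, evaluated
with the observed p as the outer weight exactly as defined (we do not
"repair" it to −Σ p_α log p_α). By Gibbs' inequality I_α ≤ I₀, with I₀
the ordinary MI. One can show (and the tests assert) that the adjustment
term has the closed form

    I_α − I₀ = mm·log₂(1−α) + p₀₀·log₂(1 + α·mm/p₀₀),
    mm = P(X=0) + P(Y=0) − 2 p(0,0),

so the penalty grows with the background-mismatch mass mm and shrinks as
mass moves onto (0,0) — the precise sense in which background-to-background
matching is rewarded. Note the *full* score is not monotone under such a
move, because the standard-MI part changes with the marginals. Cells with
p = 0 contribute nothing; at α = 1 an observed background-mismatch pair
makes the score −∞, which the optimizer treats as worst-possible. Default
α = 0.25; logarithms are base 2 (scores in bits), configurable.

## Transformation model and resampling

Transforms are parameterized as (tx, ty, θ, s): rotation by θ degrees and
isotropic scaling s about the *template center*, then translation of that
center by (tx, ty) pixels relative to the moving-image center:

    x' = s·R(θ)(x − c_t) + c_m + (tx, ty),

0-based pixel-center coordinates, columns right, rows down. Centering
makes the four axes approximately independent, which the per-parameter
grid search relies on. Rigid motion fixes s = 1; translation-only also
fixes θ = 0. Default limits: s ∈ [0.8, 1.2], θ ∈ [−30°, 30°] for template
matching (±180° for full-slide registration). Because labels are
categorical the only meaningful interpolation is nearest-neighbour; ties
are broken half-up (toward +∞) so results are bit-reproducible. Template
pixels mapping outside the slide take label 0: off-slide means "no
sample", and keeping all m pixels in every histogram makes scores
comparable across transforms.

Rotation and scale are discretized in units derived from the template
geometry: one rotation unit is the angle that displaces the farthest
template pixel by one pixel (1/R_max radians, R_max the center-to-corner
distance), one scale unit likewise (1/R_max). The finest search spacing is
one unit per parameter — finer steps cannot change any resampled label.

## Optimizer: sparse coarse-to-fine search

Exhaustive search over a whole-slide rigid space (tens of millions of
grid points) is impractical; the sparse search decomposes the *search
space* instead of the image. Level 0 evaluates a full equidistant grid at
per-parameter spacing r₀. Each subsequent level halves the spacing (not
below one unit), evaluates all grid points within one previous-level
spacing (per dimension) of any retained point, and retains the candidates
whose score clears a decaying fractional threshold ν_thresh = k₀·δk^level
(defaults k₀ = 0.6, δk = 0.5; thresholds 0.6, 0.30, 0.15, 0.075, ...).
The search stops once every parameter has been refined at unit spacing
and returns the best point evaluated anywhere. An evaluation cache
guarantees no point is scored twice; enumeration order is fixed, so runs
are deterministic.

Two numerical choices make the fractional threshold meaningful on real
score landscapes:

* **Background normalization.** RMI landscapes sit on a pedestal — the
  median score over the space is roughly half the maximum, and raw or
  min-shifted fractions would retain nearly everything from level 1 on.
  A candidate is retained when score − median ≥ ν_thresh·(max − median),
  where median and max run over all evaluations so far; the median is a
  robust estimate of the background score level.
* **Retention cap.** On landscapes with broad skirts the thresholded set
  can still grow with every halving. At most `max_retained` (default 512)
  top-scoring candidates seed the next level; the running best always
  survives, so a unimodal basin — far smaller than the cap — is never
  affected, while worst-case work per level stays bounded.

**Initial radius by self-registration.** r₀ is not a user parameter. For
each enabled parameter the template is registered against itself along
that axis alone, giving a score profile peaked at the neutral transform.
Measured profiles on k-means index images have two features: a one-unit
spike at exact overlap (noise and pixel-level texture matching itself —
absent from the cross-modality landscape around the true optimum) and a
nonzero far-field pedestal (residual self-similarity of tissue texture
plus MI estimation bias). The half-width is therefore measured on the
structural component: with bg the sweep minimum and s(1) the first
off-peak score, r₀ is the largest contiguous displacement d with
s(d) ≥ bg + k₀·(s(1) − bg), the wider of the two directions, clamped to
≥ 1. If s(1) − bg is below 10 % of s(0) − bg the profile is
structure-free (pure speckle decorrelates after one unit) and r₀ = 1.
A template whose self-score at identity is not positive is rejected as
degenerate.

The scoring hot path (map 19k template pixels, gather labels, accumulate
the joint histogram, evaluate RMI) is a numba kernel split into
vectorizable passes over a zero-padded copy of the moving image (~60 µs
per evaluation on one core); a pure-numpy path produces bit-identical
integer tables and serves as the cross-checked fallback.

## Synthetic phantoms

All tests run on generated data. A phantom is a smoothed random "tissue"
label map (per-class Gaussian random fields, argmax composition, blob
scale 25 px by default ≈ 125 µm at 5 µm/px; a connected substrate frame
and ~20 % substrate overall), rendered twice:

* **slide**: per-class H&E-like colors (hematoxylin purples to eosin
  pinks, pairwise separation ≥ ~50 gray levels), substrate pure white,
  Gaussian sensor noise, then a global color cast applied as channel-wise
  multiplication by cast/255 (default cast (242, 232, 238));
* **ROI cube**: the label map sampled through a known ground-truth
  similarity transform (same mapping conventions as the registration
  itself), each class carrying a smooth random mixture of five Gaussian
  bands over 900–1800 cm⁻¹ (60 bands), substrate nearly non-absorbing,
  plus spectral noise.

Noise levels follow a class-SNR ≈ 10 rule: σ = (minimum pairwise class
separation)/(10·√dim) per channel/band, computed from the drawn spectra
and colors. Default geometry: slide 600×400 px and ROI 160×120 px at
5 µm/px; ground-truth transforms are rigid with integer translations
drawn uniformly over placements keeping the ROI on the slide and rotation
uniform in ±30°. Identical seeds give bit-identical phantoms.

What the phantoms do *not* emulate: Mie-scattering baseline distortions,
stain inhomogeneity beyond the global cast, morphological differences
between serial sections, and tissue whose index images are self-similar
over long ranges. Passing phantom tests therefore demonstrates the
correctness and robustness of the machinery under the stated noise model,
not clinical-grade performance on arbitrary slides.

## Evaluation batteries and problem sizes

The acceptance script and test suite recompute, from scratch:

* metric identities (1000 random joint tables; normalization to 1e-12,
  agreement with an independent contingency-table MI oracle, I_α ≤ I₀,
  and the worked 2×2 example p = [[0.4, 0.1], [0.1, 0.4]], α = 0.5 →
  p_α = [[0.5, 0.05], [0.05, 0.4]], I_0.5 ≈ 0.2068 bits vs I₀ ≈ 0.2781);
* optimizer oracle equivalence (200 anisotropic Gaussian bumps on a 65×65
  translation grid, σ ∈ [3, 6], r₀ set to each map's measured basin
  half-width at k₀; sparse search must reproduce the exhaustive argmax
  while evaluating a small fraction of the grid);
* self-registration sanity on three phantom templates (neutral transform
  maximal on every 1-D sweep; estimated r₀ never above the exhaustively
  measured half-width);
* end-to-end recovery on 50 seeded default phantoms (success = within
  2 px translation and one rotation unit), plus a noise-free identity
  phantom recovered exactly;
* robustness sweeps for α ∈ {0.2, 0.3, 0.4} and k_fixed ∈ {6, 8, 10} on a
  20-phantom subset (the α sweep reuses cached joint tables; sweep size
  is chosen to keep the full battery at desk scale);
* preprocessing fidelity (cast-corrected substrate pixels snapped to
  white; Otsu mask matching the phantom substrate within a one-pixel
  boundary tolerance).

## Known limitations

* The optimizer is a global grid search; accuracy is limited to the grid
  resolution (1 px, one rotation/scale unit). No sub-unit refinement is
  attempted because nearest-label resampling is piecewise constant.
* Self-registration estimates each radius with the other parameters held
  neutral; strongly coupled landscapes (large rotations combined with
  large scale changes) could have narrower joint basins than the 1-D
  sweeps suggest.
* The metric treats label images as unordered categories, so it cannot
  exploit partial spectral similarity between clusters.
* Non-rigid deformation between the spectral and stained acquisitions is
  out of scope; the model is a global similarity transform.
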