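# Methods

## The measurement model

The *Drosophila* compound eye is a hexagonal lattice of ~750 ommatidia; in a
healthy eye each ommatidium has six neighbors at (nearly) equal distance and
60° angular increments. `ommascore` treats lattice disorder as the phenotype:
for every detected ommatidial center the fan of six nearest-neighbor vectors
is compared against hexagonal symmetry through two indices,

- ODI_D (dimensionless): sum over the five non-minimal vectors of
  (|vᵢ| − |v_min|)/|v_min|. When several vectors share the minimum length,
  exactly one — the first in angular order — is designated v_min and excluded
  from the sum. Length-ratio form makes the index scale-free.
- ODI_A (radians): sum over the six cyclically adjacent vector pairs
  (v₇ ≡ v₁) of 2·|acos(vᵢ·vᵢ₊₁/‖vᵢ‖‖vᵢ₊₁‖) − π/3|. Dot products make it
  rotation-free.

Both are exactly zero on a regular hexagonal fan, so the point-set score is
invariant under translation, rotation and uniform scaling (tested to 1e−9).

Per eye, ommatidia are sorted ascending by total index d = ODI_D + ODI_A,
ties broken by distance to the eye center (mask centroid when an image was
scored, centroid of the centers otherwise), and the N most ordered are
aggregated as ODI_T = Σ log1p(d). The phenotypic score is
P = (ODI_T / N_used) / log Z with Z the number of detected centers (fusion
index). Fewer detectable ommatidia — fusion — raises P, as does any lattice
distortion. P = 0 exactly on a perfect lattice.

### Aggregation conventions

- **log1p rather than log.** Summing log d diverges to −∞ at perfect order;
  log1p(d) is monotone in d, asymptotically log d for large d, and exactly 0
  at d = 0, which realizes the zero-entropy limit. A strict mode
  (`strict_log=True` / `--strict-log`) sums log(d + ε) with ε = 1e−9 for
  users who want the raw logarithmic form.
- **Normalization.** ODI_T is divided by N_used (per-ommatidium mean) before
  the 1/log Z factor, so scores are comparable across choices of N; the
  class ranking is empirically stable for N ∈ {150, 200, 250, 300}.
- **Default N = 200** most-ordered ommatidia per eye. N must be held fixed
  within an experiment. If Z < N the aggregator warns and uses all Z.
- **Logarithms** are natural throughout.
- **Zero clamp.** Computed ODI values below 1e−9 are clamped to exactly 0:
  lattice row offsets involve √3/2, so even an exactly regular fan carries
  ~1e−15 floating-point residue, and the clamp makes "perfect symmetry ⇒
  exactly zero score" hold as an identity. Any real disorder is orders of
  magnitude above the clamp.

## Image pipeline

**Eye localization, bright-field** (eye = cluster of bright reflection
spots): white top-hat with a disk of radius 6 px removes every structure
wider than the structuring element, keeping the per-ommatidium spots;
a 3×3 Sobel gradient magnitude thresholded at 0.15× its maximum marks spot
edges; closing with a disk of radius 10 px (about one lattice spacing, so it
bridges inter-ommatidial gaps) plus hole filling fuses the cluster; the
largest 8-connected component (area ≥ 5,000 px) is the eye. Area ties are
broken toward the image center. **SEM**: low eye/background contrast makes
the top-hat unreliable, so the image is thresholded at its global mean
intensity (the brighter side is the eye by default; `--sem-foreground dark`
flips this for the opposite detector polarity), then closed and filled the
same way. Output is always a single hole-free mask.

**Center detection** operates in bright-center polarity (SEM inverted
first): contrast stretch inside the mask → white top-hat (disk radius 4 px)
→ median filter (radius 2 px, removes boundary-reflection noise) → one
dilation/erosion round (disk radius 1) → local maxima at ≥ 0.1× the in-mask
maximum. Plateau maxima contribute their centroid rounded to the nearest
pixel (snapped back onto the plateau if rounding leaves the mask). Greedy
suppression enforces a minimum separation: higher intensity wins, ties in
row-major order. By default the separation is adaptive — half the lattice
spacing, with spacing estimated as the median nearest-neighbor distance of a
provisional maxima pass — so the detector follows magnification without
retuning. All structuring-element radii are exposed and `Config.scaled()`
rescales them for other resolutions.

Numerical note: grayscale and binary morphology with disk radii ≥ 12 px runs
through histogram-based rank filters, whose cost is independent of radius;
results are identical to plain structuring-element morphology except within
one radius of the image border, where the footprint is cropped instead of
padded (the border is background in every intended use).

## Synthetic scenes

The generator emulates the geometry the scoring model assumes: a hexagonal
lattice (spacing 10 px) clipped to an ellipse with semi-axes (126.5, 163.75)
px inside a 300×400 image — calibrated once so the zero-jitter scene contains
exactly 750 centers, the canonical ommatidium count, and then frozen. The
lattice origin is offset from the ellipse center by 0.3× the spacing because
a perfectly centered (mirror-symmetric) lattice can only realize odd counts.
Disorder enters as isotropic Gaussian jitter of each center (σ in px) and as
fusion, the uniform random removal of a fraction of centers, matching Z's
definition as the number of *identifiable* ommatidia. Jittered points that
would leave the ellipse are projected radially just inside the boundary, so
ground truth always lies within the eye. Jitter, fusion and render noise use
independent substreams of the scene seed, so the same scene topology is
compared across jitter levels and across resolutions (`spec.scaled(k)`
multiplies every length; the random draws are reused, giving an exactly
scaled scene).

Rendering: bright-field = dark background (20), convex-shaded dome
(≈ 58–83), additive Gaussian reflection spot (σ = 2 px, amplitude 147) per
center; SEM = mid-gray background (80), light eye field (≈ 184–200),
subtractive Gaussian dip (amplitude 100) per center; Gaussian read noise
(σ = 3 levels) on top. What this does **not** emulate: bristles, pigmentation
gradients, necrotic patches, specular glare, focus gradients, perspective
curvature of the eye surface. Passing tests therefore demonstrate the
algorithmic contract (detection accuracy, score monotonicity, invariances),
not robustness to every artifact of real microscopy.

A detection noise floor is expected and visible: detected centers are pixel
quantized (~0.45 px mean localization error), so even zero-jitter renders
score P ≈ 0.05 rather than 0. The identity P = 0 holds for the ground-truth
point set; dose-response claims are made on means across seeds, where the
floor is common to all classes.

## Statistics

Group comparisons use the two-sample t-test, Welch form by default (class
variances differ strongly across phenotype severities), with Bonferroni
correction across the comparisons in one call — the most conservative simple
choice, switchable to none. Rank agreement with an external severity
ordering uses Spearman correlation (Pearson available). The small-sample
utility resamples all n-image combinations (with replacement) per class,
takes each combination's mean score, and compares classes by two-sided
Mann-Whitney U; with 10 images per class this separates unjittered from
0.1×-spacing jitter at p < 0.001 already at n = 3.

## Problem sizes used in the shipped checks

Acceptance-level checks run the full image pipeline on 300×400 scenes: ten
seeds per class for the detection contract and the jitter (5 levels) and
fusion (4 levels) dose-response suites; five seeds at 600×800 and 1200×1600
for resolution robustness (mean P agreement within 10%; observed ≪ 1%);
`scripts/acceptance.py` uses six seeds per sweep level and reports means.

## Known limitations

- Eye size/area is not a phenotype here (Z enters only through 1/log Z);
  bristle, pigmentation and photoreceptor-integrity phenotypes are out of
  scope.
- One eye per frame is assumed (largest-component rule).
- The exact filter chain of the original enhancement step is not uniquely
  determined by its published description; the sequence above is one
  faithful, fully parameterized reading, and every stage is configurable.
- The SEM threshold direction depends on instrument polarity; the default
  assumes a bright eye on a darker background.
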