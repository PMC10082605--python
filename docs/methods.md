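# Methods

`scarmorph` classifies skin tissue as *normal*, *keloid scar*, or
*scar-adjacent* from paired label-free multiphoton images: a collagen
channel (second-harmonic generation, SHG) and an elastin channel
(two-photon excited fluorescence, TPEF) per imaged region. This note
describes the models, the numerical choices, and what the synthetic data
do and do not demonstrate.

## Pipeline

1. **Denoise.** Each channel is median-filtered (3×3, edge-replicated).
   The filter is a configurable stage (`FeatureConfig.denoise_window`,
   `None` disables it): the small median removes impulsive photon-counting
   noise without blurring fiber edges. No specific denoiser is canonical
   for this imagery; this one is a deliberate, replaceable default.
2. **Features.** 14 features per channel, 28 per region:
   - *morphology* (4): density, fiber length, fiber width, alignment `k`;
   - *histogram texture* (6): mean intensity, standard deviation,
     smoothness, skewness, uniformity, entropy;
   - *GLCM texture* (4): contrast, correlation, energy, homogeneity.
   A sample's 2–3 regions are averaged feature-wise into one 28-vector.
3. **Ranking.** Minimum-redundancy maximum-relevance (MRMR) ordering of
   the 28 features, then 28 nested subsets (top-1, top-2, …, top-28).
4. **Classification.** A linear SGD classifier per subset, scored by
   leave-one-out (LOO) cross-validation repeated 5 times; the smallest
   subset attaining the best mean accuracy is selected and its held-out
   scores yield one-vs-rest ROC/AUC per class.

## Morphological features

**Density** is the fraction of pixels above Otsu's global threshold.
"Effective pixel" has no unique definition for fluorescence images; Otsu
is parameter-free and standard for bimodal histograms. Flat images
short-circuit to density 0 (Otsu is undefined without variance).

**Alignment** is the concentration `k` of a semicircular von Mises
distribution fitted to the FFT-derived fiber orientation distribution:

    f(θ; μ, k) = exp(k·cos 2(θ−μ)) / (π·I₀(k)),   θ ∈ [0°, 180°)

`k = 0` is isotropic; larger `k` means tighter parallel alignment. The
orientation distribution is built from the 2-D power spectrum: Hann
window → FFT → zero-centered power → band-pass (DC disk of radius
`r_min = 4` cycles/image removed; radii above 0.8·Nyquist removed) →
radial sum into 180 one-degree bins → 90° rotation (a fiber at θ
concentrates spectral power along θ+90°) → normalization. The window is
on by default because the discontinuity at a non-periodic image border
otherwise injects an axis-aligned spectral cross that distorts the
angular mass. Fitting is nonlinear least squares on the binned mass with
moment-based initialization (μ from the mean resultant direction of the
doubled angles; k by the standard piecewise inversion of
A(k) = I₁(k)/I₀(k)), k bounded to [0, 500], with restarts at μ₀±45°/90°.
Exponentially scaled Bessel evaluation keeps large k stable. An exactly
uniform distribution fits k = 0; a tabulated closed-form density is
recovered to better than (1°, 0.05) in (μ, k).

**Fiber length and width** come from a transparent tracing stand-in for
curvelet-based fiber extraction tools: Otsu mask → morphological
skeleton → removal of branch points (more than 2 skeleton neighbors) →
8-connected segments walked end to end. Length is the inter-pixel step
sum (1 axial, √2 diagonal) plus one; width is twice the mean Euclidean
distance transform of the mask along the traced path. Segments shorter
than 10 px are discarded (configurable). This preserves the measured
quantities — per-fiber width and length — with an auditable algorithm,
but it is not a reimplementation of any curvelet pipeline: dense
crossings fragment fibers at branch points, so absolute lengths
underestimate true fiber lengths in crowded scenes. Within-study
*contrasts* (scar vs normal) are preserved, which is what the classifier
uses.

## Texture features

Histogram statistics use the normalized gray-level histogram p(zᵢ) over
L = 2^bit-depth levels: mean, standard deviation σ, smoothness
R = 1 − 1/(1+(σ/(L−1))²) (normalized so R ∈ [0,1) at any bit depth),
standardized skewness (0 when σ = 0), uniformity Σp², entropy −Σp log₂p
in bits.

The GLCM is computed on intensities linearly quantized to 8 levels,
accumulated symmetrically over the four unit-distance directions
(0°/45°/90°/135°), summed *before* normalization, then reduced to
contrast Σ(i−j)²p, correlation (defined as 1 when a marginal standard
deviation vanishes — a constant image co-occurs only with itself),
energy Σp², and homogeneity Σp/(1+|i−j|). Level count, distance and
directions are configurable; matrices-then-features (rather than
per-direction features averaged) is fixed and documented as the
package's convention.

## MRMR ranking

Relevance of feature x is the mutual information I(x; c) with the class
label; the m-th feature maximizes

    I(xⱼ; c) − (1/(m−1)) · Σ_{xᵢ ∈ S_{m−1}} I(xⱼ; xᵢ)

over candidates (the additive, "MID" criterion; the quotient variant is
not implemented). With a few dozen samples, continuous MI estimation is
hopeless, so features are cut at empirical quantiles into at most 4
equal-frequency bins (duplicate edges merged; constant features collapse
to one bin and carry zero information) and MI is the plug-in estimate in
bits. Two numerical details matter on tables this small: MI term
summation is done in sorted order so that I(x;y) = I(y;x) bit-exactly,
and greedy scores within 10⁻¹² are treated as ties and broken toward the
canonical feature order (distinct columns frequently share a
joint-histogram shape, making their scores mathematically equal).
The base of the logarithm cancels in the argmax, so the ranking is
base-invariant.

## Classifier and evaluation

The final model is a one-vs-rest linear SGD classifier with
modified-Huber loss and elastic-net penalty: α = 0.001, η₀ = 0.01,
constant learning rate, fitted intercept. `power_t` (0.5) is stored for
fidelity to the model description but is inert under a constant
learning-rate schedule. The elastic-net mixing ratio defaults to 0.15.
Features are z-scored *inside each training fold* — SGD at a constant
learning rate is scale-sensitive, and the held-out sample must not touch
the standardization statistics (this no-leakage property is asserted by
a test that perturbs a held-out sample and checks the fold's weights are
unchanged).

Evaluation is leave-one-out: n folds for n samples, deterministic given
the model seed. The subset sweep evaluates all 28 nested subsets with 5
differently-seeded LOO repeats and averages; the best subset size is the
smallest one attaining the maximum mean accuracy (parsimony tie-break).
One-vs-rest ROC curves come from held-out modified-Huber probability
scores; AUC is trapezoidal and, with tied scores collapsed into single
ROC steps, equals the rank-based Mann–Whitney statistic
U/(n₊·n₋) exactly.

Group differences per feature use the two-sided Mann–Whitney U test
(exact null for combined n ≤ 20 without ties, tie-corrected normal
approximation otherwise). No multiple-testing correction is applied
across the 28 features; reports say so.

## Synthetic cohorts

No patient imagery ships with the package; a simulator generates
cohorts with the study's design: 16 scar and 10 normal tissue-section
samples plus adjacent-region samples from 8 specimens (34 samples), each
with 2–3 imaged regions at 512×512 px, 8-bit, features averaged per
sample. Fibers are quadratic-Bézier strokes of class-specific width,
with orientations drawn from the semicircular von Mises law by the
doubled-angle construction (sample the ordinary von Mises on the full
circle at 2μ, halve), per-fiber Gaussian intensity, additive Gaussian
background noise, and a uniform background level. Rendering is
supersampled 3× and box-filtered down: integer rasterization of oblique
spines otherwise leaves staircase artifacts that scatter spectral power
across angles and depress fitted k by ~20%.

Class presets encode only the qualitative contrasts reported for keloid
tissue — scar fibers short, discrete and disordered
(k: 0.5–0.6, length ≈ 45–55 px); adjacent fibers highly ordered
(k: 6–7); normal fibers long and continuous (k ≈ 2,
length ≈ 160–180 px); elastin thinner and dimmer than collagen. No
published per-class fiber geometry exists to calibrate against, so the
magnitudes are plausible choices, not measurements. Each region draws a
random dominant orientation shared by its two channels. Every stream
seed derives from the master seed via a documented
(class, sample, region, channel) `SeedSequence` counter scheme, so
cohorts are pure functions of their design.

**What passing tests show — and do not.** The synthetic classes are
separated by construction in several features at once, so perfect or
near-perfect LOO accuracy on simulated cohorts demonstrates that the
pipeline *wiring* is sound (no leakage, correct aggregation, a
classifier able to use the features), not that real keloid tissue is
this separable. Real SHG/TPEF imagery adds depth-dependent attenuation,
cellular autofluorescence, and fiber morphologies far richer than
Bézier strokes; published clinical performance figures are not
reproducible from, and are not targets for, this simulator.

## Known limitations and numerical notes

- The FFT/von-Mises alignment estimate carries a small negative bias
  that grows with k (spectral sidelobes of finite, hard-edged fibers
  form an isotropic pedestal; fiber crossings add to it). Under
  benchmark scenes (150 straight, equal-intensity, noise-free fibers of
  length 300 px at 512 px), median fitted k over 10 scenes is within
  ~15% of generating k ∈ {1, 2, 4, 8} and strictly monotone in it.
- Fitted k is exactly invariant under 90° grid rotation. Under 45°
  rotation it is only statistically stable: single scenes fluctuate
  10–30% because the interference pattern of crossing fibers
  reconfigures; 10-scene medians agree to well within 25%. Tests assert
  exactly that, not single-image invariance.
- Fiber tracing reports length 0 and width 0 for images with no
  traceable segments; zero-variance images short-circuit every
  morphological feature to 0.
- Problem sizes in the test suite are chosen for desk-scale runs: the
  full-design cohort (34 samples, 512 px) is extracted once per session;
  property sweeps use 9-sample cohorts at 160 px with proportionally
  scaled fiber geometry.
- Staged execution (`simulate`/`extract`/`rank`/`evaluate`) and the
  one-shot `run` share one code path over on-disk artifacts, so equal
  seeds give byte-identical outputs; every run writes `run_meta.json`
  with the resolved configuration and seeds.
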