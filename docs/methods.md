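# Methods

This note documents the models, defaults, and design choices behind
`fibroquant`, and what the synthetic validation does and does not show
about real tissue.

## Optical model and deconvolution

Brightfield absorbance is treated as ideal Beer–Lambert: per channel,
OD_c = log10(I0_c / I_c) with blank-field intensity I0 (default 255 per
channel), and ODs of co-localized stains add. A stain is a unit vector of
per-channel absorbances; the deconvolution basis is the widely used H-DAB
calibration — hematoxylin ≈ (0.650, 0.704, 0.286), DAB ≈ (0.269, 0.568,
0.778) after normalization — with the residual completing the basis as the
normalized cross product of the two. The cross product necessarily carries
one negative component; forcing it non-negative would make the matrix
nearly singular, so non-negativity is enforced only for the two physical
stains. Real scanners need their own calibration; the basis is a plain
constructor argument.

Numerical choices: transmitted intensity is floored at `i_min = 1` before
the log (bounding the OD of saturated-dark pixels at log10(255) ≈ 2.41);
ODs of pixels brighter than the blank field clip to zero; per-pixel
unmixing solutions with negative stain amounts (noise off the stain plane)
clip to zero by default. The un-clipped solve agrees with an independent
per-pixel 3×3 linear solve to machine precision, and an 8-bit round trip
(compose → quantize → measure) stays inside the propagated quantization
bound: a quantized channel value q constrains OD to a width of
log10((q+0.5)/(q−0.5)), and multiplying that width by |V⁻¹| bounds the
concentration error. Note this bound grows steeply for dark pixels: a flat
"±0.02 OD" guarantee only holds while total OD stays below roughly 1.4.

## Stratification and per-region summaries

Stain amounts are classed negative/weak/medium/strong by three descending
transmission cutoffs, defaulting to 220/175/100 — common positive-pixel
values, deliberately overridable because real calibrations are set by a
pathologist per stain and scanner. Classification compares in
concentration space so a pixel exactly at a cutoff lands in the darker
class (fixed, testable tie rule). Reported strata are cumulative (strong ⊂
medium ⊂ weak); exclusive bands are derived properties. The mean positive
OD is computed over positive pixels only, so it measures stain darkness
independently of the positive-area fraction that multiplies it in the DAB
score — the two factors of the score stay orthogonal.

## Tiling

Tiles are 0.25 mm squares (a studied convention for this tumor type),
anchored at the image origin in half-open pixel intervals, edge tiles kept
at their true size. Tissue validity is decided per pixel center: inside
the union of include-polygons (whole image if none) minus all
exclude-polygons; a tile is retained when its valid fraction reaches 0.5
by default. Pixel-center rasterization and the GeoJSON annotation format
keep the geometry unambiguous and testable against an independent
point-in-polygon oracle.

## Nuclear morphometry and the chromatin density ratio

Nuclei are segmented on the hematoxylin concentration of the negative
control (hematoxylin-only) image: threshold at the weak cutoff equivalent,
fill holes, split touching blobs by watershed on a Gaussian-smoothed
Euclidean distance transform, and drop components outside 8–400 µm².
Marker spacing (`min_peak_distance_um`, default 2.0 µm) and smoothing
(`smooth_sigma_px`, default 1.75) trade under- against over-segmentation:
the smoothing must erase the shallow double maxima that discrete distance
transforms produce inside bent, elongated nuclei, while the marker window
must stay below the center distance of genuinely touching nuclei. The
defaults split end-to-end touching pairs with a clear neck and count
non-touching synthetic nuclei exactly; densely overlapping clusters are
out of scope.

CDR is computed on intensity classes restricted to segmented nuclear
pixels: the numerator is the *exclusive* medium band (medium and not
strong), matching the reading that medium marks open/active and strong
marks condensed/inactive chromatin as disjoint classes; a cumulative
variant is emitted alongside for sensitivity. A zero denominator yields a
flagged missing value rather than infinity — downstream analyses work on
log CDR (natural log; correlation is base-invariant) and drop missing
pairs, reporting n. In the full pipeline both CDR and nuclear size come
from the negative control, mirroring how nuclear measurements avoid
DAB-obscured counterstain.

## Cluster-aware statistics

ROIs within a patient are correlated, so all inference clusters on
patient.

* **Correlations.** Pearson point estimate on complete pairs; CI and p by
  resampling patients with replacement (2000 replicates by default, all
  rows of a sampled patient entering, duplicated clusters kept). The CI is
  the *expanded percentile* interval: plain percentile intervals are
  systematically narrow at small cluster counts (measured ≈ 0.93 coverage
  at 29 clusters during development), and widening the tail levels to
  match a t(K−1) reference restores ≈ 0.94 coverage; the plain interval
  remains available. The p-value is twice the fraction of replicates whose
  correlation has the opposite sign to the point estimate, clipped to
  [2/B, 1] — a sign-flip construction with a resolution floor. p-values
  are reported raw (unadjusted), labeled as such in the report header.

* **Group comparisons.** GEE with Gaussian family, identity link,
  exchangeable working correlation. With 6–7 clusters per group the
  conventional sandwich Wald test rejects far too often (measured ≈ 0.11
  at nominal 0.05), so the default pairs the Mancl–DeRouen bias-reduced
  sandwich with a t(K−2) reference, measuring ≈ 0.04 — slightly
  conservative, the safer direction at this size. A group reduced to a
  single cluster falls back to a Welch t-test on cluster means, flagged in
  the output. MTA (the ordinal 1–4 activity score) is treated as numeric
  for correlation, matching how such scores are commonly summarized;
  Spearman is a caller-side option.

## Synthetic data

The slide generator emulates the features the pipeline measures, not
histology at large. A smooth latent activity field a(x, y) ∈ [0, 1]
(rank-normalized Gaussian random field; correlation length 120 µm by
default, giving both abrupt and blended transitions) drives: nuclear
density (300 → 1200 /mm²), nuclear geometry (semi-axes from thin
4.5 × 1.2 µm ellipses at a = 0 to plump 4.4 × 3.1 µm ovals at a = 1, with
lognormal size jitter), per-nucleus chromatin mix (strong-pixel fraction
0.85 → 0.15), collagen background hematoxylin (0.03 → 0.01 OD, kept below
the weak cutoff so nuclei segment cleanly), and DAB (base 0.05 + gain
0.45 × a, localized nuclear / cytoplasmic / both per stain). Placement is hard-core thinned
Poisson (no overlap; an optional touching-pairs fraction adds end-to-end
twins to exercise watershed splitting); images are composed in OD space
along the stain vectors, Gaussian OD noise (σ = 0.01) added, transmitted,
and quantized to 8 bits. Hematoxylin OD levels for medium (0.28) and
strong (0.65) chromatin sit mid-band between the default cutoffs. Every
slide ships with a hematoxylin-only negative control of the identical
nuclei and a full truth bundle.

What this does *not* show: stain-vector miscalibration, uneven
illumination and background, chromatin texture within nuclei,
anti-aliased nuclear boundaries, overlapping nuclei in thick sections, and
batch effects are all absent. Passing recovery tests therefore validate
the pipeline's arithmetic and geometry, not its robustness to real-world
staining variation — thresholds and stain vectors must be calibrated on
real material.

The cohort generator draws patient → sample → ROI Gaussian effects
(SDs 0.5 / 0.3 / 0.8), maps the latent sum through the normal CDF to a
uniform activity (variance 1/12, making target correlations analytic from
the variance decomposition), and produces log nuclear size, log CDR, MTA
(cutpoints 0.3/0.5/0.7 on activity + noise), and four stain scores from
linear couplings plus patient-level stain effects. Defaults mirror the
study design this package targets: 29 patients × 11 ROIs, a 5-vs-7
expression-set split, and 6 non-recurring vs 7 early-recurring patients.
Outcome shifts raise three stains and lower one in early recurrers.

## Validation experiment sizes

The recovery experiments fix their own sizes, chosen for power rather than
realism: the slide-recovery experiment uses a 1.25 × 1.0 mm slide
(20 ROIs, ~800 nuclei); the cohort-recovery experiment uses 40 patients ×
2 samples × 6 ROIs with well-separated stain gains (analytic stain–CDR
targets ≈ 0.72/0.56/0.37/0.11) and 20-vs-20 outcome clusters, so a single
simulated cohort resolves the generated ordering and sign pattern;
calibration uses 500 coverage repeats (300 bootstrap replicates each) and
1000 GEE null repeats at the 6-vs-7 split. `scripts/acceptance.py` reruns
all of it from one seed.

## Known limitations

Single-plane images only (no pyramidal WSI formats); no stain-vector
estimation from data; no background/shading correction; no cross-stain
registration (each slide is analyzed independently with its own control);
MTA is emulated by ordinal cutpoints, not a model of a pathologist;
survival is dichotomized (early recurrence vs durable non-recurrence), not
modeled in time.
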