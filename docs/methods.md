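# Methods

`ptcmorph` quantifies peritubular-capillary (PTC) morphology from
endothelium-stained kidney images and explores its functional consequence
for tissue oxygenation. This note documents the models, estimators,
numerical choices, and the limits of what the synthetic-data validation can
show.

## 2D segmentation

Membrane (endothelium) stains outline capillary profiles as bright rings
with dimmer lumens. The segmentation chain is

1. percentile contrast stretch (defaults: 0.35 / 99.65 percentile → 0 / 255),
2. Gaussian smoothing, σ = 2.5 px (smooths the capillary outline),
3. a second contrast adjustment with a *background-aware black point*,
4. local adaptive thresholding (Bernsen or Phansalkar, circular window,
   radius 35 px),
5. dilate (3×3) → fill holes (4-connected, border-excluded background) →
   erode (3×3), which bridges small staining gaps and fills lumens,
6. a 1-px boundary-bias erosion (see below).

**Black point (step 3).** Fluorescence fields are majority background, so a
low-percentile stretch clips essentially nothing; after smoothing dims the
thin walls, a plain re-stretch amplifies background noise past the Bernsen
contrast threshold and floods the mask with noise particles. Step 3 instead
estimates the background level as the intensity mode, its noise as a robust
MAD, and maps mode + 3 SD → 0 — the same effect a careful manual
brightness/contrast adjustment has (dark flat background, bright outlines).
Set `background_black_point=False` in `RunConfig` for the plain percentile
behaviour.

**Local thresholds.** Bernsen: within the circular window, foreground iff
the local contrast (max − min) reaches 15 (8-bit scale) and the pixel
exceeds the local midgray; low-contrast neighborhoods are wholly
foreground iff their midgray is at least half the intensity range.
Phansalkar (intensities normalised to [0, 1]):
`t = m·(1 + p·e^(−q·m) + k·(s/R − 1))` with k = 0.25, R = 0.5, p = 2,
q = 10; foreground iff value > t. Both replicate the reference
auto-local-threshold defaults; all constants are exposed in `RunConfig`.
The min/max filters use an exact run-decomposition of the circular window
(O(radius) separable 1D passes); mean/SD use edge-padded FFT convolution.

**Boundary bias (step 6).** Thresholding a Gaussian-blurred thin membrane
places the cut near the outer half-maximum of the blurred wall profile,
about σ·√(2 ln 2) from the wall midline — systematically *outside* the true
outer edge when σ is comparable to the wall thickness. On calibrated
synthetic rings this inflates the minor axis by ≈ 0.8 px. A single final
4-connected erosion (`boundary_bias_px = 1`; 0 disables) removes the
offset; residual effects on very small, very elongated profiles are the
dominant remaining error (see Validation).

The pipeline is fully deterministic: same image + config ⇒ identical mask.

## Morphometry

Per particle (8-connected components; ROI membership decided by the
centroid; border particles kept; size filter 10–8000 µm² inclusive):

* **area** — pixel count × pixel_size²;
* **perimeter** — 8-connected outer boundary chain with Kulpa's corrected
  weights, 0.948 per straight and 0.948·√2 per diagonal step. The naive
  (1, √2) Freeman chain overestimates smooth perimeters by ≈ 5.5 % on
  average over orientations (circularity of a large digital disk ≈ 0.90);
  the corrected weights are asymptotically unbiased for smooth convex
  outlines (disk perimeter error < 1 % for r ≥ 10 px). Freeman and Crofton
  estimators remain available via `perimeter_method` because circularity is
  estimator-sensitive;
* **moment-equivalent ellipse** — orientation and axis ratio from second
  central moments (each pixel treated as a unit square: + 1/12 px² per
  axis, which keeps one-pixel-wide particles nondegenerate), axes scaled so
  the ellipse area equals the particle area. Consequently
  roundness = minor/major exactly;
* **Feret diameters** — max pairwise distance and rotating-calipers minimum
  width over the convex hull of the boundary-pixel corner points;
* **shape factors** — circularity = 4π·area/perimeter² (capped at 1.0;
  rasterisation can exceed the isoperimetric bound), roundness =
  4·area/(π·major²), plus bounding-box, aspect and Feret ratios.

Capillary density is the total particle area over the region area.

## Inter-capillary spacing

Each background pixel is assigned to the particle with the nearest
foreground pixel (exact Euclidean distance between pixel centers, one
distance transform per label, ascending label order so exact ties go to the
lowest id). Particle pairs whose compartments share a 4-adjacent pixel
pair are neighbors; for each pair the shortest boundary-pixel-to-
boundary-pixel distance is reported and the mean over pairs is the mean
inter-capillary distance. Distances are boundary-to-boundary (not
centroid); the mean is over neighbor pairs, not pixels.

## Shape statistics

Distributions of roundness/circularity are summarised over [0, 1] in
0.05-wide half-open bins (last bin closed) with mean, median, mode (modal
bin center, ties to the lowest bin), SD and IQR. ROC analysis sweeps all
distinct score values; AUC is the trapezoidal area, identical to the
concordance probability with ties counted ½; the Youden-optimal cutoff
maximises sensitivity + specificity − 1, ties resolved toward the lower
cutoff. Classification as "round" is inclusive (≥ cutoff); shipped default
cutoffs are roundness 0.47 and circularity 0.60 per capillary and mean
circularity 0.51 per region — they are defaults carried from the original
ROC analyses of undeposited clinical data, not quantities this package can
recompute. Group comparisons use the two-sided Mann–Whitney U (exact for
small untied samples), Kruskal–Wallis with Dunn–Bonferroni post hoc z
tests (pooled midranks with tie correction), and Spearman correlation for
ordinal covariates (GFR categories, IFTA grades).

## Oxygen unit-cell model

Steady zero-order diffusion–consumption in the tissue of one periodic
square cell of side L (the nearest-neighbor capillary distance), capillary
cross-section centered with fixed area A:

    α·D·∇²PO₂ = R,   PO₂ = P₀ on the capillary surface,
    ∂PO₂/∂n = 0 on the cell edges (lattice symmetry).

Defaults: α = 1.53×10⁻⁶ mol O₂ L⁻¹ mmHg⁻¹, D = 2.4×10⁻⁵ cm² s⁻¹,
R = 13.2×10⁻⁵ mol O₂ L⁻¹ s⁻¹, P₀ = 45 mmHg. Nondimensionalised with
u = PO₂/P₀ this is ∇²u = β, β = R/(α·D·P₀) ≈ 7.99×10⁻⁴ µm⁻². Reference
cases: physiological L = 20 µm, A = 80 µm² (density 0.20) and pathological
L = 25 µm, A = 62.5 µm² (density 0.10).

Discretisation: 5-point finite differences on a uniform N×N node grid
(default N = 256), staircase Dirichlet boundary on the rasterised
capillary, mirror-ghost Neumann edges, sparse direct solve. The
rasterisation thresholds the shape's implicit function at the quantile
matching the target node count, so the capillary area is exact to one node
(a naive inequality carries an O(h) area bias, noticeable for the rotated
square). The scheme is conservative: the discrete capillary-boundary flux
balances total consumption to solver precision. Validation against the
closed-form Krogh annulus profile
P(r) = P₀ + (R′/4)(r² − r_c²) − (R′·r_t²/2)·ln(r/r_c), R′ = R/(αD), gives a
maximum relative error < 2 % at N = 256; the mean tissue PO₂ changes by
< 0.2 % from N = 256 to N = 512. If the solution would go negative
(consumption too strong for zero-order kinetics) the solver raises rather
than clamps.

Shapes: circle (radius √(A/π)), axis-aligned ellipse with aspect ratio 2
(πab = A, a = 2b), and square (side √A) rotated 45° by default so its
corners point toward the neighboring capillaries. The lattice-aligned
square is a degenerate special case — its faces parallel to the lattice
planes produce quasi-one-dimensional diffusion and an artificially uniform
edge profile; the diagonal orientation is the representative misaligned
case. With it, the model reproduces the expected physiology: the circular
cross-section yields the most homogeneous edge PO₂, the elongated ellipse
the least, while mean tissue PO₂ varies by < 2 % across shapes at fixed L
and A and is higher in the physiological than the pathological case.
`orientation_deg` overrides the orientation for sensitivity analyses. The
edge profile is sampled counterclockwise from the mid-right edge point and
normalised by P₀; homogeneity is its SD and max − min.

## 3D vessel skeletons

Anisotropic stacks are linearly resampled along z to the in-plane voxel
size (original planes preserved). Bright tubes are emphasised per z-plane
with a Hessian ridge score (Gaussian-derivative Hessian at σ = 4 µm,
eigenvalues λ₁ ≥ λ₂; score σ²·|λ₂| where λ₂ < 0, else 0; reflective
boundaries), linearly scaled to 8 bits and thresholded at t = 100, then
thinned to a 26-connected voxel skeleton (medial-axis preserving).

Skeleton voxels are classified by 26-neighbor count (1 endpoint, 2 slab,
≥ 3 junction). Junction voxels within the local vessel radius are merged
into one branch point (thinning scatters junction voxels over a blob of
about the tube radius at each branching; the merge dilation defaults to
the median skeleton-sampled distance-transform radius). Segments are
maximal slab chains between node voxels; junction-attached ends are routed
to the branch-point centroid so the junction blob does not swallow length
from each branch. Segment length integrates Euclidean steps along the
voxel-center polyline after a 5-sample moving-average smoothing (endpoints
fixed) — the raw voxel chain overestimates curved lengths by ≈ 5 %, which
a straight segment does not suffer (its tortuosity is exactly 1).
Terminal tips are extended by one voxel along the terminal tangent when
the skeleton came from a thinned volume, compensating the one-voxel end
retraction of topological thinning. Tortuosity is length over end-to-end
distance (∞ for closed loops, which are excluded from the mean); radius is
the Euclidean distance transform of the binary volume sampled along the
skeleton — a documented substitute for thickness estimation from the
filtered image, whose exact original rule is unspecified. Terminal spurs
with fewer than 2 slab voxels are pruned and counted. Totals: volume
fraction, total/mean segment length, branch-point, segment and endpoint
counts, mean tortuosity.

On seeded synthetic tube trees (radius 3 voxels, segment lengths 30–60 µm)
segment and branch-point counts are recovered exactly and total length
within 2–4 %; a rasterised semicircle of radius 50 voxels yields tortuosity
within 0.3 % of π/2.

## Synthetic data

`make_scene_2d` renders non-overlapping elliptical annuli (bright wall,
dim lumen, textured background, angular wall-intensity jitter, Poisson +
Gaussian noise) with analytic truth per shape: area πab, roundness b/a,
circularity from the Ramanujan perimeter. Defaults, chosen once as
realistic acquisition/biology settings: pixel size 0.5 µm/px (a 200×
widefield configuration), wall thickness 1.5 µm, areas log-uniform over
15–2000 µm² (inside the 10–8000 µm² analysis window), outer minor diameter
floored at 5 µm (capillary caliber; elongation in section comes from cut
angle, not a narrower vessel — without the floor the sampler can emit
sub-erythrocyte "capillaries" whose wall exceeds their lumen), target area
fraction 0.12, noise scale 0.3. Presets: `control_like` aspect ratios
log-uniform 1.5–6 (predominantly elongated), `injury_like` 1–2 (rounder);
they emulate the *direction* of the disease contrast, not measured
distributions. All randomness flows through one seeded generator; scenes
are byte-reproducible.

What passing recovery tests show — and what they do not: on 200-shape
scenes the pipeline recovers mean roundness/circularity within ±0.05 and
round-capillary fractions within ±10 points of analytic truth, and
preserves the injury > control circularity ordering. The renderer omits
point-spread blur, uneven illumination, out-of-focus haze, touching or
overlapping profiles, and non-capillary stained structures, so these
results bound estimator error under controlled conditions; they do not
certify accuracy on real tissue. Residual bias is concentrated in small,
elongated profiles whose width approaches the smoothing scale.

`make_network_3d` grows random binary trees (odd segment count s;
junctions (s−1)/2, endpoints (s+3)/2) with ≥ 50° sibling divergence and a
3·radius clearance so the rasterised swept-sphere tubes realise the truth
topology; optional sinusoidal bending sets per-segment tortuosity, computed
analytically from the generating polyline.

## Problem sizes

Default validation sizes — 200 capillaries per 2D scene (≈ 1600² px),
oxygen grids N = 256 (one N = 512 convergence check), 13-segment networks
in ≈ 100–250³-voxel volumes, 50-seed spacing oracles on ≤ 128² images —
were chosen so the full suite exercises every claim at desk scale.

## Known limitations

* The 2D boundary localisation is accurate to about one pixel; shape
  factors of profiles narrower than ~4 px remain biased upward.
* Bernsen's low-contrast rule needs the background dark relative to
  half-range; the black-point stage provides this, but images whose
  background genuinely exceeds mid-range would need manual percentiles.
* The oxygen model is 2D, zero-order, single-capillary-periodic: no axial
  gradients, hemoglobin kinetics, Michaelis–Menten consumption or flow.
* Skeleton metrics assume tubes ≥ ~2 voxel radius; thinner structures
  fragment. Junction merging at the vessel-radius scale can absorb genuine
  segments shorter than the vessel diameter.
* Published clinical cutoffs (0.47 / 0.60 / 0.51) and AUCs ship as defaults
  only; the underlying biopsy data are not public and are not reproduced.
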