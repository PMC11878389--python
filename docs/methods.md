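# Methods

## The screening problem

Corneal topographers print color-coded axial-power maps; reading them is a
pattern-recognition task with a steep learning curve. The pipeline
implemented here follows the semi-automatic smartphone workflow: a printed
topogram is photographed, aligned to the application's 3/5/7-mm reference
zones, the examiner traces the colored relief, and a small convolutional
network classifies the traced pattern into four diagnostic classes —
spherical, regular symmetric astigmatism, regular asymmetric astigmatism,
and irregular astigmatism (keratoconus), the screening-positive class.
Because the original clinical image bank is private, the package ships a
parametric generator that emulates it; everything downstream is exercised
against that synthetic bank, plus a fixed confusion-matrix fixture holding
the published 212-image clinical test results.

## Surface model

Axial power on the 4.5-mm-radius corneal disc is modeled as

    K(r, θ) = k₀
            + Σ_{i ∈ {sup, inf}} Aᵢ · max(cos(θ − aᵢ), 0)² · w(r / eᵢ)
            + ΔK_cone · exp(−d((r,θ), (r_c,θ_c))² / (2σ²))
            + ΔK_central · exp(−r² / (2σ_c²))
            + ε(x, y)

* `k₀` — base power, drawn U(42.8, 44.2) D so normals sit in the green band.
* The cos² bow tie is the standard minimal model of regular astigmatism.
  Each semimeridian lobe carries its own amplitude `Aᵢ` (D) and radial
  extent `eᵢ` (mm); the half-wave rectification `max(cos, 0)²` confines each
  lobe to its own half so the two halves can differ. Lobe directions are
  `a_sup = φ` and `a_inf = φ + 180° + skew`, with the steep-meridian axis φ
  ~ U(0°, 180°); a non-zero `skew` produces the skewed-radial-axes
  (loss-of-perpendicularity) keratoconus variant.
* `w(x) = x² e^(1−x²)` is a smooth radial window: zero at the apex, peak 1
  at `r = e`, decaying beyond. At the contour level used below a lobe
  reaches ≈ 1.63·e, so extents are chosen so regular ties reach between the
  5- and 7-mm zones.
* The Gaussian cone (`ΔK_cone`, center (r_c, θ_c), width σ) models the
  localized ectatic steepening; an optional tangential smear (`cone_arc_mm`)
  turns it into the inferior arc of pellucid marginal degeneration.
* `ΔK_central` models post-refractive-surgery confounders attached to the
  spherical class only: negative (flatter, colder center) after myopic
  ablation, positive after hyperopic.
* `ε` is a smooth seeded noise field (12 random Fourier features,
  correlation length ≈ 0.8 mm, marginal s.d. `noise_sd` = 0.15 D by
  default), a pure function of position so `eval_power` is deterministic.

### Class parameter ranges (the generator's study conditions)

| class / variant | key draws |
|---|---|
| SPHERICAL (70% plain, 15% post-myopic, 15% post-hyperopic) | amplitudes 0; ΔK_central U(−4.5,−2.5) or U(2.0,3.5) D |
| SYMMETRIC | A U(2.0,4.5) D shared; e U(1.8,2.1) mm shared |
| ASYMMETRIC | inferior lobe as symmetric; opposite extent ratio U(0.55,0.75), amplitude ratio U(0.8,1.0); relative lobe difference ≥ 25% by construction |
| IRREGULAR, classic inferior (40%) | ΔK_cone U(3.0,6.5) D, r_c U(1.2,2.2) mm, θ_c U(200°,340°), σ U(0.7,1.0) mm |
| IRREGULAR, skewed (15%) | symmetric tie + skew ±U(35°,60°) |
| IRREGULAR, pellucid (15%) | arc cone: r_c U(2.0,2.6) mm, θ_c U(255°,285°), σ_r U(0.45,0.65), arc U(1.8,2.8) mm |
| IRREGULAR, incomplete tie (15%) | symmetric tie with e U(0.9,1.35) mm — reaches only the 5-mm zone |
| IRREGULAR, rudimentary tie (15%) | inferior lobe normal; superior amplitude ratio U(0.55,0.70), extent ratio U(0.25,0.34) |

The ranges were chosen once so that each class's defining geometry clears
the rule-classifier thresholds with a noise margin (labels are well-posed),
and are not tuned thereafter. The default bank composition is 275 / 302 /
295 / 300 images with 240 per class assigned to the train split by a seeded
within-class draw (the split being random within class is our reading; a
curated split was also possible), giving 960 train (81.91%) and 212 test
(18.09%).

All randomness flows from one integer bank seed through counter-based seed
spawning (`numpy.random.SeedSequence(seed, spawn_key=...)`), so per-image
draws are independent of generation order.

## Rendering and the color scale

No standard diopter color scale exists across topographers; the package
adopts an absolute scale 35.0–52.0 D in 1.5 D steps, twelve hues from blue
(cold/flat) through green (normal) and yellow to red (steep), so the
default k₀ falls in the green band. Rendering is a pure per-pixel binning
(invertible off the overlay, which the tests exploit), plus black 3/5/7-mm
zone rings and axis ticks on a white background. The canonical frame is
256×256 px with the disc inscribed (mm/px = 9/256), superior at the top,
θ counter-clockwise from the rightward horizontal.

## Capture simulation and rectification

A hand-held capture is simulated by mapping the canonical frame onto a
random convex quad (corners pulled inward by up to `corner_jitter_px`,
default 18 px ≈ 7% of the frame; retried up to 32 times if concave, then an
error) with optional brightness gain U(0.92, 1.08) and Gaussian blur
σ ≤ 0.5 px. Rectification estimates the 3×3 homography from the four corner
correspondences by the exact 8×8 direct linear solve (h₃₃ = 1); corner
residuals are at numerical precision, and user corner order is forgiven by
an angular sort around the centroid. Warping is inverse-mapped bilinear
interpolation with constant white fill. A quality check measures the mean
radial distance of detected ring pixels from the expected 3/5/7-mm radii
and signals recapture when rings are missing or misaligned — alignment of
these zones is precisely the failure mode the original workflow blames for
its symmetric/asymmetric confusions. HSV conversion is the standard hexcone
transform (hue in degrees, gray pixels hue 0), exactly invertible in 8 bit.

## Examiner-oracle contour and rule classifier

In clinical use the contour is drawn by hand on the touch screen; for
synthetic data an automatic oracle stands in so the pipeline is testable
without a human (a polyline-from-file entry path remains for real images).
For tie/cone classes the oracle extracts iso-power level sets (marching
squares) at `k₀ + 0.5 · max(A_sup, A_inf, ΔK_cone)` — half the peak
elevation, guaranteeing both semimeridians are traced at one color shade —
and raises a degenerate-pattern error if the peak is below one color step
(1.5 D). For the spherical class it draws the examiner's peripheral outline,
a circle at 95% of the 7-mm zone radius. Closed polylines with ≥ 8 vertices
and area ≥ 0.02 mm² are kept.

Shape features: lobes are the non-peripheral polylines (minor blobs below
8% of the largest lobe's area are ignored — noise wiggles or a rudimentary
remnant); lobe length is the maximal radial reach, width the extent
perpendicular to the lobe direction (centroid angle). The inter-meridian
angle is half the angle between the two lobe directions, so an intact tie
(opposed lobes) scores 90° and a skew of s degrees deviates by s/2. The
symmetry ratio is min/max of the paired lobe lengths.

Rule classifier (decision list, thresholds configurable):

1. no lobes / peripheral-only trace → SPHERICAL;
2. one lobe → IRREGULAR;
3. |inter-meridian angle − 90°| > 15° → IRREGULAR (skewed axes);
4. symmetry ratio < 0.35 → IRREGULAR (rudimentary half);
5. longest lobe ≤ 2.5 mm → IRREGULAR (small tie confined to the 5-mm zone);
6. symmetry ratio ≥ 0.75 → SYMMETRIC (a tie at the threshold breaks toward
   the less severe class);
7. otherwise → ASYMMETRIC.

On noiseless generator output this rule set recovers the generated label
exactly (tested at 200 seeds per class); with default noise it stays above
99%, the residual errors being asymmetric ties whose measured length ratio
drifts across the 0.75 boundary — the same confusion the clinical
evaluation reports as its dominant error. This anchors dataset label
quality independently of the CNN.

## Classifier

Nothing beyond "pairs of convolution and max-pooling layers" is specified
for the original network, so the default architecture is the smallest stack
that separates the synthetic classes: input 64×64×2 (filled contour mask +
hue plane, hue zeroed where achromatic; mask-only via `channels=1`),
conv 5×5×8 / 2×2 max-pool, conv 3×3×16 / 2×2 max-pool, dense 64, softmax 4.
Whether the original network saw the raw colors, the contour, or both is
not stated; including both planes is our choice, which also lets the
post-surgery confounders matter. Training: cross-entropy, mini-batch SGD
(batch 64, learning rate 10⁻², momentum 0.9), 100 epochs ("training
seasons"), He-normal initialization. The implementation is plain numpy
(im2col convolution; exact argmax pooling so the backward pass is
deterministic; the first layer's input gradient is skipped as unused), all
float32, fully seeded: the same seed reproduces initial weights, shuffling,
the epoch curve and the confusion matrix bit-for-bit on one thread.
Optional augmentation applies only small rotations (±10°) and brightness
jitter — never vertical flips, because superior/inferior identity is
diagnostic (keratoconus steepening is "usually inferior"). Augmentation is
off by default; the synthetic classes separate without it.

On the full synthetic bank (960/212) the default network reaches ~80%
held-out accuracy after the first epoch and plateaus near 98–99%, giving a
mean per-epoch held-out accuracy around 98% — comfortably above the ~90%
average the original training curve reports, as expected for a cleaner
synthetic bank.

## Evaluation

Confusion matrices use the fixed class order (SPHERICAL, SYMMETRIC,
ASYMMETRIC, IRREGULAR), rows = truth. Percentages are rounded half-up to
two decimals to match the printed style of clinical reports. Screening
metrics take IRREGULAR as positive: sensitivity = row diagonal / row total,
specificity = non-positive samples not called positive / non-positive
total. The built-in `published_test_matrix()` fixture reconstructs the
published 212-image test matrix from its row totals and per-class error
narratives; its printed spherical-row percentages (97.15/2.85) are
arithmetically inconsistent with 34/35 = 97.14/2.86, which we treat as a
typo in the source and do not special-case.

## Problem sizes and determinism

The acceptance computation uses the full study conditions: a 1,172-image
bank at 256×256, contour extraction on a 128×128 power-map grid (ample for
polylines rasterized at 64×64), and three 100-epoch trainings — about ten
minutes on one CPU core. Unit tests use smaller banks (3–30 images per
class, 128×128 renders) chosen to exercise the same code paths in seconds.
End-to-end reports embed the config and its hash; two runs with the same
config hash are byte-identical.

## What the synthetic bank does and does not show

The generator reproduces the geometry of the diagnostic taxonomy —
bow-tie symmetry/asymmetry, reach, skew, localized cones, post-surgery
central shifts — under a single known color scale, with smooth noise and a
perfectly consistent labeling rule. Real topograms differ in ways the bank
does not model: vendor-specific palettes and normalized scales, Placido-ring
artifacts and dropout, eyelash/lid shadows, off-axis fixation, printing and
lighting variation, and — most importantly — a human labeler whose
boundary cases are genuinely ambiguous ("unusual patterns" that confuse
training). Passing tests therefore demonstrate that the pipeline's
machinery is correct and that the CNN can learn the taxonomy's geometry;
they do not certify clinical performance on real images. Elevation maps,
ray-traced Placido simulation and patient demographics are out of scope.

## Numerical choices and degenerate inputs

* Homography: exact linear solve; collinear corner triples raise a
  degenerate-geometry error rather than returning a least-squares fit.
* Warp: bilinear, constant fill, uint8 rounding at the end only.
* Contour level sets: marching squares on the raw grid; open contours
  (touching the boundary) are discarded.
* Rule thresholds sit midway between class clusters (0.75 symmetry, 0.35
  rudimentary floor, ±15° perpendicularity, 2.5 mm reach) so that default
  noise rarely crosses them.
* Softmax is computed with the max-subtraction trick; prediction ties break
  to the lowest class index (documented, tested).
* Spherical surfaces asked for a tie-level contour, amplitudes below one
  color step, empty level sets, non-convex capture quads, out-of-disc
  coordinates and manifests with missing columns all raise typed errors.
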