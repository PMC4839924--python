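# Methods

## Signal model and quantification

A FAIR acquisition alternates a slice-selective and a global inversion;
at the effective inversion time TI their difference ΔM = selective −
global is perfusion-weighted. We use the standard single-TI,
single-compartment quantification

    f = 60 · λ · ΔM · exp(TI / T1_blood) / (2 · M0 · TI)   [mL/min/100 g]

with the blood–tissue water partition coefficient λ = 80 mL/100 g and
T1_blood = 1.2 s (1.5 T literature values); both are configurable
(`QuantificationParams`), as the exact constants used by any given
scanner package vary. Protocol defaults follow a renal FAIR True-FISP
protocol: TI = 1200 ms, in-plane 2.3 × 1.2 mm, slice 8 mm. Pixels below
5% of max(M0) are flagged invalid rather than divided by; negative
values produced by noise are retained (clipping would bias ROI means).
Assumptions: complete inversion, negligible transit-time differences
within the slice, no T1 mapping — all standard for this protocol class
and out of scope here.

The phantom synthesizes ΔM by inverting the same formula, so end-to-end
recovery tests are independent of the particular constants chosen.

## Synthetic phantom

The phantom is a 2-D kidney-like object at a 96 × 96 grid: an outer
cortical rim, a medullary band and a bright central calyceal region,
built from concentric scaled copies of a bean-like outline (an ellipse
with semi-axes 20 × 30 px carrying a smooth hilar notch, depth 0.15,
half-width 0.5 rad). The notch matters: a pure centered ellipse is
almost rotationally unobservable from a contour-to-edge cost, which
would make pose recovery ill-posed in a way real (bean-shaped) kidneys
are not. All compartment boundaries share the angular profile, so the
cortex:medulla area ratio is exact by construction; its default 0.93
makes the area-weighted mean of the default compartment truths (cortex
337.10, medulla 279.61 mL/min/100 g) equal the whole-kidney 307.26.
The calyx occupies 18% of the kidney area and has zero perfusion
(urine). M0-relative gray levels are background 0.10, medulla 0.55,
cortex 0.75, calyx 0.95 at an M0 plateau of 1000 signal units; global
images are attenuated by 0.6 (inversion recovery).

Each pair is rendered *analytically* at its jittered pose (every pixel
classified through the pulled-back coordinates) rather than by warping a
reference image, the way a scanner samples a kidney that actually moved;
the generator itself therefore introduces no interpolation blur.
Breathing jitter draws translations uniform in ±2 px per axis and
rotations in ±2°; a corrupted pair replaces the translation by one of
magnitude 3–4× the jitter bound in a random direction — the
irrecoverable-shift failure mode QC must catch. Noise is additive
Gaussian, 2% of the M0 plateau per image; at these settings the
per-pixel SNR of a single-pair perfusion map is near 1, which is
realistic for single-average renal ASL. Gaussian (not Rician) noise is
adequate at this SNR of the *raw* images. Fixed seeds make every output
bit-reproducible.

What the phantom does not emulate: multi-slice geometry, medullary
heterogeneity (pyramids vs interlobar vessels), partial-volume
anisotropy of the true 2.3 × 1.2 mm grid, T2*/banding artifacts, or
respiratory drift within an acquisition. Passing tests therefore show
the analysis chain is correct and well-conditioned under idealized
contrast, not that it segments pathological kidneys.

## Live-wire delineation

Link costs follow the classic intelligent-scissors form
l(p,q) = 0.43·f_Z(q) + 0.43·f_D(p,q) + 0.14·f_G(q) on an 8-connected
grid: f_Z is 0 on Laplacian zero-crossing pixels, f_G = 1 − |∇I|/max|∇I|
(diagonal links scaled by 1/√2), and f_D is the gradient-direction
smoothness term; the image is pre-smoothed with a σ = 1 Gaussian. Of the
two pixels straddling a zero crossing we consistently mark the
negative-Laplacian side — the interior of a bright object — so a traced
kidney keeps its outermost pixel ring. Paths are found with Dijkstra's
algorithm using (cost, row, col) heap keys: ties break lexicographically
and results are platform-independent. Seeds come from a JSON file (or
`default_seed_points` on the phantom); no GUI is provided, interactivity
being out of scope. Closure validates 8-adjacency and simplicity
(shapely); rasterization uses an even–odd polygon fill plus the contour
pixels themselves.

## Stiff affine registration and QC

The drawn contour is propagated to each pair's global image by
minimizing the mean target edge cost f_G (σ = 2 Gaussian) sampled along
the transformed contour, plus a quadratic identity penalty on the
normalized parameters (tx/10 px, ty/10 px, rot/10°, scale−1, shear) with
diagonal weights (1, 1, 0.5, 25, 25, 50) at stiffness 0.05. The heavy
weights on scale and shear encode the physics — breath-hold kidney
motion is nearly rigid — and prevent a known gauge pathology where a
wrong-sign rotation plus a small shear fits image noise as well as the
true pose. Numerics, all deterministic: the contour template is first
snapped, point by point, to the reference image's gradient ridge along
the outward normal (the ridge sits a subpixel, orientation-dependent
distance outside the traced pixel ring; without snapping the fit
acquires a spurious ~2% dilation); a coarse σ = 2 stage runs Nelder–Mead
from identity plus four translation- and two rotation-shifted starts;
the fine σ = 1 stage restarts from the coarse optimum with the rotation
reset to each value of an 11-point grid (rotation is the weakly
identified direction). Translation is bounded in Euclidean norm (5 px
default) so that a corrupted pair's ≥6 px shift is unreachable in every
direction; rotation ±5°, scales 0.9–1.1, shear ±0.1.

`residual_error` is the pure edge-cost term at the optimum. A pair is
rejected iff its residual exceeds `rejection_factor` (default 2.0) times
the median residual of the series — the threshold is relative because
absolute edge costs depend on contrast. A single pair is its own median
and always passes. On phantoms, self-registration recovers the exact
identity and 96% of random jitter warps are recovered to a mean contour
point error below 1 px; corrupted pairs are rejected with a ~2× residual
margin.

## Compartment separation

Clustering runs on the average of the registered (inverse-warped,
cubic-interpolated) global-inversion images, which show the best
gray-level separation of calyces/medulla/cortex/background. Features
per pixel inside the 2-px-dilated kidney contour: (α · min-max
normalized gray, distance to the kidney's center of gravity normalized
by its maximum), with α = 1 and distance weight 1 by default; k-means
with k = 4, a fixed seed and 10 initializations. Clusters map to labels
geometrically — darkest = background-within-contour, most central of
the rest = calyx, most peripheral of the remaining two = cortex — which
is contrast-polarity independent; an explicit `label_map` can override
it. Labels outside the contour are cleared.

The morphological cortex filter demotes every cortex pixel whose
8-neighborhood contains a non-cortex label, in one simultaneous pass.
The surviving cortex is a strict subset guaranteed to contain cortex
only ("slightly under-segmented"). Demoted pixels are excluded from all
ROIs by default: they are precisely the pixels whose compartment is
uncertain, and folding them into the medulla would import cortical
signal into the medullary mean (≈ +3% on the phantom). A
`demote_to="neighbor"` option relabels them to the adjacent compartment
instead. Consistently, the final summary takes the cortical mean over
the purified cortex but the medullary and whole-parenchyma means over
the raw clustering; "whole kidney" is parenchyma = cortex ∪ medulla,
excluding calyces.

## Pair selection and summary

Perfusion is quantified per pair in its native frame (the pair's ΔM is
divided by the M0 image carried into that frame with the recovered
transform, cubic interpolation), and the map is resampled back with
linear interpolation; quantifying after resampling the pair into the
reference frame is available as a config switch but measurably inflates
the medullary boundary. Among QC-passing pairs, the 4 with the highest
mean perfusion over the kidney mask are averaged (ties to the lower
index; fewer than 4 good pairs are all used, with a warning). Note the
top-4 rule is intrinsically upward-biased when all pairs are
statistically equivalent — on the phantom it contributes roughly +1–2%
to compartment means — and is retained because it is part of the method
being reproduced.

## Reproducibility statistics

Tables are long-format (subject, session, repetition, value). The
within-subject CV is 100·SD/mean per subject over its repetitions
(sample SD throughout), summarized as mean ± SD across subjects. The
ICC is the two-way random-effects, absolute-agreement form from the
ANOVA mean squares; the average-measures form ICC(2,k) is the headline
number because it is the only form numerically consistent with jointly
reporting ICC ≈ 0.97 and a repetition CV of ≈ 3–4% (the single-measures
value implied by those dispersions is ≈ 0.86); both forms are reported,
and they satisfy the Spearman–Brown identity to machine precision.
Bland–Altman limits are mean difference ± 1.96 SD of differences of the
per-subject session means; the paired t-test is two-sided and returns
NaN (flagged, not raised) for identically-zero differences. The total
ICC/CV treat the 6 repetitions as exchangeable, ignoring session
nesting, and the report states per-session values alongside. Balanced
designs are required; violations name the offending subject.

## Problem sizes and determinism

Default analyses use a 96 × 96 phantom with 8 pairs (a full pipeline run
takes a few seconds on one core); cohort simulations use 14 subjects × 6
measurements with 200 Monte-Carlo replicates. All randomness flows
through explicit integer seeds (phantom, cohort, k-means), and identical
inputs give bit-identical outputs.

## Known limitations

- 2-D single-slice only; the right-kidney, single-slice design is baked
  into the geometry defaults.
- The registration objective is contour-based; gross intensity artifacts
  that leave the kidney edge intact would pass QC.
- The medullary mean inherits small positive biases from top-4 selection
  and residual misregistration at compartment boundaries (≈ +2–5% on the
  default phantom); the cortical mean is protected by purification.
- The k = 4 geometric label mapping assumes one connected kidney with a
  central calyceal cluster; duplex or severely hydronephrotic kidneys
  would need an explicit label map.
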