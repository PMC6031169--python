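# Methods

## Scope and assumptions

The package recognizes four coarse whole-body postures
(standing/walking, sitting, stooping, lying) from synchronized 8-bit
depth image streams. The model is frame-wise: no temporal features,
no tracking, one subject per scene. Cameras are uncalibrated and may
sit at arbitrary azimuths; the fusion step is deliberately
calibration-free (per-layer products and a max), which is what makes
the feature vector independent of the camera count. Streams are
assumed pre-synchronized at capture, so multiview pairing is by
ordinal frame index; no timestamp alignment is attempted.

The depth dialect is fixed: single-channel 8-bit, 0 = near, 255 =
far. Other bit depths are rejected rather than rescaled, because a
silent rescale would corrupt the depth→cm regression that the layer
depth features depend on.

## Subject extraction

The background model is a per-pixel **lower median** over the leading
background-only frames (default 40) with a median-absolute-deviation
spread. The lower median (element `(B−1)//2` of the sorted stack)
fixes the tie between the two central order statistics of an even
stack, keeping the model fully deterministic. Foreground is
`|depth − reference| > max(τ, c·spread)` with τ = 15 codes and
c = 2.5; the spread term absorbs sensor flicker in noisy background
regions. The extractor sits behind a pluggable interface so an
adaptive mixture-of-Gaussians model or an externally supplied
per-frame mask (datasets segmented by color keying, for instance) can
replace it without touching the rest of the chain.

Denoising is a morphological opening-then-closing with a
`(2r+1)`-square element (default r = 1); borders are treated as
background (`mode="min"`), matching the convention of
`scipy.ndimage`'s binary morphology. The subject is the largest
8-connected component; equal-area ties resolve to the component whose
first pixel comes earliest in scan order (topmost, then leftmost).

Arm rejection — excluding thin protruding limbs so only the torso
profile feeds the layer features — is realized as an opening of the
blob mask with a square element of side `max(1, round(s·H_h))`,
s = 0.05 by default. The operation never enlarges the mask, re-tightens
the bounding box afterwards, and can be disabled with `s = 0`. A blob
thinner than the element everywhere is treated as "no subject" and
the frame is skipped. This is a pragmatic, tunable realization of limb
exclusion; nothing deeper is claimed for it.

Whether to locate the box on the raw or the denoised mask was an open
choice; the denoised mask is used, since speckle would otherwise
inflate the box by stray pixels.

## Layer features

Layer bounds use integer floor arithmetic,
`y_T[k] = ⌊H(k+N)/(2N+1)⌋+1`, `y_B[k] = ⌊H(k+N+1)/(2N+1)⌋` (1-based
inclusive rows). This provably partitions rows 1..H — contiguous,
disjoint, covering — for every `H ≥ 2N+1`; the test suite checks this
exhaustively up to H = 500, N = 9. Internally all image coordinates
are 0-based half-open; the 1-based convention exists only at this
boundary.

The depth→cm conversion is a degree-6 regression polynomial evaluated
by Horner's rule in double precision. It is applied exactly as
fitted, without clamping, although it is not monotone over the full
0–255 code range (it dips around mid-range and rises again); its
values over the valid range stay positive, which is all the
downstream normalization needs. Inputs outside [0, 255] raise.

`D′[k]` is the **mean foreground depth code** of the layer converted
to cm — i.e. the layer's depth sum divided by the raw pixel count
`ρ′[k]`, not by the normalized density, since only the former yields
an 8-bit code the regression can accept. Empty layers contribute
`D′ = 0` rather than NaN so normalization and fusion stay defined;
max-normalization of an all-zero profile returns zeros rather than
erroring. Note one consequence: in the inverse depth
`D_i = (D − max D)/(min D − max D)`, an empty layer (D = 0 = min)
maps to 1. A flat profile (max = min) maps to all zeros — no layer
stands out as nearer.

`Z[k] = (1−α)Q[k] + αρ[k]` with `Q = D_i·ρ`. Under this formula
α = 0.9 puts 90 % of the weight on the plain density ρ. Usage in the
field also describes the opposite reading (α as the weight on Q);
both are supported through `alpha_convention: printed | prose`, with
`printed` as the default, so either convention can be reproduced
explicitly instead of guessing. Defaults L = 3 (N = 1) and α = 0.9
follow the reported optima of the layer-size and α sweeps on real
multiview recordings.

## Fusion

`ω[k] = Π_v ρ_v[k]`, `ω̄[k] = Π_v Z_v[k]`, `P_m = max_v P_v`. The
per-layer factors are multiplied in sorted order, making the products
*exactly* invariant to view order (naive left-to-right float
multiplication is not, for three or more views). A view with no
detected subject at a time step is dropped from the product for that
step — d shrinks — rather than contributing zeros that would
annihilate every layer; each drop is logged. Zero-annihilation versus
dropping was an open design point; dropping is the deliberate choice
here because a missed detection carries no evidence about the
posture.

## Classification and evaluation

The ANN is a single hidden layer of 20 units trained with the
full-batch lbfgs solver — deterministic under a fixed seed and
reliable at the corpus sizes involved; the SVM is an RBF-kernel C-SVC
with the library's standard `C = 1, γ = scale` heuristics, since no
specific values are prescribed. Features enter exactly as fused:
layer entries are already in [0, 1]; `P_m` is passed through
unscaled, its larger scale being itself informative for lying.

Evaluation reports the 4×4 confusion matrix (rows = true) and
per-class precision `TP/(TP+FP)` in percent with the macro average. A
class receiving no predictions has undefined precision; it is
reported as 0 and explicitly flagged, keeping the macro average
defined. When only a single corpus exists, the protocol is a
stratified 70/30 hold-out split at the *sequence* level (whole
recordings never straddle the split, preventing leakage between
near-identical frames); rows are put into canonical order before
splitting so the protocol is invariant to input row order. Explicit
train/test manifests support the two-scenario design where a model is
trained in one room setup and tested in another.

## Synthetic scene generator

The generator emulates the assumed capture geometry — cameras at 2 m
height tilted 30° below horizontal, subject at 3–5.5 m, ≥ 40 leading
background frames, 8-bit depth with the background plane at code 240 —
without true 3-D rendering: the feature model consumes only binary
silhouettes and 8-bit depths, so each action is composed directly in
image space from axis-aligned body segments whose projected widths
and depth offsets depend on the actor's orientation relative to each
camera. Distance maps to depth code linearly over 200–620 cm; the
camera tilt appears as a top-to-bottom distance ramp along the body.

Class geometry: standing/walking is a tall column with near-uniform
per-layer area; sitting widens the lower half when seen side-on but
front-on keeps nearly the standing column's height, with the thigh
showing only as a nearer-depth band — deliberately reproducing the
real ambiguity of front-view sitting; stooping concentrates mass in
the upper layers with a strong depth gradient along the bent torso;
lying is a horizontal silhouette at floor level with width/height
≥ 1.5. A per-frame `Posture` draw (tilt spread 15–45 cm, seated-height
jitter ±0.06, thigh prominence 0.1–1.2, widening jitter ±0.15, stoop
lean 30–60 cm) provides the within-class variability that keeps the
classes from being trivially separable — a tucked-leg sitter seen
front-on genuinely overlaps a short stander, and only the second view
resolves it.

Per-sample draws: stature 155–190 cm, shoulder width 38–50 cm, torso
depth 20–30 cm, orientation from {0°, 45°, 90°, 135°, 180°}, base
distance uniform in the operating range with ±30 cm per-view offsets.
Noise is a per-pixel mask flip (default rate 0.005, capped at 0.05)
plus Gaussian depth jitter (default σ = 1 code). All randomness flows
from one seeded generator recorded in the corpus manifest, so
regeneration from a manifest is byte-identical. The default corpus
uses one action frame per sequence: the model is frame-wise, so one
frame per actor placement maximizes placement diversity per unit of
compute, and the hold-out split is at sequence level either way.

What the generator does **not** emulate: articulated kinematics,
self-occlusion beyond the coarse front-view effects above, shadows,
multi-person scenes, sensor-specific artifacts (holes,
quantization banding), or photorealistic shape. Passing tests
therefore demonstrate that the feature model and fusion recover the
geometric contrasts the classes are defined by — not performance on
any real recording.

## Numerical choices and degenerate inputs

* Lower-median tie rule in the background model; deterministic.
* All-zero feature profiles normalize to zero vectors.
* Empty mask / vanished blob raises a "no subject" signal; the frame
  is skipped and logged, and a view missing at a time step is dropped
  from fusion.
* Fusion factors multiplied in sorted order (exact permutation
  invariance); products of ≤ a handful of views, so no log-domain
  accumulation is needed.
* The open-close denoise filter is *not* idempotent on adversarial
  dense speckle (a known property of alternating morphological
  filters); on silhouette-plus-speckle masks, the inputs it actually
  sees, a second pass is a no-op and the tests assert exactly that.
* Even layer counts, α outside [0, 1], depth codes outside [0, 255]
  and mixed-length feature vectors are rejected with explicit errors.

## Problem sizes used by the test suite

The exhaustive layer-partition check covers H ≤ 500, N ≤ 9. Oracle
equivalence runs 1000 random blobs (heights 9–80, widths 5–50).
End-to-end parameter recovery uses the default corpus of 4 × 200
two-view sequences at 160×120 px, with the identical-geometry
ablation (every class rendered as the standing column) as the
chance-level control; smaller corpora back the remaining integration
tests.

## Known limitations

Frame-wise classification cannot use motion cues, so standing vs
walking is a single class by construction. The arm-rejection step is
a stand-in realization, not a validated limb segmenter. The
depth→cm regression is sensor-specific; other sensors need their own
fit. Real-data performance claims are out of scope here: the
acceptance surface is analytic and property-based plus synthetic
parameter recovery.
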