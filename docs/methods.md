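# Methods

This note documents the model, the numerical and design choices behind
`polypdet`, and what the synthetic-data experiments do and do not show.

## Architecture

The detector is a single-stage, anchor-based network: a CSP-Darknet-style
backbone (stem, strided CBL convolutions, C3 cross-stage blocks at strides
4/8/16/32, SPPF), an optional context-feature-augmentation block (CFA) on
the deepest map, a PAN neck (top-down nearest-neighbour ×2 upsampling with
lateral concatenation, then bottom-up strided convolutions), optional
coordinate attention, and three 1×1 heads emitting `3·(5+nc)` channels at
strides 8/16/32. Channel widths are the base plan (64…1024) times
`width_multiple`; stage depths are (3, 6, 9, 3) times `depth_multiple`,
rounded with a floor of 1. All of this is implemented on a small
reverse-mode autodiff engine (`polypdet.nn`) over NumPy `float32` arrays;
convolutions are evaluated as sums over kernel taps of BLAS `tensordot`
calls, so peak memory stays proportional to the activations.

Fixed conventions (each has a config switch where noted):

- **CBL** = convolution (no bias) + per-channel batch normalisation
  (momentum 0.03, ε 1e-3) + SiLU. The activation is switchable
  (ReLU/leaky/hard-swish) but SiLU is the default used throughout.
- **Stem**: pixel-parity Focus slice (order: even-even, odd-even, even-odd,
  odd-odd, row parity first) followed by a 3×3 CBL; a strided 6×6
  convolution variant with identical parameter count is selectable.
- **P-BottleNeck wiring**: path A = 1×1 CBL → 3×3 CBL; path B = 1×1 CBL;
  identity shortcut; the three are combined by element-wise addition
  (concatenation selectable), then a final 3×3 CBL, then the selectable
  residual add. Under addition-combine the block has exactly twice the
  parameters of the plain bottleneck (20h²+8h vs 10h²+4h at hidden width h).
- **Coordinate attention**: the nonlinearity after the shared 1×1 transform
  is hard-swish by default; a strict switch uses a sigmoid there (the gates
  already apply a sigmoid, so the strict variant compresses gate range —
  kept selectable, not default).
- **Heads**: layout `(x, y, w, h, obj, cls…)`, sigmoid-decoded as
  `xy = (2σ−0.5+cell)·stride`, `wh = (2σ)²·anchor`. Head weights are
  initialised at 1% scale so the initial decode equals the anchor prior at
  each cell centre, and objectness biases start at the prior of ~8 objects
  per image; with data-fitted anchors this makes early training a
  refinement rather than a search.

## Parameter-count calibration

The four ablation configurations (baseline / +CFA / +CFA+CAM / full) are
calibrated against published totals for this architecture family. The
calibrated knob settings, found by exhaustive search over the documented
switches, are: width 0.5, depth 0.33 with stage depths (1, 2, 3, 1), one
class; CFA with CBL dilated convolutions, *bare* (no norm, no bias) 1×1
reduce convolutions of width 82 and a bare 1×1 fusion; coordinate attention
with reduction r=16 (compressed width floor 8, conv biases and shared-path
norm on) inserted after CFA and on the four PAN concatenation outputs
(channel widths 512, 512, 256, 256, 512); P-C3 replacing the four backbone
C3 stages. The resulting counts, against the published totals:

| group | configuration | count | published | residual |
|---|---|---|---|---|
| 1 | baseline | 7,022,326 | 7,055,192 | −32,866 (−0.47%) |
| 2 | +CFA | 21,520,118 | 21,520,118 | 0 |
| 3 | +CFA+CAM | 21,696,630 | 21,697,294 | −664 (−0.003%) |
| 4 | +CFA+CAM+P-C3 | 22,938,870 | 22,933,134 | +5,736 (+0.025%) |

Group 2 is exact, and the three *module deltas* (CFA +14,497,792; CAM
+176,512; P-C3 +1,242,240) all land within 0.5% of the published deltas —
the only persistent gap is the baseline absolute. That gap is not closable:
every configuration expressible with the documented switches has a total
≡ 2 (mod 4) — the single-class head biases contribute 3·18 = 54 ≡ 2, and
every other knob moves the count in multiples of 4 — while the published
baseline is ≡ 0 (mod 4). The same parity argument rules out hitting groups
1 and 2 simultaneously, since their published difference is itself
≡ 2 (mod 4). We therefore fix the configuration that makes group 2 exact
and minimises the remaining residuals, and report counts and residuals
as above. Two consequences of the calibration are worth noting as
deviations from the otherwise-natural defaults: the CFA reduce width is 82
rather than channels/4 (the default for non-calibrated widths), and the
calibrated configuration converts only the backbone C3 blocks to P-C3 — a
neck switch exists, but converting the neck too overshoots group 4 by
about 1.03 M parameters under every documented wiring.

## Loss and assignment

`Loss = L_cls + L_box + L_obj`. `L_box = λ_coord · mean(1 − CIoU)` over
assigned pairs with λ_coord = 0.25; `L_cls` and `L_obj` are binary
cross-entropies on sigmoid outputs, with per-scale objectness balance
(4.0, 1.0, 0.4) and cls weight 0.5. The objectness regression target of an
assigned pair is its CIoU clamped to [0,1] (treated as a constant for the
gradient), with a plain 0/1 switch. Assignment is the deterministic
shape-ratio rule: every anchor with
`max(w_g/w_a, w_a/w_g, h_g/h_a, h_a/h_g) < 4` claims the ground truth in
its own cell plus the two nearest neighbour cells; a ground truth that no
anchor claims falls back to its best-ratio anchor, so no target is
orphaned. Degenerate aspect ratios use `atan(x/0) := π/2`. The α·v term is
zero whenever v = 0. During optimisation the scalar loss is multiplied by
the batch size (the per-scale terms are means, so this keeps the gradient
per sample independent of batching).

λ_coord deserves a note: a conventional small value (0.05) systematically
under-weights box regression on the short CPU schedules this package runs —
small polyps end up confidently detected but with boxes stuck just below
the 0.5 match IoU. At 0.25 the regression tightens without destabilising
the other terms, so 0.25 is the default (it remains a config knob).

One caveat found while validating
gradients numerically: finite-difference checks of the full network are
only meaningful at input sizes whose deepest grid is larger than ~2×2 —
batch normalisation over degenerate 1×1 maps makes the loss surface so
curved that central differences at ε ≈ 1e-3 no longer approximate the
derivative. All analytic gradients check out at regular sizes.

## Training loop

SGD with momentum 0.9 from lr 0.01, batch size 16, 200 epochs — the
reference protocol; smoke-scale runs use the same optimiser with fewer
epochs and smaller batches. Cosine decay to 1% of lr0 after a 3-epoch
linear warmup. Weight decay 5e-4 on convolution weights only. Batches are
a fixed seeded partition of the (letterboxed) training set, and the target
assignment for each batch is computed once up front — augmentation is
offline (Mosaic pre-expansion doubles the set when enabled), so targets do
not change between epochs. Gradients are clipped to a global norm of 10.

Batch normalisation gets special treatment at the small batch sizes used
here: at 80% of the schedule the running statistics are recalibrated to
exact training-set moments (one momentum-1 pass) and frozen, and the rest
of training proceeds against that fixed normalisation. Without this,
inference-time statistics can diverge from the batch statistics the
weights were trained under, which measurably costs recall; without the
gradient clipping, training against frozen normalisation can overflow
float32. Both are config switches (`bn_freeze_fraction`, `clip_grad_norm`).

## Synthetic scenes

The generator renders mucosa-like backgrounds (reddish base hue,
low-frequency mottling, radial vignette, curved fold streaks, Gaussian
sensor noise) and 1–4 polyps per image as rotated ellipses with
Gaussian-feathered borders, a luminance offset proportional to the
`contrast` parameter, and optional specular glints. Ground-truth boxes are
the tight bounding boxes of the rendered support, so labels are exact.
Per-image polyp counts are uniform on 1..4 (mean 2.5). Difficulty presets
mirror the hard clinical regimes: `low_contrast` (contrast 0.10), `tiny`
(major axes 8–16 px at a 640 frame), `multi` (4 polyps). What passing the
synthetic suite shows is that the architecture, loss, assignment, decoding
and bookkeeping are implemented correctly and that the model class can fit
such scenes; it says nothing about accuracy on real endoscopy video, which
differs in texture statistics, motion blur, instrument artefacts and the
sheer variety of polyp morphology.

## Problem sizes used by the checks

The end-to-end check synthesises 20 scenes at 160 px (sizes 8–40 px),
fits anchors by kmeans++ on the training boxes, trains the full model
(CFA+CAM+P-C3) at `width_multiple` 0.25 for 150 epochs with batch size 8,
and evaluates pooled precision/recall/F on the training split at
confidence 0.25, NMS IoU 0.45, match IoU 0.5 — an overfitting contract
chosen to exercise every stage on one CPU in a few minutes. Parameter
calibration builds all four full-scale (width 0.5) configurations, which
takes seconds. Oracle checks (pooling equivalence on 100 random maps,
NMS against an O(n²) reference on ≤50-box sets, CIoU hand geometry,
directional-pool conservation) are instantaneous.

## Known limitations

- CPU-only and NumPy-based: throughput is orders of magnitude below a GPU
  framework; full-scale (width 0.5, 640 px) training is out of reach here,
  which is why quantitative claims are confined to parameter accounting,
  oracle equivalences and small-scale overfitting.
- The evaluation matching threshold (IoU 0.5), confidence 0.25 and NMS IoU
  0.45 are conventional defaults; published operating points for this
  architecture family do not state them, so absolute precision/recall are
  not directly comparable.
- Mosaic is applied as offline dataset expansion; an online per-batch mode
  would decorrelate epochs but requires re-assigning targets per epoch.
- The synthetic generator does not model depth, motion blur, fluid or
  instrument occlusion.
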