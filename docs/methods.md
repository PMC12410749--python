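# Methods

## Problem setting

Fine-grained multiclass nuclei segmentation from a structure stain, trained
from weak and noisy annotations. The package implements the full workflow at
desk scale: synthetic paired stain/marker patches stand in for registered
PAS + immunofluorescence data, a classical promptable segmenter stands in
for a vision foundation model at annotation time, and a small numpy
encoder–decoder stands in for a large pre-trained backbone at training time.
The corrective-learning loss, the adapter contract and the evaluation suite
are implemented in full; the scale of data and model is the only reduction.

## Synthetic data generator

`allinsam.synthdata` emulates 2-class glomerular patches:

- **Structure channel** — bright background (0.85) with multiplicative
  low-frequency texture (Gaussian-filtered noise, ±15%), nuclei as dark
  ellipses. Class 1 nuclei are larger (major radius 6–9 px) and darker
  (darkness 0.75–0.95); class 2 smaller (4–6.5 px) and paler (0.45–0.65).
  The class-dependent morphology is deliberate: marker channels exist only
  at annotation time, so the structure channel must carry the class signal a
  trained model can use — as it does for real podocytes vs. mesangial cells.
- **Distractors** — small dark non-nucleus objects (radius 1.2–3.5 px,
  darkness 0.4–0.6; by default half the nucleus count) drawn on the
  structure channel only. They emulate debris and injured-tissue artifacts
  and give annotator false positives something nucleus-like to attach to.
- **Marker channels** — one per class, equal to the nucleus intensity inside
  that class's nuclei and 0 elsewhere, plus clipped Gaussian noise
  (sd 0.05 by default; exactly zero when noise is off, so registration is an
  exact set equality the tests assert).
- **Ground truth** — instance labels with z-order overlap resolution (later
  nucleus wins) and per-class binary masks.

**Annotation noise** (`NoiseConfig`, applied per instance with a seeded
generator): false negatives (instance dropped, probability `fn_rate`), class
swaps (`class_swap_rate`), boundary erosion/dilation up to `boundary_jitter`
px, and false-positive blobs (3–6 px discs) covering `fp_rate` of the
background per class. When the image is available, blob centres are drawn
proportionally to darkness⁴, so false positives cluster on distractors —
lay errors are perceptual, not uniform over empty background. The default
study conditions are `fn_rate=0.2`, `class_swap_rate=0.2`, `fp_rate=0.01`,
`boundary_jitter=0`.

What the generator does *not* emulate: histological texture realism,
staining variability across slides, cross-modal misregistration, touching
nuclei chains, or out-of-focus artifacts. Passing tests therefore
demonstrate the mechanics and the direction of the method's effects, not
clinical-grade performance.

## Box-to-mask conversion

`fallback_box_segment` inverts the structure channel inside the box,
Otsu-thresholds, closes with a radius-1 disk and keeps the connected
component nearest the box centre; degenerate boxes fall back to the
inscribed ellipse. It is deterministic and needs no weights. The
`PromptableSegmenter` protocol (segment(image, box) → mask) is the seam
where a real promptable model would attach. Cross-class overlaps between
converted masks go to the smaller mask (a nucleus inside a larger spurious
box keeps its own label), ties to the lower class index.

## Backbone and adapters

A 3-level encoder–decoder (~11k parameters at the default width 8; widths
double per level) in NHWC numpy with hand-written backpropagation, taking
the structure channel only:

- encoder convs 3×3 with ReLU and 2×2 average pooling; decoder with nearest
  upsampling, skip concatenation, 1×1 channel mixing and 3×3 convs;
- a softmax head over background + n classes (probabilities sum to 1 per
  pixel; pad-and-crop handles sizes not divisible by 4);
- the penultimate decoder activation, L2-normalized per pixel, is exported
  as the embedding map E (cosine similarity is norm-free, and normalization
  stabilizes prototype selection); it is exported detached;
- after every encoder stage a residual bottleneck adapter
  h + Up(ReLU(Down(h) + Proj(t))) receives the texture prompt t — the
  standardized high-pass residual of the stain channel (channel minus its
  Gaussian blur, σ = 2 px). Up-projections are zero-initialized so an
  untrained adapter is the identity.
- `adapter_mode="adapter"` trains only adapters and head; the trunk is
  excluded from the optimizer and its SHA-256 parameter hash is verifiable
  before and after training. `adapter_mode="full"` trains everything (the
  default here, since the desk-scale trunk has no pre-trained weights worth
  preserving; the contract is what matters).

Training uses Adam (lr 5e-3 default), mini-batches of 4, per-epoch seeded
shuffling, and per-class binary losses averaged over classes. Everything is
pure numpy and single-threaded deterministic: identical config + seed gives
byte-identical results.

## Corrective loss

`allinsam.mocl` implements the five-stage corrective scheme literally:
confidence W is the foreground probability slice; the top-k annotated pixels
by confidence (ties broken in row-major order) form the prototype set;
cosine similarity against the prototypes is aggregated by mean (max
available); ω(W) = exp(W)·Y and ω(S) = S·Y; the combined weight
exp(W)·S — clipped below at 0 so negative similarities cannot create a
negative objective — scales a weighted soft-Dice plus pixel-weighted BCE.

Choices made where the scheme leaves room:

- **k** defaults to max(1, ⌈5% of annotated pixels⌉), configurable.
- **Weights are detached** — no gradient flows through W or E into the
  weights, the standard treatment for loss reweighting.
- **Background weight.** Taken literally, multiplying by Y zeroes the loss
  outside the annotation and destroys background supervision; the intent is
  highlighting, not exclusion. Pixels outside Y receive `background_weight`
  (default 1; 0 reproduces the literal masking).
- **Where weights enter.** A scalar loss times a pixel map is ill-typed for
  Dice; weights are pushed inside both terms (weighted Dice sums,
  pixel-weighted BCE mean), which preserves the down-weighting intent with a
  well-defined objective.

### Refinement staging

Corrective learning refines an already-trained predictor: confidence ranks
and embedding similarities are meaningless at initialization, and applying
the weights from epoch 0 suppresses exactly the hard true pixels the model
has not yet learned. With `loss="mocl"` the first `mocl_warmup` fraction of
epochs (default 0.8) trains with unit weights; the corrective weighting then
switches on at a reduced learning rate (`mocl_refine_lr_factor`, default
0.2), with weights recomputed once per epoch from a frozen forward pass so
the within-epoch objective is stationary. Per-step weight recomputation and
early activation were both destabilizing in ablations (they are available by
setting `mocl_warmup=0`).

## Metrics

Dice, IoU with the both-empty → 1.0 convention (logged); pixel ROC AUC
(undefined single-class truth → NaN with a warning); precision/recall at
threshold 0.5 and best F1 over all thresholds; instance F1 with greedy
one-to-one matching in descending IoU at threshold 0.5 (config-exposed;
greedy agrees with exhaustive assignment on the map sizes tested); and the
aggregated Jaccard index — each ground-truth instance matched to the
best-IoU unused prediction, accumulated intersection over accumulated union
with unmatched predictions added to the union. The ADJ column emitted in
CSV reports is this aggregated Jaccard index.

## Study conditions and problem sizes

The packaged experiments use 128×128 patches, 6+6 nuclei, 20 training / 10
validation / 10 test images, 30 epochs, and 5 seeds for the
corrective-vs-plain comparison; the conversion-quality check uses 20 patches
with tight and 5-px-jittered boxes. These sizes keep a full run in minutes
on one CPU while leaving each effect measurable.

## Known limitations

- The benefit of corrective weighting is directional and modest at this
  scale; the comparison asserts corrective ≥ plain on most seeds, not a
  margin. With a weak warm model the weighting can suppress genuine learning
  signal ("agreement" favours what is already learned).
- Boundary-jitter noise relocates the true boundary; confidence/similarity
  weighting cannot repair it (the weights act on annotated pixels, and the
  misplaced boundary is self-consistent). It is off in the default
  conditions and exposed in `NoiseConfig`.
- False negatives (dropped instances) are labeled background, where the
  corrective weights do not act; only the relative up-weighting of correctly
  annotated nuclei counteracts them.
- The fallback segmenter assumes dark-on-bright nuclei; a real promptable
  model should replace it for any other contrast.
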