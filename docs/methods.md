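# Methods

This note records the modelling and engineering decisions behind
`veinid`, in the order the data flows.

## Problem setting

Closed-set finger-vein identification: every finger is its own class,
several NIR images of it exist from one or two capture sessions, and a
probe image must be assigned to one of the known classes.  The metric
is the correct identification rate (CIR): the fraction of probes whose
top-1 softmax class matches the truth *and* whose softmax probability
exceeds 50 %.  Plain top-1 accuracy is logged alongside — the two
readings coincide once the model is confident, and reporting both
sidesteps any ambiguity about whether the threshold belongs to the
metric or to the deployment rule.

## Architecture

Input images are zero-padded to a square along their short axis
(content centered), bilinearly resized to 112×112, and the gray channel
is replicated to 3 channels.  Pixels stay in [0, 1]; no mean/variance
standardization is applied.

The network is three flows:

* input flow: 3×3 DBB → ReLU → coordinate attention → APS
  (112×112×3 → 56×56×16);
* middle flow: four diverse-branch residual blocks with widths
  16→32→64→128→256 and spatial sizes 56→28→14→7→4 (4×4×256 out);
* output flow: global average pooling → 256-d vector → dropout
  (rate 0.2) → bias-free cosine classifier on the L2-normalized
  embedding.

The width sequence doubles per block; it is the only doubling sequence
that connects the fixed endpoints (16 after the input flow, 256 at the
embedding) in four blocks, and it keeps channel growth — the dominant
parameter cost — modest.  The deployed backbone then counts 1,233,464
parameters and 185.5 M MACs at 112×112, matching the intended ≈1.23 M /
≈0.19 G budget.  The classifier head (n_classes × 256) is excluded from
the backbone figure because it varies with the class count; the
profiler reports both numbers.

Inside a DBRB the main path is DBB(3×3) → ReLU → DBB(3×3) → coordinate
attention → APS; the shortcut is a plain 1×1 convolution followed by
APS.  Two deliberate choices here:

* the shortcut APS *reuses the phase selected on the main path* instead
  of selecting independently — otherwise the two half-resolution grids
  could come from different parities and the residual addition would
  misalign spatially;
* the 1×1 shortcut is a plain convolution, not a degenerate one-branch
  DBB (a 1×1 DBB collapses to almost nothing and would only add
  bookkeeping).

ReLU follows the residual addition.  No extra batch norm follows a
DBB — every DBB branch is already BN-terminated, and a second
normalization would break the exactness of fusion.

The 7×7 map entering the last block's APS is zero-padded (bottom/right)
to 8×8 before decimation, giving the 4×4 output; bottom/right padding
preserves the top-left anchoring of the polyphase grid.

## Diverse branch block and exact fusion

Train-time branches (all BN-terminated, stride 1, "same" shape):
K×K conv; 1×1 conv; 1×1 conv → BN → K×K conv; 1×1 conv → BN → K×K
average pool.  The internal width of the sequential branches equals the
output width (no bottleneck).  BN uses ε = 1e-5 everywhere.

Fusion is a composition of four closed-form transforms
(`veinid.reparam`): BN folding into conv weights/bias, zero-padding
small kernels into a common K×K grid and summing parallel branches,
collapsing 1×1→K×K sequences by convolving the kernels, and expressing
average pooling as a fixed diagonal kernel.  Two details make the
result *exact* rather than approximate:

* a sequential branch applied with "same" padding must pad its
  **intermediate** map with the BN response to a zero input
  (β − μγ/√(v+ε)), not with zeros — the train-time forward implements
  exactly this padding, so train and deploy agree at the borders;
* fusion arithmetic runs in float64 and is cast to the working dtype at
  the end.

Fusion requires evaluation mode: the algebra is only valid for frozen
(running) BN statistics.  Measured equivalence: ≤1e-10 per block in
double precision, ≤1e-3 on whole-network logits in single precision
(the logits are cosines scaled by s = 64, which amplifies embedding
rounding).  At train time the average-pool branch runs as true pooling
(O(K²·C) per pixel), not as its fused diagonal-conv form (O(K²·C²));
both compute the same function.

## Adaptive polyphase sampling

Downsampling decimates after stride-1 operators: the four parity
sub-grids x[i::2, j::2] are candidate outputs and the one with the
largest norm is kept.  Choices: p = 2 (fused single-pass norm); norms
computed over all channels jointly, one phase per sample per layer
(a single coherent grid per map); ties broken by raster order
(0,0) < (0,1) < (1,0) < (1,1); odd extents zero-padded bottom/right.
Boundary handling of the surrounding convolutions is zero-padding, so
shift consistency is exact only for circular shifts — the property
tests therefore use circular shifts (even-shift equivariance is exact;
unit shifts preserve the output value multiset).  The gradient flows
through the selected component only (the selection is piecewise
constant, so this is the exact gradient almost everywhere).  A
max-pool-replacement form (2×2 stride-1 max pooling before selection)
is available in the functional API; the network itself uses plain
selection after its convolutions.

## Coordinate attention

Reduction r = 32 with a floor of 8 mid-channels; shared 1×1 encoder
with BN and hard-swish; per-axis 1×1 gate convolutions (no BN) with
sigmoid.  These are the customary settings of the attention design this
follows; the networks here have 16-256 channels, so the floor is
active everywhere except the widest blocks.  The internal 1×1
convolutions are not DBB-wrapped (nothing to gain at 1×1).

## Elastic angular-margin loss

Embeddings and classifier rows are L2-normalized; the target logit gets
an additive angular margin drawn per sample per step from N(m, σ²).
Defaults s = 64, m = 0.5 rad, σ = 0.05 rad — the customary settings of
the elastic-margin family.  cos(θ+E) is expanded as
cosθ·cosE − sinθ·sinE with sinθ = √(max(1−cos²θ, 0) + 1e-12), avoiding
arccos; the cross-entropy uses max-logit subtraction.  No easy-margin
fallback is applied for θ + m > π: the formula is kept literal.  With
σ = 0 the loss is exactly the fixed-margin (ArcFace-style) softmax,
which the tests verify against an independent arccos-based oracle.
Inference logits carry no margin.

## Training

AdamW (β = 0.9/0.999, weight decay 0.01 on all parameters), initial
learning rate 2e-4, no schedule or warm-up, batch size 32, image size
112.  Full-scale training budgets are hundreds of epochs; the package's
desk default is 30 and the test suite uses an 8-epoch run (see below).
The loop is fully seeded (data shuffling, margin draws, dropout,
initialization) and single-threaded deterministic; the best-validation
checkpoint (by CIR) is restored at the end.

## Synthetic data: what it emulates and what it does not

Each identity owns one vein skeleton: 3-6 smooth dark curves running
along a 100×300 finger ROI (random low-order cosine paths with random
width 2-4.5 px and depth 0.25-0.40), drawn over a bright tissue
background with a gentle illumination gradient, then Gaussian-blurred
(σ = 1.2 px) into soft-edged vessels.  Every image re-renders that
skeleton with a per-session brightness factor (±8 %), a per-image
integer translation of up to ±3 px per axis (zero fill), and additive
Gaussian sensor noise (σ = 0.03).  Defaults: 12 images per identity in
2 sessions — the structure of a typical two-session acquisition.

This captures the properties the architecture is built around —
identity-specific curvilinear structure, session illumination change,
small placement translation, sensor noise — but not finger rotation or
bending, non-rigid skin deformation, occlusion, or realistic NIR
scattering.  Passing tests therefore demonstrate that the pipeline
learns translation-robust identity features under controlled
conditions, not field performance on real sensors.

## Desk-scale study sizes

The acceptance suite trains on 50 identities × 12 images (4:1:1 split:
400 train / 100 validation / 100 test).  The suite runs 16 epochs —
fewer than the 30-epoch desk default, chosen from a pilot as the point
where the best-validation checkpoint clears CIR 0.90 on the held-out
split with margin (the pilot reaches test CIR 0.93) while keeping the
whole test run compact.  The fused deployment must reproduce the
train-structure CIR to four decimals on the same split, which
exercises the whole fusion path end to end.

## Numerical and engineering notes

* The autodiff engine stores activations in whatever float dtype enters
  the graph; equivalence audits run in float64, training in float32.
* Convolutions lower to one GEMM per kernel tap on a channels-last copy
  (BLAS accumulation directly into the output); the input gradient is
  itself a convolution with the flipped, channel-transposed kernel.
* Batch-norm statistics and backward use fused single-pass reductions;
  training batch statistics are biased (running statistics unbiased),
  the usual convention.
* `backward(free_graph=True)` releases interior activations during the
  sweep; the training loop also tunes the glibc allocator and trims the
  heap between epochs — without this, large-array churn dominates the
  run time on a single CPU.
* Dropout masks, margin draws and data shuffling each use their own
  seeded generator, so training histories are bit-reproducible.

## Known limitations

* Shift robustness is exact only in the circular-boundary idealization;
  real zero-padded borders leave a small residual sensitivity.
* The >50 % decision rule makes CIR depend on the logit scale s; both
  CIR and raw top-1 accuracy are reported for transparency.
* The synthetic generator's simplifications listed above; no claim is
  made about accuracy on real vein databases.
* Grouped/depthwise DBB variants, asymmetric (K×1/1×K) branches,
  APS upsampling, learned phase selection and verification-mode (EER)
  evaluation are out of scope.
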