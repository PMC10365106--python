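# Methods

This note documents the model, the synthetic study the package generates,
and the numerical/design choices that were genuinely open, in enough detail
to interpret what a green test run does and does not establish.

## Problem setting

Hepatocellular carcinoma recurs within one year of resection ("early
recurrence", ER) in roughly 39% of patients in the cohort composition this
package emulates (65 ER / 102 non-ER of 167). The predictor combines two
preoperative sources: three-phase contrast CT of the tumor ROI (non-contrast,
arterial, portal-venous — the phases in which hypervascular tumors show rim
enhancement and washout) and routine clinical variables.

## Clinical arm

Seventeen variables are dichotomized at standard cutoffs (age 60 y, tumor
size 5 cm, NLR 2.81, ALT 40 U/L, AST 50 U/L, AKP 125 U/L, GGT 45 U/L, ALB
40 g/L, TB 20.5 µmol/L, AFP 9 µg/L; binary yes/no for portal vein invasion,
cirrhosis, HBV, multiple tumors; categorical sex, Child–Pugh A/B, BCLC
0/A/B/C). The cutoff rule is strict-less-than for the low category
(value < cutoff → 0), matching the "<60 or ≥60" convention.

Association with the outcome is tested per variable with **Pearson's
chi-square, no Yates continuity correction, df = r − 1** for an r×2 table,
even when expected counts are small. This variant was verified against all
seventeen reference contingency tables before being frozen: it reproduces
every printed p-value at its printed rounding (including a table with a
zero cell and a 4×2 table with a sparse row); an exact test or a corrected
statistic would not. Zero *marginals* are an error; zero cells are fine.
No multiple-testing correction is applied, by design.

Variables with p < 0.05 (seven on the reference tables) enter the model as
a 9-bit vector: age, size, portal vein invasion, NLR, TB, AFP as bits
c1–c6, and BCLC as a 3-bit code c7–c9 (0→000, A→001, B→010, C→100).
The wording that introduces the "seven factors" lists six names; age is
the seventh, as the c1 definition makes explicit. The canonical ordering of
the vector is fixed and never driven by p-values.

## Image arm

Per phase, a residual CNN branch (weights independent across phases)
produces a feature map. Supported depths:

* `18` — basic-block layout 2/2/2/2, stage widths 64/128/256 and **256** in
  the last stage by default (the reference layout prints 256 where the
  conventional architecture has 512; both are supported, `standard_conv5`
  restores 512). 224×224 input → 512-/256-channel 7×7 map.
* `50` — bottleneck 3/4/6/3, final width 2048.
* `small` — the desk-scale variant used by tests and the acceptance
  benchmark: 3×3 stride-2 stem (16 ch) + 2×2 average pool, one basic block
  per stage at widths 16/32, both stages stride 2; a 64×64 input yields a
  32-channel 4×4 map. Stem/block-count/stride choices here are ours, made
  so that three full 10-fold CV trainings fit in the 15-minute/1-CPU
  budget of the acceptance benchmark; all contracts are depth-agnostic.

Phase images are grayscale and replicated to three channels at the stem so
externally supplied natural-image pretrained weights remain loadable (the
loader is file-based only; nothing is downloaded).

**Intra-phase attention** (per phase): channel branch GAP → FC(C→⌊C/r⌋,
floor, min 1; r = 16) → ReLU → FC(→C) → sigmoid, applied as per-channel
scaling; spatial branch [channel-max ; channel-mean] → 7×7 conv
(same-padding) → sigmoid, applied per-pixel; the two attended maps are
summed. The nonlinearity between the two FC layers is a rectifier (the
reference text says only "non-linear processing"); sigmoid appears only at
the end.

**Inter-phase attention**: each phase's channel vector and spatial map are
computed (independent parameters per phase by default; a switch shares
them), averaged across the three phases into one shared vector and one
shared map, applied to each phase's *original* map, and all six resulting
maps are summed into a single fused map. Placement — intra on each branch's
final-stage map, then inter fusing the three attended maps — follows the
left-to-right reading of the architecture diagram; the alternative
(per-phase sum, concatenate) is exposed as a config option but not default.

Useful identities (asserted in tests): with zero-initialized attention
parameters every sigmoid is ½, so the intra module is the identity and the
inter module is the plain sum of its inputs; the inter module is invariant
to phase permutation when parameters are permuted along.

## Fusion, loss, training

Fused map → global average pooling → FC to 30 (ReLU) = S(I); clinical
vector → FC 9→30 (ReLU) = T(c). The 30-dim width follows the reference
design; the pooled dimension before it is whatever the fused channel count
gives (32 for `small`, 256/512 for `18` — the printed "2048" is treated as
configuration-dependent, not a contract). [S ⊕ T] feeds the final 2-neuron
FC + softmax directly; no hidden layer in between.

Cross-entropy is the mean of −[y ln p₁ + (1−y) ln p₂] with probabilities
clamped to [1e-7, 1−1e-7] inside the logs. Joint mode adds auxiliary
softmax heads to both pathways before concatenation and optimizes
¼L_image + ¼L_clinical + ½L_combine; the decomposition is logged per epoch
and holds exactly in the training history. The optimizer is Adam at the
reference learning rate 1e-4 (the optimizer itself is unnamed there; Adam
is the standard choice for fine-tuning at this rate), batch 8, default 50
epochs. Optional augmentation (flips/right-angle rotations/±2% intensity
jitter) exists but is off by default. Training is fully seeded: parameter
init, shuffling and augmentation all derive from the run seed.

The whole network runs on a package-internal numpy autodiff engine
(`dpanet.nn`): im2col+GEMM convolutions (stride-1 input gradients as
transposed convolutions), fused batch-norm kernels, and a lockstep "group"
execution path that evaluates the three structurally identical branches as
batched GEMMs. The fused path is bit-identical to the sequential one (same
per-group GEMMs) and is an execution strategy only — parameters stay owned
by the individual branches. Every layer's analytic gradient is checked
against central finite differences in float64 in the test suite.

## Synthetic study

`dpanet.synthetic` generates the full study the other modules consume. Per
patient: a Bernoulli(0.389) ER label; a clinical record sampled from the
class-conditional category frequencies of the reference tables (variables
independent given class — a deliberate simplification; real risk factors
co-occur); raw continuous values drawn uniformly on the correct side of
each cutoff so dichotomization reproduces the target frequencies; and 3–7
co-registered three-phase 64×64 slices (224 is supported) in which the
central slice has the largest lesion cross-section.

Images are a smoothed background field plus an elliptical lesion. The class
signal is planted the way aggressive HCC presents: arterial-phase rim
enhancement, portal-venous washout, boundary irregularity and internal
speckle, all *stronger on average* for ER. Each patient draws their own
rim amplitude, washout depth, speckle and roughness from class-conditional
normal distributions (≈1 within-class sd of separation per feature). The
overlap matters: with deterministic class effects the imaging arm is
perfectly separable and fusion cannot demonstrate any benefit from clinical
data — the opposite of the regime the package emulates, where imaging alone
is informative but imperfect and clinical fusion adds measurable AUC.
Images are quantized to the 16-bit export grid at generation time so the
PNG export/load round-trip is exact.

What the generator does **not** emulate: organ anatomy, CT physics, scanner
effects, slice-thickness variation, registration error, or clinical–imaging
correlation (a synthetic patient's tumor-size *image* and tumor-size
*clinical bit* are independent draws). A green benchmark therefore
establishes that the pipeline can learn planted class-conditional contrast
patterns and fuse them with a class-conditional clinical code — not any
clinical claim.

## Evaluation protocol

Cross-validation is stratified by patient and class: within each class,
patients are shuffled (seeded) and dealt round-robin; each class's
remainder goes to the currently lightest folds, so with 65/102 and k = 10
every fold holds 6–7 ER and 10–11 non-ER patients (16–17 total). Slices
never straddle folds. Per patient, the slice with the largest tumor area
(ties → lower index) ± 2 adjacent slices with positive area are used.
Metrics are slice-level by default (the reference bookkeeping counts
slices); a patient-level option averages slice probabilities first.
Accuracy thresholds P(ER) at 0.5; AUC is the rank statistic (ties count
half); fold aggregates are mean ± sample (n−1) sd.

## Numerical notes and limitations

* float32 throughout by default; `dpanet.nn.autograd.DTYPE` switches the
  engine to float64 (used by gradient-verification tests).
* Batch norm uses biased batch variance for normalization and for the
  running averages (momentum 0.1).
* Max-along-axis gradients go to the first argmax on ties.
* The 7×7 spatial-attention convolution uses same-padding, so attention
  works down to 4×4 maps, where a 7×7 receptive field is effectively
  global.
* Lesions require images of at least ~32×32; smaller inputs error.
* The engine is single-threaded numpy; it is sized for the small backbone
  at 64×64. Depths 18/50 are functional (and shape-tested) but training
  them at 224×224 is not a desk-scale activity.
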