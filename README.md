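# dpanet

Early-recurrence prediction for hepatocellular carcinoma (HCC) from
three-phase contrast-enhanced CT and routine clinical data, using a
**deep phase-attention fusion network**. The package is aimed at
medical-imaging ML researchers who want a fully testable, dependency-light
implementation of the model family — including a seeded synthetic cohort
generator, so every component runs and is verified without access to any
patient data.

## The model

A patient contributes 3–7 tumor-ROI CT slices, each acquired in three
contrast phases — non-contrast (NC), arterial (ART), portal-venous (PV) —
plus a clinical record. The network has two pathways:

**Image pathway.** Three residual CNN branches (one per phase, weights not
shared) extract per-phase feature maps. Each map passes through
*intra-phase attention*: a squeeze-excite channel branch and a CBAM-style
spatial branch applied in parallel and summed,

```
A(F) = F ⊙ σ(W₂ relu(W₁ GAP(F)))  +  F ⊙ σ(conv7×7[max_c F ; mean_c F])
```

Then *inter-phase attention* averages the three phases' channel vectors and
spatial maps into one shared vector/map, applies them to each phase's
original map, and sums all the results into a single fused map. Global
average pooling and a fully connected layer give a 30-dim image feature
S(I).

**Clinical pathway.** Seventeen routine variables (age, tumor size, portal
vein invasion, NLR, bilirubin, AFP, BCLC stage, liver-function labs, ...)
are dichotomized at standard clinical cutoffs and screened against the
outcome with Pearson chi-square tests (no continuity correction, df = r−1);
variables with p < 0.05 are encoded into a 9-element binary vector
(six binary factors + a 3-bit BCLC code), which an FC layer lifts to a
30-dim feature T(c).

**Fusion and loss.** The concatenated feature [S ⊕ T] feeds a 2-neuron
softmax head, p_k = e^{z_k}/Σe^{z_k}, trained with mean binary
cross-entropy. In *joint* mode, auxiliary softmax heads on both pathways
add deep supervision:

```
L = ¼·L_image + ¼·L_clinical + ½·L_combine
```

Evaluation is patient-stratified 10-fold cross-validation (no patient's
slices ever straddle train/test), slice-level accuracy and rank-statistic
AUC, reported as mean ± sd over folds.

The network is implemented on a small numpy reverse-mode autodiff engine
(`dpanet.nn`) — no deep-learning framework required; every layer's gradient
is verified against finite differences in the test suite.

## Worked example

```bash
# 1. simulate a synthetic study: 40 patients, three-phase 64x64 ROI stacks
dpa simulate --seed 7 --n-patients 40 --out cohort/

# 2. chi-square screening of the exported clinical CSV
dpa chi2 --csv cohort/clinical.csv --out screening/

# 3. 3-fold cross-validation of the full fusion model
dpa crossval --cohort cohort/ --seed 7 --k 3 --epochs 8 \
    --loss-mode joint --out cv/
```

A run of step 1 prints

```
generating cohort: n=40, seed=7
wrote 40 patients (17 ER, 42.5% prevalence) to cohort/
```

(ER = early recurrence within one year; labels are Bernoulli draws at the
38.9% prevalence of the reference cohort). Step 2 writes `chi_square.csv`
(statistic, df, p, selected per variable) plus the patients' 9-bit vectors,
and reports the selection on stderr:

```
selected at alpha=0.05: ['tumor_size_mm', 'afp', 'ggt']
```

— at n=40 only the strongest effects reach p < 0.05; on the full
167-patient reference tables the same screening selects exactly the seven
encoded variables (age, tumor size, portal vein invasion, NLR, TB, AFP,
BCLC), which is what the test suite asserts. Step 3 trains one model per
fold and prints

```
accuracy 70.1% +/- 17.5, AUC 0.790 +/- 0.162
```

meaning: mean slice-level accuracy/AUC across the 3 held-out folds ± sample
sd — even this small run largely recovers the planted arterial-rim/washout
imaging signal and class-conditional clinical profile (the fold spread is
wide at n=40; the acceptance benchmark uses n=200 and 10 folds).
`cv/report.json` and `cv/folds.csv` carry the per-fold numbers, seeds and
the patient→fold map for exact replay.

The library surface mirrors the CLI: `dpanet.clinical` (screening +
encoding), `dpanet.backbone` / `dpanet.attention` / `dpanet.model`
(the network), `dpanet.synthetic` (cohort generator), `dpanet.evaluation`
(cross-validation harness).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the main computation from scratch: the chi-square screening and
encoding on a cohort reconstructed from the reference contingency tables,
then a seeded synthetic cohort and a cross-validated fusion model. Progress
goes to stderr and the results JSON is written to `--out`.

## Layout

```
src/dpanet/        library (nn engine, clinical, backbone, attention,
                   model, synthetic, evaluation, cli)
tests/             pytest suite incl. end-to-end acceptance checks
docs/methods.md    model, synthetic-data and numerical details
scripts/           acceptance runner
```
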