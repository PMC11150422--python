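# fundusfair

Implicit-fairness multi-label screening of ocular disease from fundus
images, at desk scale.

AI screening models trained on clinical fundus datasets inherit the
datasets' demographic imbalances: their per-disease average precision can
differ sharply between sexes and between age groups. `fundusfair`
implements an *implicit fairness learning* approach for this problem — a
two-branch classifier whose disease decisions are routed through fundus
*pathology* evidence (microaneurysms, drusen, laser scars, …). Because
the causal link between fundus features and diseases is largely
independent of patient sex and age, grounding the classifier in that
evidence mitigates group disparities without any explicit fairness
regulariser. The package is aimed at researchers studying fairness in
medical imaging who want every component — metrics, model, losses,
biased data — runnable and testable on a laptop CPU.

## What is inside

**Fairness metrics** (`fundusfair.fairness`). For disease k and sensitive
groups i ∈ S with per-group average precision AP_{k,i} (percent):

    ΔD_k = 100 · (max_i AP_{k,i} − min_i AP_{k,i}) / mean_i AP_{k,i}
    ΔM   = max_k ΔD_k          (max screening disparity)
    ΔA   = mean_k ΔD_k         (average screening disparity)

A disease missing an AP value for any group (no positive samples there)
is excluded, and ΔA divides by the number of *scored* diseases. Min/max
ratio companions: PQD (per-class AP ratio), DPM (positive-prediction-rate
parity) and EOM (true-positive-rate parity), each 100 at perfect parity;
DPM/EOM need per-sample predictions.

**Screening metrics** (`fundusfair.screening`): non-interpolated AP, ROC
AUC, sensitivity/specificity/precision at a threshold, macro averages,
and group-stratified AP tables with explicit missing cells.

**The two-branch model** (`fundusfair.model`): pathology and disease
encoders produce feature volumes F_p, F_d ∈ R^{C×H×W}; channel attention
w = σ(ReLU(W·gap(F_p)+b)) (components necessarily in [0.5, 1)) selects
pathology channels, which are fused additively, F_e = (F_p ∘ w) ⊕ F_d; a
pathology head classifies fundus features from F_p and a disease head
classifies diseases from F_e. A single-branch `BaselineNet` is the
fairness comparator. The networks, BatchNorm, Adam and the one-cycle
schedule are implemented in numpy with hand-written backprop, verified
against finite differences in the test suite.

**The composite objective** (`fundusfair.losses`):

    L = λ₁·L_patho + λ₂·L_disea + λ₃·L_joint + λ₄·L_consis,
    λ = (0.01, 1, 0.01, 1e-5)

with asymmetric losses (γ⁺=0, γ⁻=4, clip=0.05) on both heads, a
prediction-consistency penalty tying disease probabilities to the scores
implied by the predicted features through a feature–disease relation
matrix, and the mean-squared feature-map consistency term.

**A biased synthetic fundus simulator** (`fundusfair.synthetic`):
scattered lesion glyphs on noisy backgrounds, disease labels derived
from feature labels through a causal map, label densities calibrated to
1.94 (diseases) and 2.05 (features), sex/age-dependent prevalence tilts
and a sex-linked image-style shortcut. Same seed ⇒ bit-identical data.

**Pipeline + CLI** (`fundusfair.pipeline`, `fundusfair` console script):
seeded training with the Adam/one-cycle recipe, group-stratified
evaluation, table-only disparity reports, and a two-arm comparison
harness. Subcommands: `simulate`, `train`, `evaluate`, `table-metrics`,
`compare`.

## Worked example

Disparity metrics straight from a published class-by-group AP table
(packaged with the library):

```bash
$ fundusfair table-metrics sex_twobranch --markdown
| metric | value |
|---|---|
| dM (max screening disparity) | 66.5% |
| dA (average screening disparity) | 7.6% |
| excluded classes | Retinal white dots |
```

The two-branch model reaches an average sex disparity of 7.6% over the
37 diseases with AP values for both sexes; the worst single disease
(aneurysms, AP 44.0% male vs 87.8% female) has ΔD = 66.5%. The same
command on `sex_baseline` gives ΔA = 10.3%, ΔM = 60.5% — the baseline is
worse on average though its single worst disease is milder.

A full desk-scale experiment — simulate a sex-biased dataset (n = 1000),
train both arms for 5 epochs, evaluate sex fairness (a few minutes on
one CPU):

```bash
$ fundusfair compare --seed 0 --out runs/demo
| arm | map | delta_a | delta_m | pqd_mean | dpm | eom |
|---|---|---|---|---|---|---|
| baseline | 63.1 | 49.4 | 122.8 | 63.8 | 75.5 | 92.3 |
| two_branch | 66.2 | 40.1 | 114.9 | 70.4 | 66.3 | 87.1 |
```

On this seed the two-branch model screens more accurately (mAP 66.2 vs
63.1) *and* more fairly (sex ΔA 40.1 vs 49.4) than the single-branch
baseline — the directional effect the architecture is designed for.
`compare_over_seeds` repeats this over seeds and reports the fraction of
wins.

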