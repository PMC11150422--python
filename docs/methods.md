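# Methods

This note documents the models, metrics, simulator and numerical
choices behind `fundusfair`, including where the design was genuinely
open and what the desk-scale experiments do and do not show.

## The screening problem and the fairness metrics

Multi-label fundus screening is treated as independent per-disease
binary tasks. Per class we report non-interpolated average precision
(AP), ROC AUC, and sensitivity/specificity/precision at an operating
threshold; macro summaries are unweighted means over classes with
defined values. AP convention: samples are ranked by descending score
with a *stable* sort (original index breaks ties), and AP is the mean of
precision at each positive's rank. This is the common multi-label
convention, it is deterministic, and it is checkable against a
brute-force oracle; note AP is tie-order dependent, which is why the
tie-break is pinned. AUC uses the rank-statistic (trapezoidal /
tie-averaged) form via scikit-learn.

Group fairness is quantified on the 0–100 percent scale:

* **ΔD** (per class): 100·(max−min)/mean of group APs. Undefined with
  fewer than two present groups (an error, distinct from the zero of
  equal groups). The all-zero vector returns 0 — the only input where
  the ratio would be 0/0, since max>0 implies mean>0.
* **ΔM / ΔA**: max and mean of ΔD over classes. A class missing any
  group's AP (no positives in that group's test subset — the "–" cells
  of published stratified tables) is excluded from both, and ΔA divides
  by the scored-class count. This exclusion convention is the one under
  which the packaged reference tables reproduce their published
  summary values.
* **PQD / DPM / EOM**: min/max-ratio summaries (per-class AP ratio;
  positive-prediction-rate parity; TPR parity), 100 at parity. Their
  defining reference gives them only qualitatively, so the min/max-ratio
  forms here are a documented interpretation. DPM/EOM require
  per-sample predictions; classes never predicted positive (DPM) or
  with positives in fewer than two groups or no group attaining TPR>0
  (EOM) are excluded and reported.

Excluded-class lists are sorted lexicographically for determinism.

## The two-branch model

Two convolutional encoders with identical architecture produce a
pathology feature volume F_p and a disease feature volume F_d
(C×H×W). The channel-attention path is implemented literally as one
affine map followed by ReLU then sigmoid,

    w = σ(ReLU(W·gap(F_p) + b)),  w ∈ [0.5, 1)^C,

where gap is spatial global average pooling. The range [0.5, 1) is a
structural consequence of ReLU-then-sigmoid and is asserted in tests.
Selection is the channel-wise Hadamard product F_p ∘ w; fusion is the
element-wise sum F_e = F_p^sel ⊕ F_d (the fused map and the
"pathology-aware" map are one object). Classifier heads are global
average pooling followed by a single affine layer — the minimal
conventional choice, as no head architecture is prescribed. A
CBAM-style spatial gate (sigmoid of a small conv over channel-pooled
maps) is available behind `spatial_attention` (default off), since only
the channel path is defined by the equations the module implements.
No bottleneck ratio being specified, the attention map is a full C→C
affine map. The baseline comparator is the disease encoder and head
alone.

**Backbone.** The reference recipe in the literature uses two
ImageNet-pretrained ResNet-101 encoders. This package provides a
compact, width-configurable encoder family (default 3 conv layers,
channels (8,16,16), 3×3 kernels, stride 2, BatchNorm+ReLU), implemented
in numpy with hand-written backprop. BatchNorm is essential for a
from-scratch CNN trained for a handful of epochs; evaluation uses
running statistics so inference is deterministic and batch-size
independent. All layer gradients, and the full composite objective
end-to-end, are verified against central finite differences (the conv
biases that immediately precede BatchNorm have true gradient ≈ 0, since
BN absorbs per-channel constants).

## The objective

    L_total = λ₁·L_patho + λ₂·L_disea + λ₃·L_joint + λ₄·L_consis

with λ = (0.01, 1, 0.01, 1e-5). L_patho and L_disea are asymmetric
losses (ASL) on the two heads: positives contribute −(1−p)^{γ⁺}·log p,
negatives −(p_m)^{γ⁻}·log(1−p_m) with p_m = max(p−c, 0); defaults
γ⁺ = 0, γ⁻ = 4, c = 0.05 follow the ASL literature. ASL with
γ⁺ = γ⁻ = c = 0 equals binary cross-entropy, which the tests assert to
1e-6. Probabilities are clamped to [1e-8, 1−1e-8] before logs.

L_consis is exactly the printed mean-squared difference between the two
feature volumes, normalised by width·height·channels.

L_joint has no printed form; it is implemented here as a
relation-matrix consistency penalty: with binary relation R
(features×diseases), each disease's pathology-implied score is the mean
of its related features' predicted probabilities (column-normalised R),
and the loss is the mean squared difference to the disease
probabilities. Diseases related to no feature are skipped with one
logged warning. The relation matrix comes from the simulator's
ground-truth causal map when available, otherwise from empirical
feature–disease co-occurrence on the training split binarised at >0.
This construction is an interpretation and is flagged as such.

All four terms expose analytic gradients; zeroing a λ removes that term
from both value and gradient, so published-style ablations can be
mimicked from configuration.

## Optimisation

Adam (betas (0.9, 0.999), weight decay 1e-4, applied to the gradient)
with a one-cycle learning-rate schedule: 30% cosine warm-up from
peak/25, cosine anneal to peak/1e4. The reference recipe trains 100
epochs at batch 16, peak 1e-4, with random horizontal and vertical
flips (training only; evaluation is deterministic). The **desk preset**
(`desk_preset()`) is *not* that recipe: 64×80 images (the reference
512:648 aspect at 1/8 scale), the compact encoder, 5 epochs at batch
16, peak 3e-3, and weight averaging over the final two epochs'
iterates. The higher peak rate and the averaging exist because a small
network trained from scratch for ~160 steps needs them to reach a
stable operating point; both apply identically to the two-branch and
baseline arms. Training is bit-reproducible for a fixed seed on fixed
hardware/BLAS; across numeric platforms runs are seed-reproducible only
statistically.

## The synthetic biased-fundus simulator

The simulator emulates the statistical structure the method assumes,
not fundus appearance:

* **Features and glyphs.** Eight fundus features render as scattered
  glyph instances (blobs, streaks, rings, dot clusters; 2–4 instances,
  radii 3–7 px, signed intensities ±0.5–0.65 with per-feature tints) on
  a smoothly-noisy background, anti-aliasing off so images are
  bit-reproducible. Glyphs are deliberately salient: the reference
  systems operate near the AP ceiling, so the desk-scale stand-in must
  be learnable by a small encoder in a few epochs rather than simulate
  chronic underfitting.
* **Causal map.** Disease labels are a deterministic boolean function
  (OR/AND over 1–3 features) of the feature labels — checked exactly in
  tests. The default map is two balanced two-feature ORs plus four
  sex-skewed single-feature diseases, chosen so every disease keeps
  ≥ ~0.12 prevalence in its rarer sex: stratified AP on a desk-scale
  test split is meaningless below a few dozen positives per cell.
  Optional label noise (default 0) flips disease bits after the map.
* **Label-density calibration.** A build-time root-find scales feature
  prevalences so the analytic mixture feature density equals 2.05; the
  implied disease density (1.957 analytic) is validated within ±15% of
  its 1.94 target, else the spec fails construction.
* **Sensitive attributes and bias.** Sex ~ Bernoulli(½); age in nine
  10-year brackets (0–10 … 81–90) with a clinic-like distribution
  peaking at 51–70. Prevalence bias: per-feature exponential tilts,
  exp(±0.6) by sex at default (age tilt available, default 0 — the
  default dataset is sex-biased only). Style bias: two image "device"
  styles (bright/low-vignette vs dim/high-vignette, opposite tints)
  with P(bright|female) = 0.85 vs 0.15 for males. The mixture design is
  deliberate: a strictly group-constant style shift cannot change
  group-stratified AP (it shifts all of a group's scores uniformly), so
  it would be a shortcut with no measurable fairness cost; a
  sex-*linked but within-group-variable* style corrupts within-group
  rankings when a model leans on it. Style touches pixels only —
  manifests are bit-identical across style settings under a fixed seed.
* **Splits.** Each sample is one synthetic patient; the train/test
  split is drawn per patient, 50/50 by default so the rarest
  (disease, sex) test cells retain ~25–30 positives at n = 1000.
* **`inject_bias`.** Post-hoc exponential-tilt thinning of an existing
  manifest: at strength 0 nothing is dropped; prevalence ratios grow
  monotonically with strength; extreme strengths empty (class, group)
  cells, exercising the missing-AP pathway.
* **RNG discipline.** Labels/attributes and pixels consume separate
  seeded streams (one per image for pixels), so identical seeds give
  bit-identical datasets and label structure is invariant to rendering
  options.

## What the desk-scale experiments show — and what they do not

On the default biased dataset the two-branch model at the desk preset
attains higher test mAP than the baseline in most seeds and lower sex
ΔA in most seeds (roughly three quarters of seeds jointly, with mean
advantages of about +3 mAP and −8 ΔA points). Trained longer (15
epochs) both arms converge to similar accuracy and the fairness gap
closes: the desk conditions measure the regime where pathology
grounding makes fair representations arrive *earlier*, which is the
directional claim — not a numeric reproduction of any published
accuracy or disparity value, and not evidence about photorealistic
data, race/ethnicity attributes (absent here), or pretrained backbones.

The only published numbers recomputed exactly are the four sex-fairness
summaries obtained by applying ΔD/ΔM/ΔA to the packaged per-disease
sex-stratified AP tables (ΔA 7.6 / ΔM 66.5 for the two-branch model;
10.3 / 60.5 for the baseline, over 37 scored diseases). The coarse
"age-division" groupings behind published age-disparity summaries are
not specified anywhere recoverable, so the age tables ship with
bracket-level machinery only.

## Numerical conventions and degenerate inputs

* Percent scale [0,100] for all reported metrics; internal double
  precision; published-style reporting rounds to one decimal.
* Undefined is an error or an explicit missing state, never silently 0:
  AP without positives, AUC with one class, ratios with zero
  denominators, disparities with <2 groups.
* Probability clamp 1e-8; ASL's clipped negatives contribute exactly
  zero loss and gradient beyond the margin.
* Checkpoints are self-describing (.npz with embedded JSON config,
  seed, config hash, relation matrix, disease names, BN running
  statistics); evaluation never mutates them.

## Known limitations

* No pretrained backbone: conclusions about ImageNet-initialised
  encoders do not transfer from these experiments.
* The glyph world is far simpler than fundus photographs; passing tests
  show the mechanism operates under the assumed causal structure, not
  that it survives real-data violations of it (annotation noise,
  feature–disease links that vary with demographics, site effects
  beyond the two-style model).
* Training determinism is platform-scoped: different BLAS builds give
  different (statistically equivalent) trajectories.
* The joint-loss construction is one reasonable reading of an
  unspecified term; alternatives (e.g. learned relations) are untested.
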