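# Methods

`ppcsurv` implements a postoperative pulmonary complication (PPC)
surveillance pipeline in two coupled stages: a hybrid tabular risk
classifier, and a deterministic recommendation engine that converts
predicted risk plus abnormal findings into structured nursing-surveillance
actions. Because real postoperative EMR extracts of this kind are
access-restricted, the package also ships the synthetic cohort generator on
which every stage is developed and tested. This note records the models,
the defaults and why they were chosen, and what the synthetic setting does
and does not demonstrate.

## The cohort model

A cohort is a flat table of 41 features per patient plus a binary label
`ppc`: 18 numerics (demographics, anthropometrics, anesthesia time, minimum
hemoglobin, and min/max summaries of postoperative vitals), 13 categoricals
(surgical site/approach, diagnosis group, admission route, lifestyle and
history codes, and three derived bin columns), and 10 booleans (seven
"judge" flags marking vitals outside their configured normal range, three
nursing-note symptom indicators). Column names, including the spellings
`Sugical_code_approach` and `Is_acivity_free`, follow the source EMR export
verbatim.

The generator assigns labels first — exactly `round(n * prevalence)`
positives, default prevalence 0.2 — then draws features class-conditionally:

- numerics from truncated normal distributions inside physiologic hard
  bounds, with case means shifted by a configurable `case_shift`;
- categoricals from class-conditional multinomials (cases lean toward open
  approach, emergency admission, and higher-burden sites/diagnoses);
- the three symptom booleans from label-dependent Bernoulli rates (they
  summarize nursing notes and have no vital to be derived from);
- BMI from height and weight; the bin columns (`Age_1`, `BMI_1`,
  `Anesthesia_time_1`) and all seven judge flags deterministically from the
  sampled values. Flags are *never* sampled independently of the vitals, so
  a generated cohort always passes its own consistency validator.

Min/max pairs are ordered by swapping the rare inversions after sampling.

Two presets are shipped. The `paperlike` preset plants its three largest
standardized shifts on `Min_SpO2` (-0.64 SD), `Anesthesia_time` (+0.65 SD)
and `PR_max` (+0.62 SD), with the remaining planted effects at or below
~0.37 SD; it was calibrated once so that well-specified reference
classifiers (random forest, logistic regression on the encoded table) reach
a held-out AUROC of roughly 0.8 at n = 5000, the regime reported for the
real cohort. The `separable` preset doubles-to-triples those shifts and
makes symptom indicators strongly label-dependent, giving AUROC > 0.99 for
pipeline smoke tests. No distributional forms or parameters for the real
data were available, so all generator parameters are package defaults, not
facts about any hospital.

What the generator deliberately omits: missing data (the modeled dataset
contains none, so validation treats any missing value as a hard failure and
no imputation path exists), longitudinal structure (the postoperative
window is collapsed to min/max summaries), inter-feature correlation beyond
the BMI identity and the flag derivations, and site-specific coding
idiosyncrasies. Passing tests therefore demonstrate that the pipeline's
machinery is correct and recovers planted structure — not that its
operating characteristics transfer to real EMR data.

## Preprocessing

Continuous features are z-scored with mean/SD (population form, ddof = 0)
fit on the training split only; a zero-variance feature is an error naming
the feature. Categorical levels map to stable schema-declared indices;
booleans to {0, 1}; unseen levels are schema violations rather than an
"other" bucket. The derived bin columns are always regenerated from their
source numerics, never trusted from input. Default adult normal ranges
(editable configuration): SBP 90–140 mmHg, DBP 60–90 mmHg, BT 36.0–38.0 °C,
RR 12–20 /min (inclusive), PR 60–100 /min, SpO2 abnormal iff < 95%, NRS
abnormal iff >= 4. Only the SpO2 cut-off is externally anchored; the others
are standard adult defaults chosen so the shipped case-study example
reproduces its printed labels.

## Importance weighting

A simplified random forest (100 trees, depth 6, balanced class weights,
fixed seed) is fit on the encoded training table, and per-feature global
importance is the mean absolute SHAP value over the training patients.
TreeSHAP is implemented in-package (numba-compiled, path-dependent
conditional expectations with cover weighting); it satisfies local accuracy
to machine precision and is verified in the tests against a brute-force
Shapley-over-subsets oracle on small trees. Importance is computed on
training data only, after averaging when folds are supplied, and then
max-normalized to `imp ∈ [0, 1]`; max-normalization makes the weight bound
exact. The encoder-input weight of feature *i* is

    w_i = 1 + λ · imp_i^γ ,   defaults λ = 0.27, γ = 0.82,

so `w ∈ [1, 1 + λ]`: the most important feature is scaled by 1.27, an
uninformative one passes through unchanged, and no feature is ever dropped.
Numeric columns are multiplied by `w_i`; each categorical/boolean feature's
embedding vector is scaled by its `w_i`. λ = 0 reproduces the unweighted
input exactly and is the "no weighting" ablation arm.

## The hybrid classifier

The encoder is a two-hidden-layer MLP (256 → 64, ReLU, dropout 0.43)
implemented directly on numpy with manual backpropagation. Continuous
inputs enter directly; every categorical *and boolean* feature gets a
learned embedding (default dimension 8) so that each feature has a
weightable input vector. A single-logit head is used only for pre-training.
Optimization is Adam (lr 2.16e-3, batch 256) for up to 50 epochs with a
linear warm-up from lr/10 over the first 5 epochs, early stopping on
validation AUROC (patience 10) and best-weight restoration. The latent
representation is the *post-activation* value of the second hidden layer in
inference mode (dropout off).

Class imbalance is handled by four cooperating mechanisms, each removable
for ablation:

1. pos-weighted BCE-with-logits, `pos_weight = n_neg / n_pos` by default
   (≈ 4 at the default 8:2 distribution); a focal-loss alternative
   (`-α_t (1-p_t)^γ log p_t`, α applied to the positive term so γ=0, α=1
   reduces exactly to plain cross-entropy) is available and searchable;
2. an inverse-class-frequency weighted sampler with replacement, giving an
   expected 50% positive fraction per batch;
3. balanced class weights in the forest head;
4. a decision threshold tuned on validation data instead of fixed 0.5.

The forest head (200 trees, max depth 10) is fit on the latents. The
threshold optimizer maximizes positive-class F1 (F-beta configurable) over
the midpoints between consecutive sorted unique validation probabilities
plus 0.5 — exhaustive over achievable confusion matrices — with ties broken
toward the larger threshold (favoring specificity). Classification is
strict: positive iff probability > threshold. Forest probabilities are the
standard mean of per-tree class fractions, so end-to-end predictions are
bit-reproducible under fixed seeds.

Training and importance estimation use only the training portion; when no
validation table is supplied, a stratified 20% of the training cohort is
held out internally for early stopping and threshold calibration.

## Evaluation

Seven metrics: precision, recall (sensitivity), accuracy, F1-macro
(unweighted mean of per-class F1), ROC-AUC (Mann–Whitney / trapezoidal),
PR-AUC (step-wise interpolation of precision between recall points — the
interpolation convention is recorded because conventions differ), and
specificity. Confidence intervals are percentile intervals from 1000 paired
case resamples (resamples with a single class are redrawn, at most 100
times); the CI method is labeled in outputs since analytic alternatives
exist. Hyperparameter search is seeded random search over a declared space,
scored by mean validation AUROC over 5 stratified folds whose partition is
fixed by a seed shared across trials; the full trial log is returned. The
four-arm ablation (`full`, `no_shap`, `no_imbalance`, `baseline`) shares
splits and seeds within each replicate so arm differences are attributable
to the removed components.

## Recommendation engine

The 12-action surveillance ontology (respiratory observation, sputum
assessment, SpO2 and vital-sign monitoring, temperature and infection-sign
monitoring, pain monitoring and expression, early ambulation, physician
communication, chest X-ray follow-up) ships as editable YAML with, per
action, an admissible-evidence feature set and a tier (`basic` /
`elevated`). The evidence map is anchored to the actions' clinical
semantics: respiratory actions accept RR/SpO2/respiratory symptoms; the
sputum action accepts bronchial-secretion symptoms; generic
monitoring-intensity actions (4, 5) accept any abnormal vital; temperature
actions accept BT and systemic-infection symptoms; pain actions accept the
pain score; the two physician-communication actions accept any abnormal
finding; early ambulation needs no evidence.

Assessment lists one finding per vital outside its normal range and per
documented symptom. The engine emits, for each finding, every action whose
admissible set contains it; high-risk patients additionally receive the
monitoring defaults (actions 4 and 5) justified by the predicted risk
itself; low-risk patients without findings receive only the basic tier
(action 10). Rationale text comes from fixed per-(action, finding)
templates and is never part of the validation contract.

The validator labels a record `unnecessary_action` when its cited value is
within range (or cited symptom absent), `evidence_mismatch` when the value
is abnormal but inadmissible for the action, and `correct` otherwise;
risk-tier evidence is correct iff the action is the declared default for
that risk level. Scores are 5 (correct) or 1, averaged per patient and
rounded half-up into bins 1–5 (the rounding rule is a package choice; only
the averaging into five scores is externally specified). By construction
the engine is sound: every record it emits validates as correct, which the
tests check on hundreds of emitted records. The prompt builder renders the
same patient state as an itemized instruction prompt so an external
language model can replace the rule engine and have its parsed output
pushed through the identical validator and scorer.

## Numerical and design notes

- Losses use softplus-based stable forms; the test oracle is 50-digit
  decimal arithmetic, since the naive `log(1-sigmoid(z))` formula loses
  precision beyond |z| ≈ 20.
- The all-zero importance vector maps to all-zero `imp` (weights ≡ 1) with
  a warning rather than dividing by zero.
- A degenerate validation probability vector (all values equal) yields
  threshold 0.5 with a warning.
- Booleans are embedded rather than passed as numerics so that importance
  weights act uniformly on every feature's input vector.
- Whether the latent should be pre- or post-activation was an open choice;
  post-activation was chosen and is part of the persisted model contract.
- Substantial components are implemented in-package rather than imported:
  the MLP encoder (numpy, manual gradients), path-dependent TreeSHAP
  (numba), and the random search. Scikit-learn provides the forests, fold
  construction, and reference metric implementations; pydantic validates
  the recommendation JSON.

## Problem sizes used by the test and acceptance runs

Heavier properties run at the sizes the study conditions prescribe:
pipeline discrimination at n = 5000 (paper-like, 10 seeds) and n = 2000
(separable); SHAP ranking recovery at n = 2000 over 20 seeds; the
imbalance-benefit comparison at n = 2000, prevalence 0.10, 10 paired seeds;
the ablation echo at n = 5000 over 5 seeds (at markedly smaller n the
four-arm F1-macro differences are dominated by split noise and the
comparison is uninformative); bootstrap coverage over 200 simulated
datasets of n = 500 against a fixed scoring rule whose population AUC is
computed once from a 120 000-patient draw. `scripts/acceptance.py` trains
the full defaults once at n = 5000 and reports the panel, ablation arms at
n = 5000 over 3 seeds, SHAP ranking over 5 seeds, and the recommendation
statistics for the held-out test patients.

## Known limitations

Synthetic features are conditionally independent given the label (beyond
derived columns), which favors additive models and makes importance
recovery easier than in collinear EMR data. The threshold is tuned for
positive-class F1, which on moderately imbalanced data can trade macro-F1
against the fixed-0.5 arms within noise. Reported operating characteristics
describe the generator's regime only; deployment on real data would require
re-fitting, local normal-range configuration, recalibration and prospective
validation.
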