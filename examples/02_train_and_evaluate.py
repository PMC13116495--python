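"""Train the hybrid risk model end to end and evaluate the metric panel.

Pipeline: z-scoring + index coding -> SHAP-importance input weights
(w = 1 + 0.27 * imp^0.82) -> MLP encoder (256 -> 64, pos-weighted BCE,
weighted sampler) -> random-forest head (200 trees, balanced) -> decision
threshold tuned on validation data.
"""

from ppcsurv import (
    LABEL_COLUMN,
    PipelineConfig,
    evaluate,
    generate_cohort,
    make_config,
    split_cohort,
    train_hybrid,
)

table = generate_cohort(make_config(5000, 0.2, "paperlike", seed=0))
train, test = split_cohort(table, 0.2, stratified=True, seed=0)

model = train_hybrid(train, PipelineConfig(seed=0))
print(f"decision threshold (tuned on validation): {model.threshold:.3f}")
top = model.weights.to_frame().nlargest(3, "w")[["feature", "imp", "w"]]
print("largest input weights:\n", top.to_string(index=False))

probs = model.predict_proba(test)
preds = model.predict(test)
report = evaluate(test[LABEL_COLUMN].to_numpy(), preds, probs, n_boot=500, seed=0)
print(report.to_frame().round(3).to_string(index=False))
# roc_auc ~0.8 on this preset; the CI columns are percentile bootstrap
# intervals from 500 paired case resamples.
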