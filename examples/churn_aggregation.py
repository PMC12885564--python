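"""Aggregating three churn models' importance tables (packaged fixture).

Logistic regression, a decision tree and XGBoost rank six churn
predictors.  All agree tenure matters; they disagree on the rest, and age
is prominent only for XGBoost.  With k=3 (six features, top half) the
consensus keeps tenure first and flags age as a one-model signal.
"""

import wisfc as w

outputs = w.load_churn_example()
for o in outputs:
    print(f"{o.model_id:22s} metric={o.metric:16s} performance={o.performance}")
print()

result = w.aggregate(outputs, w.AggregationConfig(k=3))
print(result.table.to_string(index=False), end="\n\n")

# the same table with performance-based (softmax) weights
soft = w.aggregate(
    outputs,
    w.AggregationConfig(k=3, weighting=w.Weighting.SOFTMAX_PERFORMANCE),
)
print("softmax model weights:", dict(zip(soft.weights.model_ids, [round(x, 3) for x in soft.weights.weights])))
print(
    "\nFC counts one vote per model regardless of weights; the weighting only\n"
    "shifts WIS toward the better-performing model's view."
)
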