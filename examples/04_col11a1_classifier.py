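"""Train the Random Forest to predict COL11A1 positivity from texture.

Runs the discovery -> validation workflow end to end at reduced tile
counts and prints the confusion matrix under both metric conventions.
"""

from stromatex.classify import ForestConfig, MetricConvention
from stromatex.pipeline import PipelineConfig, run_discovery_validation

config = PipelineConfig(
    seed=7,
    n_discovery_pos=20, n_discovery_neg=20,
    n_validation_pos=10, n_validation_neg=10,
    forest=ForestConfig(n_trees=200),
)
result = run_discovery_validation(config)
s = result["evaluation"]

print(f"validation tiles: {s.total}  (TP={s.tp} FP={s.fp} TN={s.tn} FN={s.fn})")
print(f"accuracy: {100 * s.accuracy:.2f}%")
for conv in MetricConvention:
    print(f"  {conv.value:10s} convention: sensitivity {100 * s.sensitivity(conv):6.2f}%"
          f"  specificity {100 * s.specificity(conv):6.2f}%")
print("The reference convention divides by true class sizes; the predicted")
print("convention divides by predicted class sizes (precision / NPV).")
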