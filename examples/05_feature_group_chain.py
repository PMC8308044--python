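"""A chain of complementary feature-groups and the certainty registry.

Stage 1 classifies with the petal pair; points landing in calibration
categories shared by several species are re-examined with the sepal pair.
The registry marks each observed pattern-category certain (one true label
ever seen there) or uncertain, and any external classifier's decision can
be dissected against it.
"""

from sklearn.model_selection import train_test_split

from ceda import build_registry, chain_predict_table, classify_ml_decision, load_iris_fixture
from ceda.chain import PatternCategory

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _helpers import fit_stage  # noqa: E402

iris = load_iris_fixture()
train, test = train_test_split(iris, test_size=0.2, random_state=0, stratify=iris["species"])
test = test.reset_index(drop=True)
y = test["species"].to_numpy()

petal_stage = fit_stage(train, ["petal_length", "petal_width"], seed=10, label_column="species")
sepal_stage = fit_stage(train, ["sepal_length", "sepal_width"], seed=11, label_column="species")

stages = [petal_stage, sepal_stage]
registry = build_registry(stages, test, y)
print("pattern-category registry (calibration = the held-out 20%):")
print(registry.to_frame().to_string(index=False))

table = chain_predict_table(test, y, stages, registry)
print("\nterminal pattern-categories x true species:")
print(table.to_string())

# Dissect a hypothetical external classifier call: suppose it labels a
# point in the first uncertain category as 'virginica'.
for key, entry in registry.items():
    if entry.status == "uncertain":
        case = classify_ml_decision("virginica", PatternCategory(key), registry)
        print(f"\nML says 'virginica' in category {PatternCategory(key)}: {case}")
        break
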