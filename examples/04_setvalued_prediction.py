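"""Set-valued classification by descending the label-embedding tree.

Splits Iris 80/20 (stratified), trains the petal-pair LET classifier with
k* = 20 and the pseudo-likelihood band [0.65, 100/65], and prints the
predictive map: rows are observed predicted label-sets, columns true
species.
"""

from sklearn.model_selection import train_test_split

from ceda import (
    CompetitionConfig,
    LetClassifier,
    build_let,
    load_iris_fixture,
    predictive_map,
    relative_distance_matrix,
    triplet_competitions,
)

iris = load_iris_fixture()
petal = ["petal_length", "petal_width"]
train, test = train_test_split(iris, test_size=0.2, random_state=2, stratify=iris["species"])

clouds = {sp: g[petal].to_numpy() for sp, g in train.groupby("species")}
tree = build_let(relative_distance_matrix(triplet_competitions(clouds, n_rounds=1000, seed=2)))
clf = LetClassifier(clouds, tree, CompetitionConfig(k_star=20, cl=0.65, cu=100 / 65))

pm = predictive_map(test[petal].to_numpy(), test["species"].to_numpy(), clf)
print("predictive map (rows = predicted label-sets, columns = true species):")
print(pm.matrix.to_string())

# Setosa and versicolor resolve to correct singletons; a virginica point
# in the overlap region receives the honest set {versicolor, virginica}
# instead of a forced guess — the mixing geometry does not support a
# singleton there.  A query far from all training data would get the
# empty set (outlier).
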