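"""Contrast the original and improved selection algorithms.

The original algorithm stops outright the first time a provisionally
accepted gene significantly hurts validation accuracy (left-tailed paired
t-test) -- on noisy small-sample data that can happen almost immediately,
leaving good genes unexplored. The improved algorithm only discards the
offending candidate and keeps searching.
"""

import numpy as np

from igisplus import ClassifierSpec, LabeledExpressionMatrix, igis_original, igis_plus, make_folds

# small noisy dataset with one moderate gene: prone to early termination
rng = np.random.default_rng(49)
labels = np.repeat([0, 1], 12)
values = rng.standard_normal((24, 40))
values[:, 0] = labels * 1.2 + rng.standard_normal(24)
data = LabeledExpressionMatrix(values, [f"g{i}" for i in range(40)], labels)
folds = make_folds(labels, 4, seed=49)

clf = ClassifierSpec("knn")
orig = igis_original(data, None, clf, folds)
plus = igis_plus(data, None, clf, folds)

for name, res in (("original", orig), ("improved", plus)):
    print(f"{name:>9}: |S| = {len(res.selected)}, "
          f"wrapper evaluations = {res.wrapper_evaluations:3d}, "
          f"stop reason = {res.stop_reason}")
print("The improved search evaluates strictly more candidates because a "
      "validation drop discards one gene instead of ending the search.")
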