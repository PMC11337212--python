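"""Additive per-feature attribution for random-forest predictions.

Tree-path decomposition: walking a sample down each tree, the change in the
node value at every split is credited to the split feature.  Contributions
therefore sum exactly to (prediction - base value), where the base value is
the mean root value over trees.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor


def _node_value(tree, node: int, classifier: bool) -> float:
    v = tree.value[node][0]
    if classifier:
        s = v.sum()
        return float(v[1] / s) if s > 0 else 0.0
    return float(v[0])


def _tree_contributions(tree, x: np.ndarray, classifier: bool) -> tuple[float, np.ndarray]:
    contrib = np.zeros(x.shape[0])
    node = 0
    base = _node_value(tree, node, classifier)
    value = base
    while tree.children_left[node] != -1:
        feat = tree.feature[node]
        if x[feat] <= tree.threshold[node]:
            child = tree.children_left[node]
        else:
            child = tree.children_right[node]
        child_value = _node_value(tree, child, classifier)
        contrib[feat] += child_value - value
        value = child_value
        node = child
    return base, contrib


def forest_contributions(
    forest: RandomForestClassifier | RandomForestRegressor, x: np.ndarray
) -> tuple[float, np.ndarray]:
    """(base_value, per-feature contributions) for one sample.

    base + contributions.sum() equals predict_proba(x)[1] for classifiers
    (predict(x) for regressors) to floating-point accuracy.
    """
    x = np.asarray(x, dtype=np.float32)  # trees compare in float32
    classifier = isinstance(forest, RandomForestClassifier)
    bases = []
    total = np.zeros(x.shape[0])
    for est in forest.estimators_:
        b, c = _tree_contributions(est.tree_, x, classifier)
        bases.append(b)
        total += c
    n = len(forest.estimators_)
    return float(np.mean(bases)), total / n


__all__ = ["forest_contributions"]
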