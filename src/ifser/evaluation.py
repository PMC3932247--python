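"""Leave-one-out evaluation of rankings with off-the-shelf classifiers.

The harness estimates, for each candidate subset size k, the LOOCV accuracy
of a classifier trained on the top-k features.  By default the ranking is
recomputed inside every fold from the training samples only, so the held-out
sample can never influence which features are selected; a ``global`` mode
ranks once on the full data for comparability with studies that did so, at
the cost of selection leakage.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import ClassifierMixin
from sklearn.model_selection import LeaveOneOut
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .selector import ergs_rank, ifser_weights, select_top_k
from .stats_core import DEFAULT_GAMMA, LabeledMatrix

__all__ = ["CLASSIFIERS", "rank_features", "loocv_accuracy_grid"]

#: Name-keyed classifier factories. The classifiers themselves are standard
#: scikit-learn estimators; they are evaluation machinery, not part of the
#: ranking method.
CLASSIFIERS: dict[str, Callable[[], ClassifierMixin]] = {
    "nn": lambda: KNeighborsClassifier(n_neighbors=1),
    "tree": lambda: DecisionTreeClassifier(random_state=0),
    "svm": lambda: SVC(kernel="linear", random_state=0),
}


def rank_features(
    data: LabeledMatrix,
    method: str = "ifser",
    gamma: float = DEFAULT_GAMMA,
    **flags,
):
    """Dispatch to the requested ranking method."""
    if method == "ifser":
        return ifser_weights(data, gamma, **flags)
    if method == "ergs":
        return ergs_rank(data, gamma, mode=flags.get("mode", "sorted"), ddof=flags.get("ddof", 1))
    raise ValueError(f"unknown method {method!r}")


def loocv_accuracy_grid(
    data: LabeledMatrix,
    k_grid: Sequence[int],
    classifiers: Sequence[str] = ("nn",),
    method: str = "ifser",
    gamma: float = DEFAULT_GAMMA,
    ranking: str = "per-fold",
    **flags,
) -> pd.DataFrame:
    """LOOCV accuracy for every (classifier, k) combination.

    Returns a DataFrame with one row per classifier and one column per k,
    entries in percent.  ``ranking='per-fold'`` (default) recomputes feature
    weights on each training fold; ``'global'`` ranks once on all samples.
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid or k_grid[0] < 1 or k_grid[-1] > data.n_features:
        raise ValueError(f"k grid must lie within [1, {data.n_features}], got {k_grid}")
    unknown = [c for c in classifiers if c not in CLASSIFIERS]
    if unknown:
        raise ValueError(f"unknown classifiers {unknown}; available: {sorted(CLASSIFIERS)}")
    if ranking not in ("per-fold", "global"):
        raise ValueError(f"ranking must be 'per-fold' or 'global', got {ranking!r}")

    X, y = data.values, data.labels
    global_weights = rank_features(data, method, gamma, **flags) if ranking == "global" else None

    correct = {(c, k): 0 for c in classifiers for k in k_grid}
    n = data.n_samples
    for train_idx, test_idx in LeaveOneOut().split(X):
        if global_weights is None:
            fold = LabeledMatrix(
                values=X[train_idx], labels=y[train_idx], feature_names=data.feature_names
            )
            weights = rank_features(fold, method, gamma, **flags)
        else:
            weights = global_weights
        for k in k_grid:
            cols = select_top_k(weights, k)
            for c in classifiers:
                clf = CLASSIFIERS[c]()
                clf.fit(X[np.ix_(train_idx, cols)], y[train_idx])
                pred = clf.predict(X[np.ix_(test_idx, cols)])
                correct[(c, k)] += int(pred[0] == y[test_idx][0])

    table = pd.DataFrame(
        [[100.0 * correct[(c, k)] / n for k in k_grid] for c in classifiers],
        index=list(classifiers),
        columns=k_grid,
    )
    table.index.name = "classifier"
    table.columns.name = "k"
    return table
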