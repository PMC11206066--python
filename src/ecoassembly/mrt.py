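"""Multivariate regression tree on a single numeric predictor (elevation).

Recursive binary splits minimise the within-node sum of squared deviations
of (transformed) community rows from node centroids.  With one numeric
predictor every subtree corresponds to a set of thresholds, i.e. a
partition of the predictor axis into intervals; subtree size k uses the
first k-1 thresholds in greedy (best-gain-first) order.  Tree size is
chosen by k-fold cross-validation with the 1-SE rule.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MRTModel", "grow_mrt", "prune_mrt", "assign_bands", "hellinger"]

_THREE_BAND_LABELS = ("LEG", "MEG", "HEG")


def hellinger(counts: np.ndarray) -> np.ndarray:
    """Hellinger transform: sqrt of per-sample proportions.

    *counts* is OTUs x samples; the result is samples x OTUs, ready to be
    used as a multivariate response.
    """
    counts = np.asarray(counts, dtype=float)
    props = counts / counts.sum(axis=0, keepdims=True)
    return np.sqrt(props).T


@dataclass
class MRTModel:
    """Fitted tree: ordered thresholds plus optional CV pruning table."""

    predictor_name: str
    thresholds_ordered: list[float]
    gains: list[float]
    chosen_size: int
    cv_table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def max_size(self) -> int:
        return len(self.thresholds_ordered) + 1

    def thresholds(self, size: int | None = None) -> np.ndarray:
        """Sorted thresholds of the subtree with *size* leaves."""
        if size is None:
            size = self.chosen_size
        if not (1 <= size <= self.max_size):
            raise ValueError(f"size must be in [1, {self.max_size}]")
        return np.sort(np.asarray(self.thresholds_ordered[: size - 1]))

    def leaf_of(self, x: np.ndarray, size: int | None = None) -> np.ndarray:
        """Leaf index (interval along the predictor) for each value of x."""
        return np.searchsorted(self.thresholds(size), np.asarray(x, dtype=float))


def _node_ss(q_total: float, c_total: np.ndarray, n: int) -> float:
    if n == 0:
        return 0.0
    return q_total - float(c_total @ c_total) / n


def _best_split(y: np.ndarray, x: np.ndarray, min_node: int) -> tuple[float, float] | None:
    """Best threshold and SS gain for one node; None if no legal split.

    Scans every midpoint between adjacent distinct predictor values; ties
    in gain are broken toward the lower threshold.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    n = len(xs)
    if n < 2 * min_node or xs[0] == xs[-1]:
        return None
    csum = np.cumsum(ys, axis=0)
    qsum = np.cumsum(np.square(ys).sum(axis=1))
    c_tot = csum[-1]
    q_tot = qsum[-1]
    parent_ss = _node_ss(q_tot, c_tot, n)
    best = None
    for k in range(min_node, n - min_node + 1):
        if xs[k - 1] == xs[k]:
            continue
        ss_left = _node_ss(qsum[k - 1], csum[k - 1], k)
        ss_right = _node_ss(q_tot - qsum[k - 1], c_tot - csum[k - 1], n - k)
        gain = parent_ss - ss_left - ss_right
        if best is None or gain > best[1] + 1e-12:
            best = (0.5 * (xs[k - 1] + xs[k]), gain)
    if best is None or best[1] <= 0.0:
        return None
    return best


def grow_mrt(
    community: np.ndarray,
    predictor: np.ndarray,
    predictor_name: str = "MEA",
    min_node: int = 5,
    max_depth: int = 4,
    max_leaves: int | None = None,
) -> MRTModel:
    """Grow a tree best-first: repeatedly split the node with largest gain.

    *community* is samples x features (already transformed), *predictor*
    one numeric value per sample.  A constant predictor yields a
    single-leaf model with a warning.
    """
    y = np.asarray(community, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.ndim != 2 or len(x) != y.shape[0]:
        raise ValueError("community must be samples x features aligned with predictor")
    if np.all(x == x[0]):
        warnings.warn("constant predictor: returning single-leaf tree")
        return MRTModel(predictor_name, [], [], chosen_size=1)
    if max_leaves is None:
        max_leaves = 2**max_depth

    thresholds: list[float] = []
    gains: list[float] = []
    # heap of (-gain, threshold, node sample indices, depth)
    heap: list[tuple[float, float, np.ndarray, int]] = []
    counter = 0  # tie-breaker so ndarrays are never compared

    def push(indices: np.ndarray, depth: int) -> None:
        nonlocal counter
        if depth >= max_depth:
            return
        found = _best_split(y[indices], x[indices], min_node)
        if found is not None:
            thr, gain = found
            heapq.heappush(heap, (-gain, thr, counter, indices, depth))
            counter += 1

    push(np.arange(len(x)), 0)
    while heap and len(thresholds) + 1 < max_leaves:
        neg_gain, thr, _, indices, depth = heapq.heappop(heap)
        thresholds.append(float(thr))
        gains.append(float(-neg_gain))
        left = indices[x[indices] <= thr]
        right = indices[x[indices] > thr]
        push(left, depth + 1)
        push(right, depth + 1)
    return MRTModel(predictor_name, thresholds, gains, chosen_size=len(thresholds) + 1)


def _subtree_sse(y_train, x_train, y_test, x_test, model: MRTModel, size: int) -> float:
    """Test SSE when test samples are assigned to training leaf centroids."""
    train_leaf = model.leaf_of(x_train, size)
    test_leaf = model.leaf_of(x_test, size)
    sse = 0.0
    for leaf in np.unique(test_leaf):
        in_train = train_leaf == leaf
        centroid = y_train[in_train].mean(axis=0) if in_train.any() else y_train.mean(axis=0)
        resid = y_test[test_leaf == leaf] - centroid
        sse += float(np.square(resid).sum())
    return sse


def prune_mrt(
    model: MRTModel,
    community: np.ndarray,
    predictor: np.ndarray,
    k_folds: int = 10,
    seed: int = 0,
    min_node: int = 5,
    max_depth: int = 4,
) -> MRTModel:
    """Choose tree size by k-fold CV with the 1-SE rule.

    The CV table reports, per size, the cross-validated error relative to
    the total sum of squares; the chosen size is the smallest whose error
    is within one standard error of the minimum.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    y = np.asarray(community, dtype=float)
    x = np.asarray(predictor, dtype=float)
    n = len(x)
    rng = np.random.default_rng(seed)
    fold_of = rng.permutation(np.arange(n) % k_folds)
    tss = float(np.square(y - y.mean(axis=0)).sum())
    if tss == 0.0:
        return MRTModel(model.predictor_name, [], [], chosen_size=1, cv_table=None)

    fold_models = []
    for f in range(k_folds):
        train = fold_of != f
        fold_models.append(
            grow_mrt(y[train], x[train], model.predictor_name, min_node, max_depth,
                     max_leaves=model.max_size)
        )
    max_common = min([model.max_size] + [fm.max_size for fm in fold_models])

    rows = []
    per_fold = np.zeros((max_common, k_folds))
    for f, fm in enumerate(fold_models):
        train = fold_of != f
        test = ~train
        for s in range(1, max_common + 1):
            per_fold[s - 1, f] = _subtree_sse(y[train], x[train], y[test], x[test], fm, s)
    for s in range(1, max_common + 1):
        xerror = per_fold[s - 1].sum() / tss
        scaled = per_fold[s - 1] * k_folds / tss
        se = float(np.std(scaled, ddof=1) / np.sqrt(k_folds)) if k_folds > 1 else 0.0
        rows.append({"size": s, "rel_error": xerror, "se": se})
    cv_table = pd.DataFrame(rows)
    best_idx = int(cv_table["rel_error"].idxmin())
    cutoff = cv_table.loc[best_idx, "rel_error"] + cv_table.loc[best_idx, "se"]
    chosen = int(cv_table.loc[cv_table["rel_error"] <= cutoff, "size"].min())
    return MRTModel(
        model.predictor_name,
        model.thresholds_ordered,
        model.gains,
        chosen_size=chosen,
        cv_table=cv_table,
    )


def assign_bands(
    model: MRTModel, predictor: np.ndarray, sample_ids: list[str] | None = None
) -> pd.Series:
    """Label each sample by its leaf, ordered by mean predictor value.

    Exactly 3 leaves get the LEG/MEG/HEG convention (ascending elevation);
    any other size gets L1..Lk with a warning that the 3-band convention
    does not apply.
    """
    x = np.asarray(predictor, dtype=float)
    leaves = model.leaf_of(x)
    k = model.chosen_size
    # leaf indices are intervals in ascending predictor order already
    if k == 3:
        labels = list(_THREE_BAND_LABELS)
    else:
        if k != 3:
            warnings.warn(f"{k} leaves: using generic labels (3-band convention not applicable)")
        labels = [f"L{i + 1}" for i in range(k)]
    out = pd.Series([labels[i] for i in leaves], index=sample_ids, name="band")
    return out
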