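"""Absorption classifiers in the (AlogP, PSA) plane.

Two simple views of oral absorption: a bivariate-normal 95% confidence
ellipse fitted to the well-absorbed compounds (a point is called
well-absorbed when its squared Mahalanobis distance from the fitted mean
is at most the chi-square(2 df) quantile), and a single CART decision
tree grown with Gini impurity on the same two coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

WELL, POOR = "well", "poor"

#: %F threshold above which a compound is called well-absorbed
DEFAULT_WELL_THRESHOLD = 50.0


@dataclass(frozen=True)
class EllipseModel:
    """Bivariate confidence ellipse: mean, covariance, Mahalanobis cutoff."""

    mean: np.ndarray  # (2,) in (AlogP, PSA) units
    covariance: np.ndarray  # (2, 2)
    confidence: float
    threshold: float = field(init=False)  # chi2(2 df) quantile

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("covariance must be positive definite (non-collinear points)")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must lie in (0, 1)")
        object.__setattr__(self, "threshold", float(stats.chi2.ppf(self.confidence, df=2)))

    def mahalanobis_sq(self, points: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(points) - self.mean
        sol = np.linalg.solve(self.covariance, x.T)
        return np.einsum("ij,ji->i", x, sol)


def fit_ellipse(points: np.ndarray, confidence: float = 0.95) -> EllipseModel:
    """Fit the confidence ellipse of the well-absorbed cloud.

    ``points`` is an (n, 2) array of (AlogP, PSA) pairs; the model is the
    sample mean and covariance (n−1 denominator) with the chi-square
    cutoff at ``confidence``.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of (AlogP, PSA) points")
    if len(x) < 3:
        raise ValueError("need at least 3 points to fit an ellipse")
    return EllipseModel(mean=x.mean(axis=0), covariance=np.cov(x.T, ddof=1), confidence=confidence)


def ellipse_classify(model: EllipseModel, points: np.ndarray) -> np.ndarray:
    """well/poor labels; the ellipse boundary is inclusive (well)."""
    d2 = model.mahalanobis_sq(points)
    return np.where(d2 <= model.threshold, WELL, POOR)


def misclassification_rate(predicted: np.ndarray, labels: np.ndarray) -> float:
    predicted = np.asarray(predicted)
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("cannot score an empty label set")
    if predicted.shape != labels.shape:
        raise ValueError("prediction/label length mismatch")
    return float(np.mean(predicted != labels))


# ------------------------------------------------------------ decision tree

@dataclass
class TreeNode:
    feature: int | None = None  # None → leaf
    threshold: float | None = None
    left: "TreeNode | None" = None  # feature value <= threshold
    right: "TreeNode | None" = None
    label: str | None = None


@dataclass
class TreeModel:
    """A single CART classification tree over (AlogP, PSA)."""

    root: TreeNode
    max_depth: int
    min_leaf: int
    feature_names: tuple[str, ...] = ("alogp", "psa")


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p * p))


def _best_split(x: np.ndarray, y01: np.ndarray, min_leaf: int) -> tuple[int, float, float] | None:
    """Greedy Gini split; ties break on lower feature index, then lower threshold."""
    n, d = x.shape
    total = np.array([np.sum(y01 == 0), np.sum(y01 == 1)], dtype=float)
    parent = _gini(total)
    best = None  # (impurity decrease, feature, threshold)
    for f in range(d):
        order = np.argsort(x[:, f], kind="stable")
        xs, ys = x[order, f], y01[order]
        left = np.zeros(2)
        right = total.copy()
        for i in range(n - 1):
            left[ys[i]] += 1
            right[ys[i]] -= 1
            if xs[i] == xs[i + 1]:
                continue
            if (i + 1) < min_leaf or (n - i - 1) < min_leaf:
                continue
            thr = 0.5 * (xs[i] + xs[i + 1])
            gain = parent - ((i + 1) * _gini(left) + (n - i - 1) * _gini(right)) / n
            if best is None or gain > best[0] + 1e-12:
                best = (gain, f, thr)
    if best is None or best[0] <= 1e-12:
        return None
    return best[1], best[2], best[0]


def _grow(x: np.ndarray, y01: np.ndarray, depth: int, max_depth: int, min_leaf: int,
          classes: tuple[str, str]) -> TreeNode:
    majority = classes[int(np.sum(y01 == 1) > np.sum(y01 == 0))]
    if depth >= max_depth or len(y01) < 2 * min_leaf or len(np.unique(y01)) == 1:
        return TreeNode(label=majority)
    split = _best_split(x, y01, min_leaf)
    if split is None:
        return TreeNode(label=majority)
    f, thr, _ = split
    mask = x[:, f] <= thr
    return TreeNode(
        feature=f,
        threshold=thr,
        left=_grow(x[mask], y01[mask], depth + 1, max_depth, min_leaf, classes),
        right=_grow(x[~mask], y01[~mask], depth + 1, max_depth, min_leaf, classes),
    )


def fit_tree(
    points: np.ndarray,
    labels: np.ndarray,
    max_depth: int = 4,
    min_leaf: int = 5,
) -> TreeModel:
    """Grow a single CART tree (Gini impurity, midpoint thresholds).

    Single-class inputs yield a depth-0 majority leaf.
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    if len(x) != len(labels):
        raise ValueError("points/labels length mismatch")
    if len(x) < 2 * min_leaf:
        raise ValueError(f"need at least {2 * min_leaf} points for min_leaf={min_leaf}")
    classes = (POOR, WELL)
    y01 = np.array([1 if lab == WELL else 0 for lab in labels])
    root = _grow(x, y01, 0, max_depth, min_leaf, classes)
    return TreeModel(root=root, max_depth=max_depth, min_leaf=min_leaf)


def tree_classify(model: TreeModel, points: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(points, dtype=float))
    out = []
    for row in x:
        node = model.root
        while node.label is None:
            node = node.left if row[node.feature] <= node.threshold else node.right
        out.append(node.label)
    return np.array(out)


def labels_from_bioavailability(
    f_values: np.ndarray, well_threshold: float = DEFAULT_WELL_THRESHOLD
) -> np.ndarray:
    """Map %F values to well/poor labels at the configured cutoff."""
    return np.where(np.asarray(f_values, dtype=float) >= well_threshold, WELL, POOR)
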