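"""Rational dataset partitioning by sphere exclusion.

Training compounds are picked farthest-point-first in autoscaled
descriptor space; every unassigned compound within the exclusion radius
of a new training pick goes to the test set. The construction guarantees
mutual training-set dissimilarity (all pairwise distances exceed the
radius) while every test compound has a training neighbour within it.

The external validation set is carved out *before* splitting, at
quantile-spaced positions of the response so it spans the full
bioavailability range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Scaling:
    """Per-column mean/SD autoscaling fitted on one table."""

    columns: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.columns if c not in table.columns]
        if missing:
            raise ValueError(f"table lacks scaled columns {missing}")
        x = table[list(self.columns)].to_numpy(dtype=float)
        return (x - self.mean) / self.sd


def fit_scaling(table: pd.DataFrame, columns: list[str] | None = None) -> Scaling:
    """Zero-mean/unit-SD scaling; constant columns are dropped with a warning."""
    if columns is None:
        columns = [c for c in table.columns if np.issubdtype(table[c].dtype, np.number)]
    x = table[columns].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("descriptor table contains NaN cells")
    sd = x.std(axis=0, ddof=1) if len(x) > 1 else np.ones(x.shape[1])
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(columns, keep) if not k]
        logger.warning("dropping constant column(s) from the distance metric: %s", dropped)
    cols = tuple(c for c, k in zip(columns, keep) if k)
    return Scaling(columns=cols, mean=x.mean(axis=0)[keep], sd=sd[keep])


@dataclass(frozen=True)
class SplitResult:
    """Disjoint train/test/external id partitions plus the split geometry."""

    train_ids: tuple
    test_ids: tuple
    external_ids: tuple
    radius: float
    scaling: Scaling

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.test_ids), set(self.external_ids)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("split partitions are not disjoint")
        if self.radius <= 0:
            raise ValueError("exclusion radius must be positive")


def sphere_exclusion_split(
    table: pd.DataFrame,
    radius: float,
    seed: int = 0,
    columns: list[str] | None = None,
) -> SplitResult:
    """Partition a descriptor table into train/test by sphere exclusion.

    The first training pick is the point closest to the data centroid;
    thereafter the unassigned point farthest from the current training set
    is added, and unassigned points within ``radius`` of it are sent to
    the test set. Ties break on lowest row index, so the procedure is
    deterministic (``seed`` is accepted for interface symmetry only).
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if len(table) < 2:
        raise ValueError("need at least 2 rows to split")
    scaling = fit_scaling(table, columns)
    x = scaling.transform(table)
    n = len(x)
    ids = np.asarray(table.index)

    unassigned = np.ones(n, dtype=bool)
    train: list[int] = []
    test: list[int] = []

    centroid = x.mean(axis=0)
    d_cent = np.linalg.norm(x - centroid, axis=1)
    first = int(np.argmin(d_cent))  # argmin takes the lowest index on ties
    # min distance from each point to the current training set
    min_d = np.full(n, np.inf)
    current = first
    while True:
        train.append(current)
        unassigned[current] = False
        d_new = np.linalg.norm(x - x[current], axis=1)
        excluded = unassigned & (d_new <= radius)
        test.extend(np.flatnonzero(excluded).tolist())
        unassigned[excluded] = False
        np.minimum(min_d, d_new, out=min_d)
        if not unassigned.any():
            break
        cand = np.flatnonzero(unassigned)
        current = int(cand[np.argmax(min_d[cand])])

    return SplitResult(
        train_ids=tuple(ids[sorted(train)]),
        test_ids=tuple(ids[sorted(test)]),
        external_ids=(),
        radius=radius,
        scaling=scaling,
    )


def tune_radius(
    table: pd.DataFrame,
    target_train_fraction: float,
    tolerance: int = 3,
    columns: list[str] | None = None,
    max_steps: int = 60,
) -> tuple[float, SplitResult, bool]:
    """Bisect the exclusion radius until |train| hits the target size.

    Returns (radius, split, converged). Larger radii never enlarge the
    training set, which makes bisection valid.
    """
    if not 0 < target_train_fraction <= 1:
        raise ValueError("target_train_fraction must lie in (0, 1]")
    n = len(table)
    target = int(round(target_train_fraction * n))
    target = min(max(target, 1), n)

    lo, hi = 1e-6, 1.0
    # grow hi until the training set is at or below target size
    while len(sphere_exclusion_split(table, hi, columns=columns).train_ids) > target:
        hi *= 2.0
        if hi > 1e6:
            break
    best = None
    for _ in range(max_steps):
        mid = 0.5 * (lo + hi)
        split = sphere_exclusion_split(table, mid, columns=columns)
        size = len(split.train_ids)
        if best is None or abs(size - target) < abs(len(best.train_ids) - target):
            best = split
        if abs(size - target) <= tolerance:
            return mid, split, True
        if size > target:
            lo = mid
        else:
            hi = mid
    logger.warning(
        "radius tuning did not converge: best train size %d for target %d",
        len(best.train_ids), target,
    )
    return best.radius, best, False


def select_external_set(targets: pd.Series, k: int) -> list:
    """Pick k ids at quantile-spaced positions of the sorted response.

    Includes the minimum and maximum, so the external set spans the full
    observed range. Deterministic; duplicated response values still yield
    k distinct ids.
    """
    n = len(targets)
    if k <= 1:
        raise ValueError("external set needs k >= 2 to span the response range")
    if k >= n:
        raise ValueError(f"external set size {k} must be smaller than the dataset ({n})")
    order = targets.to_numpy(dtype=float).argsort(kind="stable")
    positions = np.round(np.linspace(0, n - 1, k)).astype(int)
    positions = sorted(set(positions.tolist()))
    # collisions from rounding: fill with unused neighbours
    used = set(positions)
    while len(positions) < k:
        for p in range(n):
            if p not in used:
                used.add(p)
                positions.append(p)
                break
    return [targets.index[order[p]] for p in sorted(positions[:k])]


def split_dataset(
    table: pd.DataFrame,
    target_col: str,
    train_fraction: float,
    n_external: int,
    seed: int = 0,
    tolerance: int = 3,
) -> SplitResult:
    """External-set selection followed by sphere-exclusion train/test split."""
    if target_col not in table.columns:
        raise ValueError(f"target column {target_col!r} missing from table")
    external = select_external_set(table[target_col], n_external)
    rest = table.drop(index=external)
    columns = [c for c in table.columns if c != target_col]
    radius, split, _ = tune_radius(rest[columns], train_fraction, tolerance=tolerance)
    return SplitResult(
        train_ids=split.train_ids,
        test_ids=split.test_ids,
        external_ids=tuple(external),
        radius=radius,
        scaling=split.scaling,
    )
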