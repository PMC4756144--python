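"""Mutual-information feature scoring: MaxRel and mRMR rankings.

Feature relevance is measured by the mutual information (MI) between a
feature and the class-label target vector c,

    I(x, y) = sum_{x,y} p(x, y) * log2[ p(x, y) / (p(x) p(y)) ]   [bits],

estimated by the plug-in rule on empirical joint frequencies after
discretizing continuous features.  The default discretization is the
three-state rule of the original mRMR program: values below
mean - t*sd map to state 0, within t*sd of the mean to state 1, above
mean + t*sd to state 2, with t = 1.

The MaxRel list ranks features by descending I(f, c).  The mRMR list is
built greedily: with Omega_s the already-selected set, each step picks
the remaining feature maximizing D - R where D = I(f, c) and
R = (1/|Omega_s|) * sum_{f_i in Omega_s} I(f, f_i); R = 0 when Omega_s
is empty, so the first mRMR feature is the first MaxRel feature.  Ties
are broken by the lower original feature index throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:
    from .dataset import InteractionDataset

__all__ = [
    "DiscretizationSpec",
    "RankedFeatureList",
    "discretize",
    "discretize_matrix",
    "mutual_information",
    "entropy",
    "maxrel_list",
    "mrmr_list",
]


@dataclass(frozen=True)
class DiscretizationSpec:
    """How continuous features are binned before MI estimation.

    mode="three-state-sigma" bins at mean +/- t*sd into 3 states;
    mode="quantile" uses 3 equal-frequency bins; mode="none" passes
    values through unchanged (they must already be categorical codes).
    """

    mode: str = "three-state-sigma"
    t: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("three-state-sigma", "quantile", "none"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if not (self.t > 0) or not np.isfinite(self.t):
            raise ValueError("t must be a positive finite real")


def discretize(values: np.ndarray, spec: DiscretizationSpec) -> np.ndarray:
    """Map a real vector to small-integer categorical states."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite value in input to discretize")
    if spec.mode == "none":
        return values.astype(np.int64)
    if spec.mode == "quantile":
        lo, hi = np.quantile(values, [1 / 3, 2 / 3])
        return np.digitize(values, [lo, hi], right=True).astype(np.int64)
    mean = values.mean()
    sd = values.std()  # population sd; constant input -> sd 0 -> all state 1
    lo, hi = mean - spec.t * sd, mean + spec.t * sd
    out = np.ones(values.shape, dtype=np.int64)
    out[values < lo] = 0
    out[values > hi] = 2
    return out


def discretize_matrix(X: np.ndarray, spec: DiscretizationSpec) -> np.ndarray:
    """Discretize each column of a sample x feature matrix."""
    return np.column_stack([discretize(X[:, j], spec) for j in range(X.shape[1])])


def _as_codes(v: np.ndarray) -> np.ndarray:
    return np.unique(np.asarray(v), return_inverse=True)[1]


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI estimate in bits between two categorical vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size == 0:
        raise ValueError("empty input")
    xc = _as_codes(x)
    yc = _as_codes(y)
    nx = int(xc.max()) + 1
    ny = int(yc.max()) + 1
    joint = np.bincount(xc * ny + yc, minlength=nx * ny).reshape(nx, ny) / x.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))
    return max(mi, 0.0)  # clip the tiny negative round-off


def entropy(x: np.ndarray) -> float:
    """Empirical Shannon entropy in bits of a categorical vector."""
    codes = _as_codes(np.asarray(x))
    p = np.bincount(codes) / codes.size
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


@dataclass(frozen=True)
class RankedFeatureList:
    """A permutation of feature indices with per-position scores.

    ``kind`` is "MaxRel" (scores = MI with the label, non-increasing) or
    "mRMR" (scores = D - R at the step each feature was selected).
    """

    kind: str
    order: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("MaxRel", "mRMR"):
            raise ValueError(f"kind must be MaxRel or mRMR, got {self.kind!r}")
        n = self.order.size
        if sorted(self.order.tolist()) != list(range(n)):
            raise ValueError("order must be a permutation of feature indices")
        if self.scores.size != n:
            raise ValueError("scores must align with order")

    def __len__(self) -> int:
        return int(self.order.size)

    def rank_of(self, feature_index: int) -> int:
        """0-based position of a feature in the list."""
        return int(np.flatnonzero(self.order == feature_index)[0])


def _relevance(Xd: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.array([mutual_information(Xd[:, j], y) for j in range(Xd.shape[1])])


def _check_dataset(X: np.ndarray, y: np.ndarray) -> None:
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need >= 2 samples and >= 1 feature")
    if y.shape[0] != X.shape[0]:
        raise ValueError("label vector length must match sample count")


def maxrel_list(
    dataset: "InteractionDataset | np.ndarray",
    spec: DiscretizationSpec = DiscretizationSpec(),
    y: np.ndarray | None = None,
) -> RankedFeatureList:
    """Rank features by descending MI with the class label (MaxRel).

    Accepts an :class:`~aptaselect.dataset.InteractionDataset` or a raw
    ``(X, y)`` pair.  Ties are broken by the lower original index.
    """
    X, y = _unpack(dataset, y)
    _check_dataset(X, y)
    Xd = discretize_matrix(X, spec)
    mi = _relevance(Xd, y)
    order = np.argsort(-mi, kind="stable")  # stable: ties keep lower index first
    return RankedFeatureList(kind="MaxRel", order=order, scores=mi[order])


def mrmr_list(
    dataset: "InteractionDataset | np.ndarray",
    spec: DiscretizationSpec = DiscretizationSpec(),
    y: np.ndarray | None = None,
) -> RankedFeatureList:
    """Greedy minimum-redundancy maximum-relevance ranking.

    Each step selects the remaining feature with maximum D - R; pairwise
    feature MIs are accumulated incrementally so each pair is computed
    once.
    """
    X, y = _unpack(dataset, y)
    _check_dataset(X, y)
    Xd = discretize_matrix(X, spec)
    n = Xd.shape[1]
    relevance = _relevance(Xd, y)
    remaining = np.arange(n)
    redundancy_sum = np.zeros(n)  # sum of MI(f, s) over selected s, per feature
    order = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    for step in range(n):
        if step == 0:
            crit = relevance[remaining]
        else:
            crit = relevance[remaining] - redundancy_sum[remaining] / step
        best = int(np.argmax(crit))  # first maximum -> lowest original index
        sel = int(remaining[best])
        order[step] = sel
        scores[step] = float(crit[best])
        remaining = np.delete(remaining, best)
        if remaining.size:
            sel_col = Xd[:, sel]
            for f in remaining:
                redundancy_sum[f] += mutual_information(Xd[:, f], sel_col)
    return RankedFeatureList(kind="mRMR", order=order, scores=scores)


def _unpack(dataset, y):
    if y is None:
        return np.asarray(dataset.X, dtype=float), np.asarray(dataset.y)
    return np.asarray(dataset, dtype=float), np.asarray(y)
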