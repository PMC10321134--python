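"""Class-imbalance resamplers: random over/under-sampling, SMOTE, ENN.

SMOTE synthesizes minority points as convex combinations p + u(q - p) of
a minority sample p and one of its k same-class Euclidean nearest
neighbors q, u ~ Uniform(0,1), until every class matches the majority
count.  ENN removes every sample whose own label is beaten in the vote of
its k nearest neighbors on the full set (votes computed once, on the
pre-edit set).  SMOTEENN composes the two: oversample, then clean the
class-overlap boundary.  All resamplers operate on the encoded,
standardized representation and are meant for training rows only;
original rows are never modified, only duplicated or removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class ResampleResult:
    X: np.ndarray
    y: np.ndarray
    counts_before: dict
    counts_after: dict
    provenance: np.ndarray  # per surviving row: "original" | "synthetic"
    removed_indices: np.ndarray | None = None

    def counts_json(self) -> dict:
        return {"before": self.counts_before, "after": self.counts_after}


def _class_counts(y: np.ndarray) -> dict:
    vals, counts = np.unique(y, return_counts=True)
    return {str(v): int(c) for v, c in zip(vals, counts)}


def _check(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    if len(np.unique(y)) < 2:
        raise ValueError("resampling requires at least 2 classes")
    return X, y


def _knn_indices(X: np.ndarray, query: np.ndarray, k: int) -> np.ndarray:
    """k nearest rows of X per query row, self-matches included.

    Distance ties break by sample index order (stable argsort), keeping
    every downstream vote and interpolation choice deterministic.
    """
    d = cdist(query, X)
    return np.argsort(d, axis=1, kind="stable")[:, :k]


def random_oversample(X, y, seed: int = 0) -> ResampleResult:
    """Duplicate minority rows with replacement up to the majority count."""
    X, y = _check(X, y)
    rng = np.random.default_rng(seed)
    before = _class_counts(y)
    target = max(before.values())
    keep_X, keep_y, prov = [X], [y], [np.full(len(y), "original")]
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        extra = target - members.size
        if extra > 0:
            picks = rng.choice(members, size=extra, replace=True)
            keep_X.append(X[picks])
            keep_y.append(y[picks])
            prov.append(np.full(extra, "synthetic"))
    Xr, yr = np.concatenate(keep_X), np.concatenate(keep_y)
    return ResampleResult(Xr, yr, before, _class_counts(yr), np.concatenate(prov))


def random_undersample(X, y, seed: int = 0) -> ResampleResult:
    """Remove majority rows without replacement down to the minority count."""
    X, y = _check(X, y)
    rng = np.random.default_rng(seed)
    before = _class_counts(y)
    target = min(before.values())
    keep = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        keep.append(np.sort(rng.choice(members, size=target, replace=False)))
    keep = np.sort(np.concatenate(keep))
    removed = np.setdiff1d(np.arange(len(y)), keep)
    return ResampleResult(
        X[keep], y[keep], before, _class_counts(y[keep]),
        np.full(keep.size, "original"), removed_indices=removed,
    )


def smote(X, y, k: int = 5, seed: int = 0) -> ResampleResult:
    """Interpolated minority oversampling to equal class counts.

    A class with fewer than k+1 members uses all its other members as the
    neighbor pool (k lowered per class); a singleton class is an error.
    """
    X, y = _check(X, y)
    rng = np.random.default_rng(seed)
    before = _class_counts(y)
    target = max(before.values())
    keep_X, keep_y, prov = [X], [y], [np.full(len(y), "original")]
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        extra = target - members.size
        if extra == 0:
            continue
        if members.size < 2:
            raise ValueError(f"class {cls} has a single member; SMOTE needs >= 2")
        k_cls = min(k, members.size - 1)
        nbrs = _knn_indices(X[members], X[members], k_cls + 1)  # col 0 = self
        synth = np.empty((extra, X.shape[1]))
        for j in range(extra):
            p_local = rng.integers(members.size)
            q_local = nbrs[p_local, 1 + rng.integers(k_cls)]
            u = rng.random()
            synth[j] = X[members[p_local]] + u * (X[members[q_local]] - X[members[p_local]])
        keep_X.append(synth)
        keep_y.append(np.full(extra, cls, dtype=y.dtype))
        prov.append(np.full(extra, "synthetic"))
    Xr, yr = np.concatenate(keep_X), np.concatenate(keep_y)
    return ResampleResult(Xr, yr, before, _class_counts(yr), np.concatenate(prov))


def enn(X, y, k: int = 3) -> ResampleResult:
    """Edited nearest neighbours: drop samples that lose their k-NN vote.

    A sample is removed when some other class receives strictly more of
    its k neighbors' votes than the sample's own class (self excluded);
    a tie with the own class keeps the sample.  Votes are computed once
    on the input set — survivors are not re-voted.
    """
    X, y = _check(X, y)
    if len(y) <= k:
        raise ValueError("need more than k samples for an ENN vote")
    before = _class_counts(y)
    nbrs = _knn_indices(X, X, k + 1)[:, 1:]
    classes = np.unique(y)
    keep = np.ones(len(y), dtype=bool)
    for i in range(len(y)):
        votes = {c: int(np.sum(y[nbrs[i]] == c)) for c in classes}
        own = votes[y[i]]
        if any(v > own for c, v in votes.items() if c != y[i]):
            keep[i] = False
    removed = np.flatnonzero(~keep)
    return ResampleResult(
        X[keep], y[keep], before, _class_counts(y[keep]),
        np.full(int(keep.sum()), "original"), removed_indices=removed,
    )


def smoteenn(X, y, k_smote: int = 5, k_enn: int = 3, seed: int = 0) -> ResampleResult:
    """SMOTE oversampling followed by one ENN cleaning pass."""
    sm = smote(X, y, k=k_smote, seed=seed)
    cleaned = enn(sm.X, sm.y, k=k_enn)
    survivors = np.setdiff1d(np.arange(len(sm.y)), cleaned.removed_indices)
    return ResampleResult(
        cleaned.X, cleaned.y, sm.counts_before, cleaned.counts_after,
        sm.provenance[survivors], removed_indices=cleaned.removed_indices,
    )


RESAMPLERS = {
    "random_over": random_oversample,
    "random_under": random_undersample,
    "smote": smote,
    "smoteenn": smoteenn,
}
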