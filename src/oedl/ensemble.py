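"""Stacked generalization over the three deep base learners.

Out-of-fold stacking: the training set is split into T stratified folds;
for each base family, a model trained on the other T-1 folds predicts the
held-out fold, so every training row receives class probabilities from a
model that never saw it.  The concatenated probability blocks (3 classes
x 3 families = 9 columns) train a random-forest meta-learner.  At
inference the per-fold models score the new rows and their probabilities
are averaged per family, so the meta-learner sees test meta-features
drawn from the same fold-model distribution it was trained on.  Hard and
soft voting over independently trained base learners serve as simpler
baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import learners
from .learners import LearnerSpec, TrainedLearner


def stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold id per sample; class proportions preserved within +-1 per fold."""
    rng = np.random.default_rng(seed)
    fold_of = np.full(len(y), -1, dtype=int)
    for cls in np.unique(y):
        members = rng.permutation(np.flatnonzero(y == cls))
        for pos, idx in enumerate(members):
            fold_of[idx] = pos % n_folds
    return fold_of


@dataclass
class StackModel:
    specs: dict[str, LearnerSpec]
    fold_of: np.ndarray = field(repr=False)
    fold_models: dict[str, list[TrainedLearner]] = field(repr=False, default_factory=dict)
    meta: RandomForestClassifier = field(repr=False, default=None)
    meta_features_train: np.ndarray = field(repr=False, default=None)
    n_classes: int = 3

    def base_probabilities(self, X: np.ndarray) -> np.ndarray:
        """Per-family fold-model-averaged class probabilities, concatenated."""
        blocks = []
        for fam in sorted(self.specs):
            probs = np.mean([m.predict_proba(X) for m in self.fold_models[fam]], axis=0)
            blocks.append(probs)
        return np.hstack(blocks)


def stacking_fit(
    specs: dict[str, LearnerSpec] | list[LearnerSpec],
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    n_meta_trees: int = 100,
) -> StackModel:
    """Fit the stack: out-of-fold meta-features + random-forest meta-learner."""
    if isinstance(specs, list):
        specs = {s.family: s for s in specs}
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if n_folds < 2:
        raise ValueError("stacking needs at least 2 folds (no held-out fold otherwise)")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class ({counts.min()}) is below the fold count {n_folds}"
        )
    n_classes = int(y.max()) + 1
    fold_of = stratified_folds(y, n_folds, seed)
    blocks = []
    fold_models: dict[str, list[TrainedLearner]] = {}
    for fi, fam in enumerate(sorted(specs)):
        spec = specs[fam]
        oof = np.zeros((len(y), n_classes))
        fold_models[fam] = []
        for t in range(n_folds):
            held = fold_of == t
            model = learners.fit(spec, X[~held], y[~held], seed=seed + 1000 * fi + t,
                                 n_classes=n_classes)
            oof[held] = model.predict_proba(X[held])
            fold_models[fam].append(model)
        blocks.append(oof)
    meta_X = np.hstack(blocks)
    meta = RandomForestClassifier(n_estimators=n_meta_trees, random_state=seed)
    meta.fit(meta_X, y)
    return StackModel(specs, fold_of, fold_models, meta, meta_X, n_classes)


def stacking_predict(model: StackModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels + meta-learner class probabilities for new rows."""
    meta_X = model.base_probabilities(np.asarray(X, dtype=float))
    probs = model.meta.predict_proba(meta_X)
    # align to full class range in case the forest saw a label subset
    out = np.zeros((len(probs), model.n_classes))
    out[:, model.meta.classes_] = probs
    return out.argmax(axis=1), out


def hard_vote(predictions: list[np.ndarray]) -> np.ndarray:
    """Modal label across families; ties go to the lowest class code."""
    stacked = np.stack(predictions)  # (n_families, n)
    n_classes = int(stacked.max()) + 1
    votes = np.stack([(stacked == c).sum(axis=0) for c in range(n_classes)])
    return votes.argmax(axis=0)  # argmax takes the first (lowest) class on ties


def soft_vote(probabilities: list[np.ndarray]) -> np.ndarray:
    """Argmax of the unweighted mean of the families' probability rows."""
    return np.mean(np.stack(probabilities), axis=0).argmax(axis=1)
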