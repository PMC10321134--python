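"""Dual-booster importance ranking, union/top-k selection, correlation pruning.

Two gradient-boosting conventions score every feature: total split gain
under a leaf-wise tree grower (LightGBM) and split count ("weight") under
a second-order-expansion booster (XGBoost).  The selection rule keeps the
features the two methods agree on — the intersection of their top-50
lists — plus each method's top 10.  Survivors then pass a Pearson
correlation prune: scanning in descending importance, any candidate with
|r| > 0.9 against an already-kept feature is dropped, so the kept set
contains no highly collinear pair.  Clinical and radiomics selections are
finally fused by column-wise concatenation aligned on sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureTable, check_labels, labels_to_int

LEAFWISE_GAIN = "leafwise_gain"
SECONDORDER_WEIGHT = "secondorder_weight"


@dataclass
class ImportanceRanking:
    method: str
    scores: pd.Series  # index = feature name, nonnegative

    def __post_init__(self) -> None:
        if (self.scores < 0).any():
            raise ValueError("importance scores must be nonnegative")

    @property
    def order(self) -> list[str]:
        """Feature names in descending score order, ties by column order."""
        return list(self.scores.iloc[np.argsort(-self.scores.to_numpy(), kind="stable")].index)

    def top(self, k: int) -> list[str]:
        return self.order[:k]

    def rank_of(self) -> pd.Series:
        """1-based rank per feature (1 = most important)."""
        return pd.Series(np.arange(1, len(self.scores) + 1), index=self.order)


@dataclass
class SelectionResult:
    selected: list[str]
    provenance: dict[str, str] = field(default_factory=dict)
    dropped_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "provenance": self.provenance,
            "dropped_by_correlation": [
                {"dropped": a, "kept": b, "r": r} for a, b, r in self.dropped_pairs
            ],
        }


def rank_importance(
    table: FeatureTable, labels: pd.Series, method: str, seed: int = 0, n_estimators: int = 100
) -> ImportanceRanking:
    """Score every feature with the named booster's importance convention."""
    check_labels(labels, table.n_samples)
    if len(np.unique(labels)) < 2:
        raise ValueError("importance ranking requires at least 2 classes")
    if table.data.isna().any().any():
        raise ValueError("impute missing values before importance ranking")
    X = table.to_matrix()
    y = labels_to_int(labels.to_numpy())
    names = table.feature_names
    if method == LEAFWISE_GAIN:
        import lightgbm as lgb

        model = lgb.LGBMClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1,
            deterministic=True, force_row_wise=True, verbose=-1,
        )
        model.fit(X, y)
        scores = model.booster_.feature_importance(importance_type="gain")
    elif method == SECONDORDER_WEIGHT:
        import xgboost as xgb

        model = xgb.XGBClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1, verbosity=0,
        )
        model.fit(X, y)
        raw = model.get_booster().get_score(importance_type="weight")
        scores = np.array([raw.get(f"f{i}", 0.0) for i in range(len(names))])
    else:
        raise ValueError(f"unknown method {method!r}; use {LEAFWISE_GAIN} or {SECONDORDER_WEIGHT}")
    return ImportanceRanking(method, pd.Series(scores, index=names, dtype=float))


def select_union_topk(
    rank_a: ImportanceRanking, rank_b: ImportanceRanking, k_pool: int = 50, k_head: int = 10
) -> SelectionResult:
    """(top-k_pool(A) ∩ top-k_pool(B)) ∪ top-k_head(A) ∪ top-k_head(B).

    Provenance records how each feature entered; output order is by
    ascending mean rank across the two methods (most important first).
    """
    if k_head > k_pool:
        raise ValueError("k_head must not exceed k_pool")
    if set(rank_a.scores.index) != set(rank_b.scores.index):
        raise ValueError("rankings cover different feature sets")
    pool_a, pool_b = set(rank_a.top(k_pool)), set(rank_b.top(k_pool))
    head_a, head_b = rank_a.top(k_head), rank_b.top(k_head)
    provenance: dict[str, str] = {}
    for f in pool_a & pool_b:
        provenance[f] = "in_both_top50"
    for f in head_a:
        provenance.setdefault(f, "top10_methodA")
    for f in head_b:
        provenance.setdefault(f, "top10_methodB")
    mean_rank = (rank_a.rank_of() + rank_b.rank_of()) / 2.0
    selected = sorted(provenance, key=lambda f: (mean_rank[f], f))
    return SelectionResult(selected, provenance)


def prune_correlated(
    table: FeatureTable,
    candidates: list[str],
    ranking: ImportanceRanking,
    threshold: float = 0.9,
    seed: int | None = None,
) -> SelectionResult:
    """Greedy correlation prune of candidates in descending importance.

    Default is deterministic: the higher-importance member of a
    correlated pair is kept.  Passing a ``seed`` instead scans candidates
    in a seeded random order (so which member survives is random), for
    fidelity with protocols that retain an arbitrary member.
    """
    missing = [c for c in candidates if c not in table.data.columns]
    if missing:
        raise KeyError(f"candidates not in table: {missing}")
    sub = table.data[candidates].to_numpy(dtype=float)
    sds = sub.std(axis=0)
    constant = [c for c, s in zip(candidates, sds) if s == 0]
    if constant:
        raise ValueError(f"constant column(s) {constant}; run variance_filter first")
    corr = np.corrcoef(sub, rowvar=False).reshape(len(candidates), len(candidates))
    pos = {c: i for i, c in enumerate(candidates)}
    if seed is None:
        rank = ranking.rank_of()
        order = sorted(candidates, key=lambda f: (rank[f], f))
    else:
        order = list(np.random.default_rng(seed).permutation(candidates))
    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for cand in order:
        clash = None
        for k in kept:
            r = float(corr[pos[cand], pos[k]])
            if abs(r) > threshold:
                clash = (cand, k, r)
                break
        if clash is None:
            kept.append(cand)
        else:
            dropped.append(clash)
    kept_in_input_order = [c for c in candidates if c in set(kept)]
    return SelectionResult(kept_in_input_order, {c: "kept" for c in kept}, dropped)


def fuse_features(clinical: FeatureTable, radiomics: FeatureTable) -> FeatureTable:
    """Column-wise fusion of the two modality tables, aligned by sample id."""
    a, b = set(clinical.sample_ids), set(radiomics.sample_ids)
    if a != b:
        offenders = sorted((a - b) | (b - a))
        raise ValueError(f"sample id mismatch between modalities: {offenders[:10]}")
    rad = radiomics.data.loc[clinical.sample_ids]
    overlap = set(clinical.feature_names) & set(radiomics.feature_names)
    if overlap:
        raise ValueError(f"duplicate feature names across modalities: {sorted(overlap)}")
    data = pd.concat([clinical.data, rad], axis=1)
    meta = pd.concat([clinical.meta, radiomics.meta.loc[rad.columns]])
    return FeatureTable(data, meta)
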