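"""Imputation, variance filtering, one-hot encoding, standardization, split.

The imputation stage fills each missing continuous cell with the average
over M repetitions of N-draw bootstrap means of the feature's observed
values (a repeated Monte-Carlo estimate of the feature mean); categorical
cells take the modal observed level.  Variance filtering keeps continuous
features whose population variance exceeds a threshold (categoricals pass
unconditionally).  One-hot encoding expands every categorical feature
into its full set of indicator columns.  Standardization is a z-score fit
on training rows only.  The stratified split apportions each class by
largest-remainder rounding so train proportions match exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureTable, check_labels
from .synthetic import largest_remainder_counts


@dataclass
class ImputationConfig:
    """M repetitions of N bootstrap draws per missing continuous cell."""

    m_reps: int = 5
    n_draws: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_reps < 1 or self.n_draws < 1:
            raise ValueError("M and N must both be >= 1")


def impute_monte_carlo(
    table: FeatureTable, cfg: ImputationConfig | None = None, observed_rows=None
) -> FeatureTable:
    """Fill missing cells; observed cells are never modified.

    Continuous: each missing cell is independently replaced by the mean of
    M bootstrap-sample means (N draws with replacement from the observed
    values).  Categorical: modal observed level, smallest level on ties.
    When ``observed_rows`` is given (e.g. the training index), only those
    rows feed the observed pools, keeping test information out of fills.
    """
    cfg = cfg or ImputationConfig()
    out = table.copy()
    rng = np.random.default_rng(cfg.seed)
    for name in out.feature_names:
        col = out.data[name]
        missing = col.isna()
        if not missing.any():
            continue
        pool = col if observed_rows is None else col.loc[observed_rows]
        observed = pool[pool.notna()].to_numpy()
        if observed.size == 0:
            raise ValueError(f"feature {name!r} is fully missing; cannot impute")
        if out.meta.loc[name, "kind"] == "categorical":
            levels, counts = np.unique(observed, return_counts=True)
            fill = np.full(int(missing.sum()), levels[np.argmax(counts)])
        else:
            fill = np.empty(int(missing.sum()))
            for j in range(fill.size):
                rep_means = [
                    rng.choice(observed, size=cfg.n_draws, replace=True).mean()
                    for _ in range(cfg.m_reps)
                ]
                fill[j] = float(np.mean(rep_means))
        out.data.loc[missing, name] = fill
    return out


def variance_filter(table: FeatureTable, threshold: float) -> FeatureTable:
    """Drop continuous features with population variance <= threshold.

    Operates on raw (pre-standardization) values; categorical features are
    retained unconditionally and original column order is preserved.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    keep = []
    for name in table.feature_names:
        if table.meta.loc[name, "kind"] == "categorical":
            keep.append(name)
            continue
        var = float(np.var(table.data[name].dropna().to_numpy()))  # population (÷ n)
        if var > threshold:
            keep.append(name)
    return table.subset_features(keep)


def one_hot_encode(table: FeatureTable, level_map: dict[str, np.ndarray] | None = None
                   ) -> tuple[FeatureTable, dict[str, np.ndarray]]:
    """Expand each categorical feature into its full indicator columns.

    A feature with n observed levels becomes n columns ``<name>=<level>``;
    exactly one indicator is 1 per row.  Level sets come from ``level_map``
    (fitted on training rows) when given, else from the table itself.
    Returns the encoded table and the level map used.  A value outside the
    known level set raises.
    """
    fitted = level_map is None
    level_map = dict(level_map or {})
    names, modality, kind, parent, columns = [], [], [], [], []
    for name in table.feature_names:
        col = table.data[name].to_numpy()
        if table.meta.loc[name, "kind"] != "categorical":
            names.append(name)
            modality.append(table.meta.loc[name, "modality"])
            kind.append("continuous")
            parent.append(name)
            columns.append(col.astype(float))
            continue
        if fitted:
            level_map[name] = np.unique(col[~np.isnan(col)])
        levels = level_map[name]
        unseen = np.setdiff1d(col[~np.isnan(col)], levels)
        if unseen.size:
            raise ValueError(f"feature {name!r}: unseen level(s) {unseen.tolist()}")
        for lv in levels:
            names.append(f"{name}={int(lv)}")
            modality.append(table.meta.loc[name, "modality"])
            kind.append("continuous")  # indicators are numeric downstream
            parent.append(name)
            columns.append((col == lv).astype(float))
    data = pd.DataFrame(np.column_stack(columns), columns=names, index=table.data.index)
    meta = pd.DataFrame(
        {"modality": modality, "kind": kind, "parent": parent},
        index=pd.Index(names, name="feature"),
    )
    return FeatureTable(data, meta), level_map


@dataclass
class StandardizationParams:
    """Per-feature z-score parameters fitted on training rows."""

    mean: pd.Series
    sd: pd.Series

    def to_dict(self) -> dict:
        return {"mean": self.mean.to_dict(), "sd": self.sd.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationParams":
        return cls(pd.Series(d["mean"]), pd.Series(d["sd"]))


def fit_standardizer(table: FeatureTable, rows=None) -> StandardizationParams:
    """Fit per-feature mean and population SD on the given training rows."""
    data = table.data if rows is None else table.data.loc[rows]
    mean = data.mean()
    sd = pd.Series(np.std(data.to_numpy(dtype=float), axis=0), index=data.columns)
    zero = sd.index[sd == 0].tolist()
    if zero:
        raise ValueError(
            f"zero training SD for {zero}; run variance_filter before standardizing"
        )
    return StandardizationParams(mean, sd)


def apply_standardizer(params: StandardizationParams, table: FeatureTable) -> FeatureTable:
    out = table.copy()
    out.data = (out.data - params.mean) / params.sd
    return out


def stratified_split(
    labels: pd.Series, train_frac: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class largest-remainder train/test split; returns positional indices.

    Every class contributes exactly ``round_LR(train_frac * n_class)``
    training samples, so train class proportions match the cohort's to
    within rounding.  Classes are processed in label order A < B < C.
    """
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must lie in (0, 1)")
    check_labels(labels)
    rng = np.random.default_rng(seed)
    y = labels.to_numpy()
    train_idx, test_idx = [], []
    for cls in sorted(np.unique(y)):
        members = np.flatnonzero(y == cls)
        if members.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        # per-class largest-remainder apportionment between train and test
        n_train = int(largest_remainder_counts(members.size, [train_frac, 1 - train_frac])[0])
        perm = rng.permutation(members)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))
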