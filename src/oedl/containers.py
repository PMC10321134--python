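"""Core tabular containers shared by every pipeline stage.

A :class:`FeatureTable` is a samples x features grid (a pandas DataFrame
indexed by sample id) plus per-feature metadata: which modality a feature
came from (``clinical`` or ``radiomics``) and whether it is ``categorical``
or ``continuous``.  Missing cells are NaN.  Labels are a pandas Series of
prognosis classes ``A`` / ``B`` / ``C`` aligned to the same sample index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODALITIES = ("clinical", "radiomics")
KINDS = ("categorical", "continuous")
CLASSES = ("A", "B", "C")


@dataclass
class FeatureTable:
    """Rectangular feature store with per-feature modality/kind metadata.

    Parameters
    ----------
    data
        samples x features values; index holds unique sample ids, columns
        hold unique feature names.  Categorical cells are level codes
        (small non-negative integers) stored as floats so NaN can mark
        missingness.
    meta
        One row per feature (index = feature name) with columns
        ``modality`` and ``kind``; an optional ``parent`` column records
        the originating feature of one-hot indicator columns.
    """

    data: pd.DataFrame
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not self.data.columns.is_unique:
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        if not self.data.index.is_unique:
            raise ValueError("sample ids must be unique")
        if list(self.meta.index) != list(self.data.columns):
            raise ValueError("meta rows must match data columns, in order")
        bad_mod = set(self.meta["modality"]) - set(MODALITIES)
        bad_kind = set(self.meta["kind"]) - set(KINDS)
        if bad_mod or bad_kind:
            raise ValueError(f"invalid metadata values: {bad_mod | bad_kind}")

    # -- convenience accessors -------------------------------------------

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def features_where(self, modality: str | None = None, kind: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.meta.index)
        if modality is not None:
            mask &= self.meta["modality"] == modality
        if kind is not None:
            mask &= self.meta["kind"] == kind
        return list(self.meta.index[mask])

    def subset_features(self, names: list[str]) -> "FeatureTable":
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        return FeatureTable(self.data[names].copy(), self.meta.loc[names].copy())

    def subset_samples(self, ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[ids].copy(), self.meta.copy())

    def to_matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.meta.copy())


def make_feature_table(
    data: pd.DataFrame, modality: dict[str, str] | str, kind: dict[str, str] | str
) -> FeatureTable:
    """Build a FeatureTable, broadcasting scalar modality/kind to all columns."""
    cols = list(data.columns)
    if isinstance(modality, str):
        modality = {c: modality for c in cols}
    if isinstance(kind, str):
        kind = {c: kind for c in cols}
    meta = pd.DataFrame(
        {"modality": [modality[c] for c in cols], "kind": [kind[c] for c in cols]},
        index=pd.Index(cols, name="feature"),
    )
    return FeatureTable(data, meta)


def check_labels(labels: pd.Series, n_samples: int | None = None, require_all: bool = False) -> pd.Series:
    """Validate a label vector: values in {A,B,C}, optionally all present."""
    bad = set(labels.unique()) - set(CLASSES)
    if bad:
        raise ValueError(f"labels outside {CLASSES}: {sorted(bad)}")
    if n_samples is not None and len(labels) != n_samples:
        raise ValueError(f"label length {len(labels)} != sample count {n_samples}")
    if require_all and set(labels.unique()) != set(CLASSES):
        raise ValueError("all three classes A, B, C must be present")
    return labels


def labels_to_int(labels: pd.Series | np.ndarray) -> np.ndarray:
    """Map class letters to integer codes 0, 1, 2 (A<B<C order)."""
    arr = np.asarray(labels)
    codes = np.searchsorted(np.array(CLASSES), arr)
    if not np.all(np.array(CLASSES)[codes] == arr):
        raise ValueError("labels contain values outside A/B/C")
    return codes.astype(int)


def int_to_labels(codes: np.ndarray) -> np.ndarray:
    return np.array(CLASSES)[np.asarray(codes, dtype=int)]
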