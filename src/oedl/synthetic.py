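"""Seed-reproducible synthetic clinical + radiomics-style tabular data.

Emulates the statistical shape of a three-class stroke-prognosis cohort:
imbalanced classes (default proportions 106:289:46), a small block of
mixed categorical/continuous clinical features, and a wide block of
continuous radiomics-like features containing a minority of informative
features, correlated redundant copies, and pure noise.  Continuous
features are class-conditional Gaussians; categorical features are
class-conditional multinomials; missingness is MCAR and restricted to
continuous clinical features.

Nothing here touches images: radiomics features are emulated only as a
wide correlated numeric block, which is all the downstream pipeline sees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CLASSES, FeatureTable

# fraction of clinical features drawn as categorical history-style variables
_CAT_FRACTION = 0.6


@dataclass
class SynthConfig:
    n_samples: int = 441
    class_props: tuple[float, float, float] = (106.0, 289.0, 46.0)
    n_clinical: int = 17
    n_radiomics: int = 200
    n_informative_clinical: int = 5
    n_informative_radiomics: int = 10
    n_redundant_blocks: int = 4
    block_size: int = 5
    block_corr: float = 0.9
    missing_rate: float = 0.0
    effect_size: float = 1.1
    seed: int = 0

    def validate(self) -> None:
        props = np.asarray(self.class_props, dtype=float)
        if len(props) != 3 or (props < 0).any() or props.sum() <= 0:
            raise ValueError("class_props must be 3 nonnegative weights with positive sum")
        if self.n_informative_clinical > self.n_clinical:
            raise ValueError("n_informative_clinical exceeds n_clinical")
        if self.n_informative_radiomics > self.n_radiomics:
            raise ValueError("n_informative_radiomics exceeds n_radiomics")
        if not (0 <= self.block_corr < 1):
            raise ValueError("block_corr must lie in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_redundant_blocks * self.block_size > self.n_radiomics - self.n_informative_radiomics:
            raise ValueError("redundant blocks do not fit in the radiomics budget")


@dataclass
class GroundTruth:
    """What the generator planted: the answer key for recovery checks."""

    informative_clinical: list[str]
    informative_radiomics: list[str]
    class_assignment: pd.Series
    block_members: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "informative_clinical": self.informative_clinical,
            "informative_radiomics": self.informative_radiomics,
            "class_assignment": self.class_assignment.tolist(),
            "block_members": self.block_members,
        }


def largest_remainder_counts(n: int, weights) -> np.ndarray:
    """Apportion n into integer counts proportional to weights.

    Floors the exact quotas, then hands the leftover units to the classes
    with the largest fractional remainders (ties broken by class order).
    """
    w = np.asarray(weights, dtype=float)
    quotas = n * w / w.sum()
    counts = np.floor(quotas).astype(int)
    remainder = quotas - counts
    short = n - counts.sum()
    # stable sort => ties resolved by class order A < B < C
    for idx in np.argsort(-remainder, kind="stable")[:short]:
        counts[idx] += 1
    return counts


def _class_vector(cfg: SynthConfig) -> np.ndarray:
    counts = largest_remainder_counts(cfg.n_samples, cfg.class_props)
    for i, c in enumerate(counts):
        if c == 0:
            raise ValueError(f"class {CLASSES[i]} has expected count 0 under these proportions")
    return np.repeat(np.arange(3), counts)


def _noise_sd_for_corr(rho: float) -> float:
    """SD of additive N(0,1)-independent noise giving Pearson r = rho with the base."""
    if rho == 0:
        return 1e6
    return float(np.sqrt(1.0 / rho**2 - 1.0))


# ordinal class geometry: outcome bands are ordered severity strata, so
# informative features shift monotonically with class; the severe band (C)
# sits closer to B than B sits to A, making the small C class the one that
# suffers minority neglect without balancing
_CLASS_POSITIONS = np.array([0.0, 1.0, 1.75])


def _offset_pattern(i: int) -> np.ndarray:
    """Per-feature signed ordinal class-mean offsets, centered."""
    pos = _CLASS_POSITIONS - _CLASS_POSITIONS.mean()
    return pos if i % 2 == 0 else -pos


def _tilted_multinomial(n_levels: int, offsets: np.ndarray, strength: float) -> np.ndarray:
    """Class-conditional level probabilities for an informative categorical.

    Each class tilts the uniform distribution toward a different level,
    with tilt magnitude controlled by the effect size.
    """
    probs = np.full((3, n_levels), 1.0 / n_levels)
    for c in range(3):
        lvl = int((offsets[c] + 1)) % n_levels
        probs[c, lvl] += strength
    return probs / probs.sum(axis=1, keepdims=True)


def generate_dataset(cfg: SynthConfig) -> tuple[FeatureTable, pd.Series, GroundTruth]:
    """Generate one cohort: feature table, labels, and planted ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    y = _class_vector(cfg)
    n = cfg.n_samples

    names: list[str] = []
    modality: list[str] = []
    kind: list[str] = []
    columns: list[np.ndarray] = []

    # --- clinical block: categorical history variables + continuous labs
    n_cat = int(round(_CAT_FRACTION * cfg.n_clinical))
    n_cont = cfg.n_clinical - n_cat
    # informative slots go to continuous features first, then categorical
    info_cont = min(cfg.n_informative_clinical, n_cont)
    info_cat = cfg.n_informative_clinical - info_cont
    informative_clinical: list[str] = []

    for i in range(n_cont):
        name = f"clin_cont_{i:02d}"
        if i < info_cont:
            offs = _offset_pattern(i) * cfg.effect_size
            col = rng.normal(offs[y], 1.0)
            informative_clinical.append(name)
        else:
            col = rng.normal(0.0, 1.0, size=n)
        names.append(name)
        modality.append("clinical")
        kind.append("continuous")
        columns.append(col)

    for i in range(n_cat):
        name = f"clin_cat_{i:02d}"
        n_levels = 2 + (i % 3)  # levels cycle 2, 3, 4
        if i < info_cat:
            probs = _tilted_multinomial(n_levels, _offset_pattern(i), 0.35 * cfg.effect_size)
            col = np.array([rng.choice(n_levels, p=probs[c]) for c in y], dtype=float)
            informative_clinical.append(name)
        else:
            col = rng.integers(0, n_levels, size=n).astype(float)
        names.append(name)
        modality.append("clinical")
        kind.append("categorical")
        columns.append(col)

    # --- radiomics block: informative + redundant copies + pure noise
    informative_radiomics: list[str] = []
    info_cols: list[np.ndarray] = []
    for i in range(cfg.n_informative_radiomics):
        name = f"rad_info_{i:03d}"
        offs = _offset_pattern(i) * cfg.effect_size
        col = rng.normal(offs[y], 1.0)
        informative_radiomics.append(name)
        names.append(name)
        modality.append("radiomics")
        kind.append("continuous")
        columns.append(col)
        info_cols.append(col)

    block_members: dict[str, list[str]] = {}
    noise_sd = _noise_sd_for_corr(cfg.block_corr)
    n_block_feats = cfg.n_redundant_blocks * cfg.block_size
    for b in range(cfg.n_redundant_blocks):
        if info_cols:
            base = info_cols[b % len(info_cols)]
            base_name = informative_radiomics[b % len(info_cols)]
        else:
            base = rng.normal(0.0, 1.0, size=n)
            base_name = f"rad_blockbase_{b:02d}"
            names.append(base_name)
            modality.append("radiomics")
            kind.append("continuous")
            columns.append(base)
        members = [base_name]
        for j in range(cfg.block_size):
            name = f"rad_block{b:02d}_{j:02d}"
            col = base + rng.normal(0.0, noise_sd, size=n)
            names.append(name)
            modality.append("radiomics")
            kind.append("continuous")
            columns.append(col)
            members.append(name)
        block_members[f"block_{b:02d}"] = members

    n_noise = cfg.n_radiomics - cfg.n_informative_radiomics - n_block_feats
    for i in range(n_noise):
        names.append(f"rad_noise_{i:03d}")
        modality.append("radiomics")
        kind.append("continuous")
        columns.append(rng.normal(0.0, 1.0, size=n))

    data = pd.DataFrame(
        np.column_stack(columns),
        columns=names,
        index=pd.Index([f"s{i:04d}" for i in range(n)], name="sample_id"),
    )

    # MCAR missingness on clinical continuous cells only
    if cfg.missing_rate > 0:
        cont_clin = [nm for nm, m, k in zip(names, modality, kind) if m == "clinical" and k == "continuous"]
        for nm in cont_clin:
            mask = rng.random(n) < cfg.missing_rate
            data.loc[mask, nm] = np.nan

    meta = pd.DataFrame(
        {"modality": modality, "kind": kind}, index=pd.Index(names, name="feature")
    )
    table = FeatureTable(data, meta)
    labels = pd.Series(np.array(CLASSES)[y], index=data.index, name="nihss_group")
    truth = GroundTruth(informative_clinical, informative_radiomics, labels.copy(), block_members)
    return table, labels, truth


def generate_split_signal_dataset(cfg: SynthConfig) -> tuple[FeatureTable, pd.Series, GroundTruth]:
    """Cohort where neither modality alone separates all three classes.

    Clinical informative features shift only class A (B and C share a
    mean), radiomics informative features shift only class C (A and B
    share a mean): the A-vs-B boundary lives entirely in the clinical
    block and B-vs-C entirely in the radiomics block, so only the fused
    table supports near-perfect classification.
    """
    cfg.validate()
    if cfg.n_informative_clinical == 0 or cfg.n_informative_radiomics == 0:
        raise ValueError("split-signal design needs informative features in both modalities")
    table, labels, truth = generate_dataset(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    y = np.searchsorted(np.array(CLASSES), labels.to_numpy())
    n = cfg.n_samples

    clin_offsets = np.array([cfg.effect_size, 0.0, 0.0])  # A apart; B == C
    rad_offsets = np.array([0.0, 0.0, cfg.effect_size])  # C apart; A == B
    for name in truth.informative_clinical:
        if table.meta.loc[name, "kind"] == "continuous":
            col = rng.normal(clin_offsets[y], 1.0)
        else:
            n_levels = int(table.data[name].max()) + 1 if table.data[name].notna().any() else 2
            probs = _tilted_multinomial(n_levels, np.array([1.0, 0.0, 0.0]), 0.35 * cfg.effect_size)
            col = np.array([rng.choice(n_levels, p=probs[c]) for c in y], dtype=float)
        missing = table.data[name].isna()
        table.data[name] = col
        table.data.loc[missing, name] = np.nan
    rad_cols = {}
    for name in truth.informative_radiomics:
        rad_cols[name] = rng.normal(rad_offsets[y], 1.0)
        table.data[name] = rad_cols[name]
    # regenerate redundant copies so blocks track the new informative bases
    noise_sd = _noise_sd_for_corr(cfg.block_corr)
    for members in truth.block_members.values():
        base = table.data[members[0]].to_numpy()
        for name in members[1:]:
            table.data[name] = base + rng.normal(0.0, noise_sd, size=n)
    return table, labels, truth


# --- serialization ------------------------------------------------------


def export_csv(
    table: FeatureTable,
    labels: pd.Series,
    path: str | Path,
    truth: GroundTruth | None = None,
) -> None:
    """Write the table + labels to CSV with a metadata sidecar JSON."""
    path = Path(path)
    out = table.data.copy()
    out["nihss_group"] = labels.reindex(table.data.index)
    out.to_csv(path, float_format="%.10g")
    sidecar = {
        "features": {
            name: {"modality": row["modality"], "kind": row["kind"]}
            for name, row in table.meta.iterrows()
        }
    }
    if truth is not None:
        sidecar["ground_truth"] = truth.to_dict()
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def load_csv(path: str | Path) -> tuple[FeatureTable, pd.Series]:
    """Read a CSV written by :func:`export_csv` (sidecar JSON required)."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    labels = df.pop("nihss_group")
    df = df.astype(float)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    feats = sidecar["features"]
    meta = pd.DataFrame(
        {
            "modality": [feats[c]["modality"] for c in df.columns],
            "kind": [feats[c]["kind"] for c in df.columns],
        },
        index=pd.Index(df.columns, name="feature"),
    )
    return FeatureTable(df, meta), labels
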