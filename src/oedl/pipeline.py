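"""End-to-end orchestration: simulate -> preprocess -> select -> fuse ->
split -> balance -> fit -> evaluate, with a manifest sufficient to re-run
any configuration bit-identically.

Leakage policy: the stratified split happens first; imputation pools,
variance thresholds, booster importances, correlation pruning, level
sets, standardization moments, resampling, and the architecture search's
validation split all see training rows only.  A ``select_on_all`` fidelity
switch moves feature selection before the split (with a warning), for
protocols that screened features on the whole cohort.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import balance, bboa, ensemble, feature_select, learners, metrics, preprocess, synthetic
from .containers import FeatureTable, int_to_labels, labels_to_int
from .learners import FAMILIES, LearnerSpec
from .metrics import MetricReport

MODELS = (
    "dnn", "lstm_rnn", "dbn", "hard_vote", "soft_vote", "edl", "oedl",
    "reference:dt", "reference:svm", "reference:rf",
)
BALANCERS = ("none", "random_over", "random_under", "smote", "smoteenn",
             "delegated:adasyn", "delegated:borderline")

# epoch/learning-rate profiles: "full" is the method's reference training budget,
# "reduced" is the desk-scale profile used throughout the test suite
PROFILES = {
    "full": {"epochs": 1000, "lr": 1e-4, "search_epochs": 100, "search_batch": 20},
    "reduced": {"epochs": 150, "lr": 1e-3, "search_epochs": 40, "search_batch": 64},
}


@dataclass
class RunConfig:
    synth: synthetic.SynthConfig = field(default_factory=synthetic.SynthConfig)
    split_signal: bool = False
    input_csv: str | None = None  # overrides the generator when set
    feature_set: str = "joint"  # clinical | radiomics | joint
    balancing: str = "smoteenn"
    model: str = "edl"
    train_frac: float = 0.7
    seed: int = 0
    profile: str = "reduced"
    variance_threshold: float = 0.3
    corr_threshold: float = 0.9
    k_pool: int = 50
    k_head: int = 10
    n_folds: int = 5
    select_on_all: bool = False
    bboa_pop: int = 6
    bboa_iters: int = 6
    bboa_l_max: int = 3

    def validate(self) -> None:
        if self.feature_set not in ("clinical", "radiomics", "joint"):
            raise ValueError(f"unknown feature_set {self.feature_set!r}")
        if self.balancing not in BALANCERS:
            raise ValueError(f"unknown balancing {self.balancing!r}")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.balancing.startswith("delegated:"):
            raise NotImplementedError(
                f"{self.balancing} is a delegation slot for external resampling "
                "tooling and has no built-in implementation"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["synth"] = synthetic.SynthConfig(**{
            k: tuple(v) if k == "class_props" else v for k, v in d["synth"].items()
        })
        return cls(**d)


@dataclass
class RunManifest:
    config: dict
    report: MetricReport
    stage_timings: dict[str, float]
    best_specs: dict | None = None
    selection: dict | None = None
    balance_counts: dict | None = None
    test_index: list | None = None

    def to_dict(self) -> dict:
        out = {
            "config": self.config,
            "metrics": self.report.to_dict(),
            "stage_timings": self.stage_timings,
        }
        if self.best_specs is not None:
            out["best_specs"] = self.best_specs
        if self.selection is not None:
            out["selection"] = self.selection
        if self.balance_counts is not None:
            out["balance_counts"] = self.balance_counts
        if self.test_index is not None:
            out["test_index"] = self.test_index
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------


def _select_modality_features(
    table: FeatureTable, labels: pd.Series, rows, cfg: RunConfig
) -> tuple[dict, dict]:
    """Modality-specific selection funnels on the given (training) rows.

    Radiomics features pass variance filtering, the dual-booster union
    rule, and the correlation prune.  Clinical features pass only the
    correlation prune, ordered by booster importance.
    """
    train_labels = labels.loc[rows]
    out: dict[str, list[str]] = {}
    detail: dict[str, dict] = {}

    clin = table.subset_features(table.features_where(modality="clinical"))
    if clin.feature_names:
        rank_c = feature_select.rank_importance(
            clin.subset_samples(rows), train_labels, feature_select.LEAFWISE_GAIN, seed=cfg.seed
        )
        pruned = feature_select.prune_correlated(
            clin.subset_samples(rows), clin.feature_names, rank_c, cfg.corr_threshold
        )
        out["clinical"] = pruned.selected
        detail["clinical"] = pruned.to_dict()

    rad = table.subset_features(table.features_where(modality="radiomics"))
    if rad.feature_names:
        rad_kept = preprocess.variance_filter(rad.subset_samples(rows), cfg.variance_threshold)
        rad = rad.subset_features(rad_kept.feature_names)
        rank_a = feature_select.rank_importance(
            rad.subset_samples(rows), train_labels, feature_select.LEAFWISE_GAIN, seed=cfg.seed
        )
        rank_b = feature_select.rank_importance(
            rad.subset_samples(rows), train_labels, feature_select.SECONDORDER_WEIGHT, seed=cfg.seed
        )
        union = feature_select.select_union_topk(rank_a, rank_b, cfg.k_pool, cfg.k_head)
        pruned = feature_select.prune_correlated(
            rad.subset_samples(rows), union.selected, rank_a, cfg.corr_threshold
        )
        out["radiomics"] = pruned.selected
        detail["radiomics"] = {"union": union.to_dict(), "pruned": pruned.to_dict()}
    return out, detail


def _fit_reference(name: str, X, y, seed: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    if name == "dt":
        return DecisionTreeClassifier(random_state=seed).fit(X, y)
    if name == "svm":
        return SVC(probability=True, random_state=seed).fit(X, y)
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed).fit(X, y)
    raise ValueError(f"unknown reference model {name!r}")


def reference_models(name: str, X_train, y_train, X_test, y_test, seed: int = 0) -> MetricReport:
    """Shallow-learner comparison rows (decision tree, SVM, random forest)."""
    model = _fit_reference(name, X_train, y_train, seed)
    probs = model.predict_proba(X_test)
    full = np.zeros((len(X_test), 3))
    full[:, model.classes_] = probs
    pred = full.argmax(axis=1)
    return metrics.evaluate(int_to_labels(y_test), int_to_labels(pred), full)


def _inner_split(y: np.ndarray, frac: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    labels = pd.Series(int_to_labels(y))
    return preprocess.stratified_split(labels, frac, seed)


def _fit_predict(cfg: RunConfig, X_tr, y_tr, X_te, X_tr_raw=None, y_tr_raw=None
                 ) -> tuple[np.ndarray, np.ndarray, dict | None]:
    """Fit the configured model; returns (pred, probs, best_specs).

    ``X_tr``/``y_tr`` are the (possibly balanced) training rows every
    model trains on.  ``X_tr_raw``/``y_tr_raw`` are the pre-balancing
    training rows; the architecture search validates on a carve of these
    so that fitness is measured on real samples, never on synthetic
    resampled points.
    """
    prof = PROFILES[cfg.profile]
    specs = learners.default_specs(epochs=prof["epochs"], lr=prof["lr"])
    best_specs = None

    if cfg.model in FAMILIES:
        model = learners.fit(specs[cfg.model], X_tr, y_tr, seed=cfg.seed)
        probs = model.predict_proba(X_te)
        return probs.argmax(axis=1), probs, None

    if cfg.model.startswith("reference:"):
        name = cfg.model.split(":", 1)[1]
        ref = _fit_reference(name, X_tr, y_tr, cfg.seed)
        probs = np.zeros((len(X_te), 3))
        probs[:, ref.classes_] = ref.predict_proba(X_te)
        return probs.argmax(axis=1), probs, None

    if cfg.model in ("hard_vote", "soft_vote"):
        fam_probs, fam_preds = [], []
        for fi, fam in enumerate(sorted(specs)):
            m = learners.fit(specs[fam], X_tr, y_tr, seed=cfg.seed + fi)
            p = m.predict_proba(X_te)
            fam_probs.append(p)
            fam_preds.append(p.argmax(axis=1))
        if cfg.model == "hard_vote":
            pred = ensemble.hard_vote(fam_preds)
        else:
            pred = ensemble.soft_vote(fam_probs)
        return pred, np.mean(np.stack(fam_probs), axis=0), None

    if cfg.model == "oedl":
        # architecture search on an inner 80/20 stratified carve of the
        # pre-balancing training rows; the inner-train part is balanced
        # with the run's method, the validation part is left untouched
        if X_tr_raw is None:
            X_tr_raw, y_tr_raw = X_tr, y_tr
        tr_idx, val_idx = _inner_split(y_tr_raw, 0.8, cfg.seed + 77)
        X_in, y_in = X_tr_raw[tr_idx], y_tr_raw[tr_idx]
        if cfg.balancing != "none":
            res = balance.RESAMPLERS[cfg.balancing](X_in, y_in, seed=cfg.seed + 78)
            X_in, y_in = res.X, res.y
        search_cfg = bboa.BBOAConfig(
            dims=1 + cfg.bboa_l_max,
            lower=np.ones(1 + cfg.bboa_l_max),
            upper=np.array([cfg.bboa_l_max] + [learners.MAX_NEURONS] * cfg.bboa_l_max,
                           dtype=float),
            pop_size=cfg.bboa_pop,
            n_iter=cfg.bboa_iters,
            seed=cfg.seed,
        )
        found, _ = bboa.search_architecture(
            X_in, y_in, X_tr_raw[val_idx], y_tr_raw[val_idx],
            l_max=cfg.bboa_l_max, fit_epochs=prof["search_epochs"],
            cfg=search_cfg, seed=cfg.seed, lr=prof["lr"],
            batch_size=prof["search_batch"],
        )
        # final refit at the full profile budget and the reference batch size
        specs = {
            fam: replace(s, epochs=prof["epochs"], batch_size=20)
            for fam, s in found.items()
        }
        best_specs = {
            fam: {"n_hidden_layers": s.n_hidden_layers, "neurons": list(s.neurons)}
            for fam, s in specs.items()
        }

    stack = ensemble.stacking_fit(specs, X_tr, y_tr, n_folds=cfg.n_folds, seed=cfg.seed)
    pred, probs = ensemble.stacking_predict(stack, X_te)
    return pred, probs, best_specs


# ----------------------------------------------------------------------
# the run
# ----------------------------------------------------------------------


def run(cfg: RunConfig) -> RunManifest:
    cfg.validate()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    def mark(stage):
        nonlocal t0
        now = time.perf_counter()
        timings[stage] = round(now - t0, 3)
        t0 = now

    if cfg.input_csv:
        table, labels = synthetic.load_csv(cfg.input_csv)
    elif cfg.split_signal:
        table, labels, _ = synthetic.generate_split_signal_dataset(cfg.synth)
    else:
        table, labels, _ = synthetic.generate_dataset(cfg.synth)
    mark("data")

    train_idx, test_idx = preprocess.stratified_split(labels, cfg.train_frac, cfg.seed)
    train_ids = table.sample_ids[train_idx]
    mark("split")

    table = preprocess.impute_monte_carlo(
        table, preprocess.ImputationConfig(seed=cfg.seed), observed_rows=train_ids
    )
    mark("impute")

    if cfg.select_on_all:
        warnings.warn(
            "select_on_all=True: feature selection sees test rows; "
            "metrics may be optimistically biased",
            stacklevel=2,
        )
        selection_rows = table.sample_ids
    else:
        selection_rows = train_ids
    selected, selection_detail = _select_modality_features(table, labels, selection_rows, cfg)
    if cfg.feature_set == "joint":
        names = selected.get("clinical", []) + selected.get("radiomics", [])
    else:
        names = selected.get(cfg.feature_set, [])
    if not names:
        raise ValueError(f"no features survived selection for feature_set={cfg.feature_set!r}")
    table = table.subset_features(names)
    mark("select")

    encoded, _levels = preprocess.one_hot_encode(table)
    # z-score the genuinely continuous columns on training rows; indicator
    # columns stay 0/1 (they already live in [0, 1])
    cont = [n for n in encoded.feature_names if encoded.meta.loc[n, "parent"] == n]
    if cont:
        cont_table = encoded.subset_features(cont)
        params = preprocess.fit_standardizer(cont_table, rows=train_ids)
        std = preprocess.apply_standardizer(params, cont_table)
        encoded.data[cont] = std.data
    mark("encode_standardize")

    X = encoded.to_matrix()
    y = labels_to_int(labels.to_numpy())
    X_tr_raw, y_tr_raw = X[train_idx], y[train_idx]
    X_tr, y_tr = X_tr_raw, y_tr_raw
    X_te, y_te = X[test_idx], y[test_idx]
    balance_counts = None
    if cfg.balancing != "none":
        res = balance.RESAMPLERS[cfg.balancing](X_tr_raw, y_tr_raw, seed=cfg.seed)
        X_tr, y_tr = res.X, res.y
        balance_counts = res.counts_json()
    mark("balance")

    pred, probs, best_specs = _fit_predict(cfg, X_tr, y_tr, X_te, X_tr_raw, y_tr_raw)
    mark("fit")

    report = metrics.evaluate(int_to_labels(y_te), int_to_labels(pred), probs)
    mark("evaluate")

    return RunManifest(
        config=cfg.to_dict(),
        report=report,
        stage_timings=timings,
        best_specs=best_specs,
        selection=selection_detail,
        balance_counts=balance_counts,
        test_index=[int(i) for i in test_idx],
    )


def run_from_manifest(manifest: RunManifest | dict) -> RunManifest:
    """Re-execute the configuration recorded in a manifest."""
    d = manifest.to_dict() if isinstance(manifest, RunManifest) else manifest
    return run(RunConfig.from_dict(d["config"]))


def run_grid(configs: list[RunConfig]) -> pd.DataFrame:
    """Execute a config grid; long-format comparison table, one row per run."""
    rows = []
    for cfg in configs:
        manifest = run(cfg)
        r = manifest.report
        rows.append({
            "feature_set": cfg.feature_set,
            "balancing": cfg.balancing,
            "model": cfg.model,
            "seed": cfg.seed,
            "acc": r.acc,
            "macro_precision": r.macro_precision,
            "macro_recall": r.macro_recall,
            "macro_f1": r.macro_f1,
            "macro_auc": r.macro_auc,
            "test_index": tuple(manifest.test_index),
        })
    return pd.DataFrame(rows)
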