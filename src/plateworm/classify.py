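"""Strain classification protocol: hold-out, RFE, repeated CV, grid search.

The protocol keeps a strict train/test firewall: 20% of the wells of each
strain are held out up front; recursive feature elimination (random-forest
importances), candidate-size selection by repeated cross-validation, and
hyperparameter grid search all run on the training split only, and the
test split is touched exactly once, for the final accuracy.  Chance level
is 1/(number of strains).  An audit log records which samples each stage
consumed so the firewall is checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold

FULL_GRID = {
    "n_estimators": list(range(200, 2001, 200)),
    "max_features": [None, "sqrt"],  # None = all features ('auto' convention)
    "max_depth": list(range(10, 111, 10)) + [None],
    "min_samples_split": [2, 5, 10],
    "min_samples_leaf": [1, 2, 4],
}

FAST_GRID = {
    "n_estimators": [200, 500],
    "max_features": ["sqrt"],
    "max_depth": [10, None],
    "min_samples_split": [2],
    "min_samples_leaf": [1],
}


@dataclass
class ClassifierProtocolConfig:
    test_fraction: float = 0.20
    candidate_sizes: tuple = tuple(2 ** i for i in range(7, 12))  # 128..2048
    cv_folds: int = 4
    repeats: int = 20
    rfe_step: float = 0.1  # drop 10% of remaining features per iteration
    selection_estimators: int = 100  # RF size used inside RFE/scoring
    grid: dict = field(default_factory=lambda: {k: list(v) for k, v in FULL_GRID.items()})
    seed: int = 0

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @classmethod
    def fast(cls, **kw) -> "ClassifierProtocolConfig":
        """Reduced preset: fewer repeats/folds and a small grid."""
        kw.setdefault("repeats", 3)
        kw.setdefault("cv_folds", 3)
        kw.setdefault("selection_estimators", 50)
        kw.setdefault("grid", {k: list(v) for k, v in FAST_GRID.items()})
        return cls(**kw)


class UsageAudit:
    """Log of which sample ids each protocol stage consumed."""

    def __init__(self):
        self.records: list[tuple[str, frozenset]] = []

    def log(self, stage: str, ids) -> None:
        self.records.append((stage, frozenset(ids)))

    def used_by(self, stage_prefix: str) -> set:
        out: set = set()
        for stage, ids in self.records:
            if stage.startswith(stage_prefix):
                out |= ids
        return out

    def test_untouched(self, test_ids) -> bool:
        test = set(test_ids)
        selection = self.used_by("select") | self.used_by("tune")
        return not (selection & test)


@dataclass
class Split:
    train_idx: np.ndarray
    test_idx: np.ndarray
    audit: UsageAudit


def split_train_test(values: pd.DataFrame, labels: pd.Series,
                     config: ClassifierProtocolConfig) -> Split:
    """Per-strain stratified hold-out: round(test_fraction * n) wells to test."""
    labels = pd.Series(np.asarray(labels), index=values.index)
    rng = np.random.default_rng(config.seed)
    test_parts = []
    for strain, idx in labels.groupby(labels).groups.items():
        n = len(idx)
        if n < 5:
            raise ValueError(f"strain {strain!r} has only {n} samples (need >= 5)")
        n_test = int(np.floor(config.test_fraction * n + 0.5))  # round to nearest
        pick = rng.permutation(np.asarray(idx))[:n_test]
        test_parts.append(pick)
    test_idx = np.concatenate(test_parts)
    test_pos = values.index.get_indexer(test_idx)
    mask = np.ones(len(values), dtype=bool)
    mask[test_pos] = False
    audit = UsageAudit()
    audit.log("split:test", test_idx)
    audit.log("split:train", values.index[mask])
    return Split(train_idx=np.asarray(values.index[mask]), test_idx=test_idx, audit=audit)


@dataclass
class RfeResult:
    best_size: int
    selected_features: list
    cv_curve: pd.DataFrame  # index size, columns mean_accuracy / sd


def _rf(config: ClassifierProtocolConfig, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=config.selection_estimators,
                                  random_state=seed, n_jobs=1)


def rfe_cv_select(values: pd.DataFrame, labels: pd.Series,
                  config: ClassifierProtocolConfig,
                  audit: UsageAudit | None = None) -> RfeResult:
    """Choose the candidate feature-set size by repeated cross-validation.

    For each size: within each CV training fold, recursive feature
    elimination with random-forest importances selects the features and a
    forest trained on them is scored on the fold's held-out part; the
    process repeats with different fold seeds.  The best mean-accuracy
    size wins and its features are re-selected on the full training set.
    """
    X = values.to_numpy(dtype=float)
    y = np.asarray(labels)
    width = X.shape[1]
    sizes = [s for s in config.candidate_sizes if s <= width]
    skipped = [s for s in config.candidate_sizes if s > width]
    if skipped:
        import warnings
        warnings.warn(f"candidate sizes {skipped} exceed feature count {width}; skipped")
    if not sizes:
        raise ValueError("no candidate size fits the feature count")
    if audit is not None:
        audit.log("select:rfe_cv", values.index)

    rows = []
    for size in sizes:
        accs = []
        for rep in range(config.repeats):
            skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                                  random_state=config.seed + rep)
            for fold, (itr, ite) in enumerate(skf.split(X, y)):
                seed = config.seed + 1000 * rep + fold
                rfe = RFE(_rf(config, seed), n_features_to_select=size,
                          step=config.rfe_step)
                rfe.fit(X[itr], y[itr])
                clf = _rf(config, seed).fit(X[itr][:, rfe.support_], y[itr])
                accs.append(clf.score(X[ite][:, rfe.support_], y[ite]))
        rows.append({"size": size, "mean_accuracy": float(np.mean(accs)),
                     "sd": float(np.std(accs))})
    curve = pd.DataFrame(rows).set_index("size")
    best_size = int(curve["mean_accuracy"].idxmax())

    final = RFE(_rf(config, config.seed), n_features_to_select=best_size,
                step=config.rfe_step).fit(X, y)
    selected = list(values.columns[final.support_])
    return RfeResult(best_size=best_size, selected_features=selected, cv_curve=curve)


@dataclass
class EvalResult:
    best_params: dict
    test_accuracy: float
    confusion: np.ndarray
    chance: float
    classes: list


def tune_fit_evaluate(train_values: pd.DataFrame, train_labels: pd.Series,
                      test_values: pd.DataFrame, test_labels: pd.Series,
                      selected_features: list, config: ClassifierProtocolConfig,
                      audit: UsageAudit | None = None) -> EvalResult:
    """Grid-search CV on the training set, then a single test evaluation.

    The test split enters only here, after selection and tuning are
    finished; chance level is 1/(number of strains).
    """
    if audit is not None:
        audit.log("tune:grid_search", train_values.index)
    Xtr = train_values[selected_features].to_numpy(dtype=float)
    ytr = np.asarray(train_labels)
    grid = {k: [None if v == "auto" else v for v in vals]
            for k, vals in config.grid.items()}
    search = GridSearchCV(
        RandomForestClassifier(random_state=config.seed, n_jobs=1),
        grid, cv=StratifiedKFold(config.cv_folds, shuffle=True,
                                 random_state=config.seed),
        n_jobs=1, refit=True)
    search.fit(Xtr, ytr)
    if audit is not None:
        audit.log("evaluate:test", test_values.index)
    Xte = test_values[selected_features].to_numpy(dtype=float)
    yte = np.asarray(test_labels)
    pred = search.best_estimator_.predict(Xte)
    classes = sorted(set(ytr))
    return EvalResult(
        best_params=dict(search.best_params_),
        test_accuracy=float(accuracy_score(yte, pred)),
        confusion=confusion_matrix(yte, pred, labels=classes),
        chance=1.0 / len(classes),
        classes=classes,
    )


def run_protocol(values: pd.DataFrame, labels: pd.Series,
                 config: ClassifierProtocolConfig) -> tuple[RfeResult, EvalResult, Split]:
    """End-to-end protocol: split, RFE size selection, tune, final test."""
    split = split_train_test(values, labels, config)
    labels = pd.Series(np.asarray(labels), index=values.index)
    tr_v, tr_y = values.loc[split.train_idx], labels.loc[split.train_idx]
    te_v, te_y = values.loc[split.test_idx], labels.loc[split.test_idx]
    rfe = rfe_cv_select(tr_v, tr_y, config, audit=split.audit)
    result = tune_fit_evaluate(tr_v, tr_y, te_v, te_y, rfe.selected_features,
                               config, audit=split.audit)
    return rfe, result, split
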