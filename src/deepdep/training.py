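"""Model training and selection over perturbed transcriptomes.

Pipeline: select the 1000 most variable genes across the perturbed training
profiles, scale features to [0, 1] (log2(x+1) then per-feature min-max), and
train a classifier per dependency label.  The default classifier is the
numpy feed-forward network of :mod:`deepdep.dnn` (SdA pretraining, momentum
SGD with elastic-net loss, patience early stopping).  Hyperparameters are
drawn at random from a grid (1000 trials at full scale); models are selected
by five-fold cross-validation: per fold, the best draw by validation AUC is
refit and evaluated on the untouched test fifth, and the mean test AUC of
the five best models summarises performance.  Random forest, SVM, naive
Bayes, and LDA are available behind the same scoring contract.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from . import dnn
from .dnn import EarlyStopConfig, Hyperparameters

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# feature selection and scaling

def select_features(profiles: pd.DataFrame, k: int = 1000) -> list[str]:
    """The ``k`` genes with the largest standard deviation across cases.

    ``profiles`` is cases x genes.  Ties break deterministically by gene-id
    order; with fewer than ``k`` genes, all are used with a warning.
    """
    sd = profiles.std(axis=0, ddof=0)
    if len(sd) <= k:
        if len(sd) < k:
            logger.warning("only %d genes available for %d requested features", len(sd), k)
        return sorted(profiles.columns)
    order = sorted(profiles.columns, key=lambda g: (-sd[g], g))
    return order[:k]


@dataclass
class UnitScaler:
    """log2(x+1) then per-feature min-max to [0, 1], frozen on training data."""

    features: list[str]
    lo: np.ndarray
    hi: np.ndarray

    def transform(self, profiles: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in profiles.columns]
        if missing:
            logger.warning("%d model feature(s) missing from input; scaled as 0", len(missing))
        X = np.zeros((len(profiles), len(self.features)))
        for j, f in enumerate(self.features):
            if f in profiles.columns:
                X[:, j] = np.log2(profiles[f].to_numpy(dtype=float) + 1.0)
        rng_ = self.hi - self.lo
        rng_safe = np.where(rng_ == 0, 1.0, rng_)
        X = (X - self.lo) / rng_safe
        X[:, rng_ == 0] = 0.0  # constant-on-training features map to 0
        return np.clip(X, 0.0, 1.0)


def fit_scaler(profiles: pd.DataFrame, features: list[str]) -> UnitScaler:
    logx = np.log2(profiles[features].to_numpy(dtype=float) + 1.0)
    return UnitScaler(features=list(features), lo=logx.min(axis=0), hi=logx.max(axis=0))


# ---------------------------------------------------------------------------
# hyperparameter grid

def default_grid() -> dict[str, list]:
    """The default random-search grid (93,312 combinations)."""
    return {
        "n_hidden_layers": [1, 2, 3],
        "hidden_nodes": [64, 128, 256, 512],
        "learning_rate": [0.5, 0.1, 0.05, 0.01, 0.005, 0.001, 0.0005, 0.0001],
        "momentum": [0.0, 0.5, 0.9],
        "batch_size": [32, 128, 512],
        "activation": ["relu", "sigmoid"],
        "init_scheme": ["uniform_scaled", "normal_scaled"],
        "l1": [0.0, 1e-5, 1e-3],
        "l2": [0.0, 1e-5, 1e-3],
        "dropout_rate": [0.0, 0.2, 0.5],
    }


def reduced_grid() -> dict[str, list]:
    """A small grid for desk-scale experiments and tests."""
    return {
        "n_hidden_layers": [1, 2],
        "hidden_nodes": [32, 64, 128],
        "learning_rate": [0.1, 0.05, 0.01],
        "momentum": [0.5, 0.9],
        "batch_size": [32, 128],
        "activation": ["relu", "sigmoid"],
        "init_scheme": ["uniform_scaled", "normal_scaled"],
        "l1": [0.0, 1e-5],
        "l2": [0.0, 1e-5],
        "dropout_rate": [0.0, 0.2],
    }


def grid_size(grid: dict[str, list]) -> int:
    """Number of hyperparameter combinations the grid spans."""
    n = 1
    for values in grid.values():
        n *= len(values)
    return n


def sample_hyperparameters(
    grid: dict[str, list], n_trials: int, rng: np.random.Generator
) -> list[Hyperparameters]:
    """Draw ``n_trials`` random combinations (the same node count per layer)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    draws = []
    for _ in range(n_trials):
        choice = {k: v[rng.integers(len(v))] for k, v in grid.items()}
        n_layers = int(choice.pop("n_hidden_layers"))
        nodes = int(choice.pop("hidden_nodes"))
        draws.append(Hyperparameters(hidden_nodes=(nodes,) * n_layers, **choice))
    return draws


# ---------------------------------------------------------------------------
# trained models

@dataclass
class TrainedModel:
    """A frozen classifier: feature list + scaler + parameters + fold AUCs."""

    kind: str  # "dnn" | "random_forest" | "svm" | "naive_bayes" | "lda"
    features: list[str]
    scaler: UnitScaler
    params: object  # dnn.NetworkParams or a fitted sklearn estimator
    hyperparameters: Optional[Hyperparameters] = None
    validation_auc: float = np.nan
    test_auc: float = np.nan

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        if self.kind == "dnn":
            return dnn.predict_proba(self.params, X, self.hyperparameters)
        return self.params.predict_proba(X)[:, 1]

    def score_profiles(self, profiles: pd.DataFrame) -> np.ndarray:
        return self.score_matrix(self.scaler.transform(profiles))


def predict_score(
    models: TrainedModel | Sequence[TrainedModel], profiles: pd.DataFrame
) -> np.ndarray:
    """Dependency prediction score in [0, 1].

    A single model returns its class probability; an ensemble (e.g. the five
    best cross-validation models) returns the unweighted mean.
    """
    if isinstance(models, TrainedModel):
        models = [models]
    scores = np.stack([m.score_profiles(profiles) for m in models])
    return scores.mean(axis=0)


# ---------------------------------------------------------------------------
# cross-validated random search

def make_folds(
    y: np.ndarray,
    n_folds: int,
    seed: int,
    groups: Optional[np.ndarray] = None,
) -> list[np.ndarray]:
    """Stratified, seed-reproducible, disjoint and exhaustive fold assignment.

    Stratification is by label, and additionally within ``groups`` (e.g. the
    cell line each instance came from) when given, so every partition sees
    each cell line's dependency rate; this keeps per-cell-line class
    composition comparable across training, validation, and test splits.
    """
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    if groups is None:
        strata = [np.flatnonzero(y == cls) for cls in np.unique(y)]
    else:
        groups = np.asarray(groups)
        strata = [
            np.flatnonzero((y == cls) & (groups == g))
            for cls in np.unique(y)
            for g in pd.unique(groups)
        ]
    offset = 0
    for idx in strata:
        if len(idx) == 0:
            continue
        idx = idx.copy()
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[(offset + i) % n_folds].append(j)
        offset += len(idx)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _fit_dnn(
    X: np.ndarray,
    y: np.ndarray,
    hp: Hyperparameters,
    seed: int,
    stop: EarlyStopConfig,
    pretrain_epochs: int,
    groups: Optional[np.ndarray] = None,
) -> dnn.NetworkParams:
    if pretrain_epochs > 0:
        params0 = dnn.pretrain_sda(X, hp, seed=seed, epochs=pretrain_epochs)
    else:
        params0 = dnn.init_params(X.shape[1], hp, np.random.default_rng(seed))
    return dnn.finetune(params0, X, y, hp, seed=seed, stop=stop, groups=groups).params


@dataclass
class CVResult:
    models: list[TrainedModel]
    fold_test_aucs: list[float]

    @property
    def mean_test_auc(self) -> float:
        return float(np.mean(self.fold_test_aucs))


def cross_validated_search(
    profiles: pd.DataFrame,
    labels: np.ndarray,
    n_trials: int = 1000,
    n_folds: int = 5,
    seed: int = 0,
    grid: Optional[dict[str, list]] = None,
    n_features: int = 1000,
    stop: Optional[EarlyStopConfig] = None,
    pretrain_epochs: int = 15,
    validation_fraction: float = 0.2,
    groups: Optional[np.ndarray] = None,
) -> CVResult:
    """Random hyperparameter search under five-fold cross-validation.

    For each fold: the fold is the untouched test fifth; a validation split
    (one fifth of the rest) ranks the random draws by AUC; the best draw's
    model is evaluated on the test fold.  Returns the per-fold best models
    and their test AUCs.  All sampling is seeded.
    """
    if grid is None:
        grid = default_grid()
    y = np.asarray(labels, dtype=int)
    if min(np.bincount(y, minlength=2)) < n_folds:
        raise ValueError(f"need >= {n_folds} cases of each class")
    rng = np.random.default_rng(seed)
    draws = sample_hyperparameters(grid, n_trials, rng)

    features = select_features(profiles, k=n_features)
    scaler = fit_scaler(profiles, features)
    X = scaler.transform(profiles)
    if stop is None:
        stop = EarlyStopConfig()

    groups_arr = None if groups is None else np.asarray(groups)
    folds = make_folds(y, n_folds, seed, groups=groups_arr)
    models: list[TrainedModel] = []
    fold_test_aucs: list[float] = []
    for f, test_idx in enumerate(folds):
        rest = np.setdiff1d(np.arange(len(y)), test_idx)
        val_folds = make_folds(
            y[rest],
            int(round(1 / validation_fraction)),
            seed + 1000 + f,
            groups=None if groups_arr is None else groups_arr[rest],
        )
        val_idx = rest[val_folds[0]]
        train_idx = np.setdiff1d(rest, val_idx)
        best = None
        for t, hp in enumerate(draws):
            fit_seed = int((seed * 7919 + f * 101 + t) % (2**31))
            params = _fit_dnn(
                X[train_idx], y[train_idx], hp, fit_seed, stop, pretrain_epochs,
                groups=None if groups_arr is None else groups_arr[train_idx],
            )
            val_auc = roc_auc_score(y[val_idx], dnn.predict_proba(params, X[val_idx], hp))
            if best is None or val_auc > best[0]:
                best = (val_auc, hp, params)
        val_auc, hp, params = best
        test_auc = roc_auc_score(y[test_idx], dnn.predict_proba(params, X[test_idx], hp))
        models.append(
            TrainedModel(
                kind="dnn",
                features=features,
                scaler=scaler,
                params=params,
                hyperparameters=hp,
                validation_auc=float(val_auc),
                test_auc=float(test_auc),
            )
        )
        fold_test_aucs.append(float(test_auc))
        logger.info("fold %d: validation AUC %.3f, test AUC %.3f", f, val_auc, test_auc)
    return CVResult(models=models, fold_test_aucs=fold_test_aucs)


# ---------------------------------------------------------------------------
# alternate classifiers behind the same contract

def alternate_classifier(
    kind: str,
    profiles: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    n_features: int = 1000,
    kernel: str = "rbf",
    n_trees: int = 1000,
) -> TrainedModel:
    """Random forest / SVM / naive Bayes / LDA with the shared feature pipeline.

    RF uses 1000 trees; NBC and LDA use a class prior of 0.5 for both classes;
    SVM (C-classification) supports linear, polynomial, sigmoid, and radial
    kernels with Platt-scaled probabilities.
    """
    y = np.asarray(labels, dtype=int)
    features = select_features(profiles, k=n_features)
    scaler = fit_scaler(profiles, features)
    X = scaler.transform(profiles)
    if kind == "random_forest":
        est = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    elif kind == "svm":
        if kernel not in ("linear", "poly", "sigmoid", "rbf"):
            raise ValueError(f"unknown SVM kernel {kernel!r}")
        est = SVC(kernel=kernel, probability=True, random_state=seed)
    elif kind == "naive_bayes":
        est = GaussianNB(priors=[0.5, 0.5])
    elif kind == "lda":
        est = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    est.fit(X, y)
    return TrainedModel(kind=kind, features=features, scaler=scaler, params=est)
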