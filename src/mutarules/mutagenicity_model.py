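"""Fingerprint featurization, base classifiers, and the stacked consensus model.

Molecules are featurized as MACCS keys (166 bits), RDKit path fingerprints
(2048 bits) or Morgan/ECFP fingerprints (radius 2, 1024 bits).  Base
classifiers (SVM, random forest, XGBoost, LightGBM, gradient boosting) are
tuned by grid search under stratified cross-validation, selecting on mean
AUC with sensitivity as the tie-break.  The consensus model stacks the base
classifiers' out-of-fold predicted probabilities into a feature matrix for a
logistic-regression meta-learner; the base models are then refitted on the
full training set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator, rdMolDescriptors
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

from .chem_io import LabeledDataset, POSITIVE

FINGERPRINT_BITS = {"maccs": 166, "rdk": 2048, "ecfp": 1024}

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)


def featurize(mol: Chem.Mol | str, kind: str) -> np.ndarray:
    """Deterministic binary fingerprint of the declared length.

    ``maccs``: RDKit MACCS keys with the unused bit 0 dropped (166 bits).
    ``rdk``: RDKit path-based fingerprint, 2048 bits.
    ``ecfp``: Morgan fingerprint, radius 2, 1024 bits.
    """
    if isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
        if mol is None:
            raise ValueError("unparseable SMILES")
    if kind == "maccs":
        bv = rdMolDescriptors.GetMACCSKeysFingerprint(mol)
        arr = np.zeros(167, dtype=np.uint8)
        for b in bv.GetOnBits():
            arr[b] = 1
        return arr[1:]
    if kind == "rdk":
        bv = Chem.RDKFingerprint(mol, fpSize=2048)
    elif kind == "ecfp":
        bv = _MORGAN.GetFingerprint(mol)
    else:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    arr = np.zeros(bv.GetNumBits(), dtype=np.uint8)
    for b in bv.GetOnBits():
        arr[b] = 1
    return arr


def featurize_many(smiles: Sequence[str], kind: str) -> np.ndarray:
    return np.vstack([featurize(s, kind) for s in smiles])


def dataset_arrays(dataset: LabeledDataset, kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Fingerprint matrix and 0/1 label vector (1 = Ames positive)."""
    X = featurize_many([r.smiles for r in dataset], kind)
    y = np.array([1 if r.label == POSITIVE else 0 for r in dataset], dtype=int)
    return X, y


# ---------------------------------------------------------------------------
# Base classifiers

# deliberately small grids; each value list is the documented default search
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm": {"C": [1.0, 10.0]},
    "rf": {"n_estimators": [200], "max_features": ["sqrt", 0.3]},
    "xgb": {"n_estimators": [200], "max_depth": [4, 6]},
    "lgb": {"n_estimators": [200], "num_leaves": [15, 31]},
    "gb": {"n_estimators": [200], "max_depth": [2, 3]},
}

# algorithm/fingerprint pairing of the default consensus roster
DEFAULT_ROSTER: tuple[tuple[str, str], ...] = (
    ("rf", "rdk"),
    ("svm", "ecfp"),
    ("lgb", "rdk"),
    ("xgb", "maccs"),
    ("gb", "maccs"),
)


def make_estimator(algorithm: str, params: Mapping | None = None, seed: int = 0):
    params = dict(params or {})
    if algorithm == "svm":
        return SVC(probability=True, random_state=seed, **params)
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "gb":
        return GradientBoostingClassifier(random_state=seed, **params)
    if algorithm == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            verbosity=0,
            **params,
        )
    if algorithm == "lgb":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class BaseClassifierSpec:
    """One algorithm/fingerprint combination with its search grid and, after
    training, the selected hyper-parameters, CV scores and fitted estimator."""

    algorithm: str
    fingerprint: str
    grid: dict[str, list] = field(default_factory=dict)
    best_params: dict = field(default_factory=dict)
    cv_auc: float | None = None
    cv_se: float | None = None
    fold_metrics: list[dict] = field(default_factory=list)
    estimator: object | None = None

    def __post_init__(self):
        if not self.grid:
            self.grid = dict(DEFAULT_GRIDS.get(self.algorithm, {}))

    @property
    def fitted(self) -> bool:
        return self.estimator is not None


def _grid_points(grid: Mapping[str, list]) -> list[dict]:
    if not grid:
        return [{}]
    keys = sorted(grid)
    return [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]


def train_base(
    dataset: LabeledDataset,
    spec: BaseClassifierSpec,
    folds: int = 5,
    seed: int = 0,
) -> BaseClassifierSpec:
    """Grid search maximizing mean CV AUC (ties broken by sensitivity).

    Returns the spec with per-fold metrics filled in and the winning
    estimator refitted on the full training set.
    """
    X, y = dataset_arrays(dataset, spec.fingerprint)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best: tuple[float, float] | None = None
    for params in _grid_points(spec.grid):
        aucs, ses, per_fold = [], [], []
        for train_idx, val_idx in cv.split(X, y):
            est = make_estimator(spec.algorithm, params, seed=seed)
            est.fit(X[train_idx], y[train_idx])
            prob = est.predict_proba(X[val_idx])[:, 1]
            pred = (prob >= 0.5).astype(int)
            yv = y[val_idx]
            auc = roc_auc_score(yv, prob)
            tp = int(np.sum((pred == 1) & (yv == 1)))
            fn = int(np.sum((pred == 0) & (yv == 1)))
            se = tp / (tp + fn) if tp + fn else float("nan")
            aucs.append(auc)
            ses.append(se)
            per_fold.append({"auc": auc, "se": se, "acc": float((pred == yv).mean())})
        score = (float(np.mean(aucs)), float(np.nanmean(ses)))
        if best is None or score > best:
            best = score
            spec.best_params = dict(params)
            spec.cv_auc, spec.cv_se = score
            spec.fold_metrics = per_fold
    spec.estimator = make_estimator(spec.algorithm, spec.best_params, seed=seed)
    spec.estimator.fit(X, y)
    return spec


# ---------------------------------------------------------------------------
# Consensus model


@dataclass
class ConsensusModel:
    """Stacked consensus classifier: logistic regression over base-model
    probabilities, with a 0.5 decision threshold by default."""

    base_specs: list[BaseClassifierSpec]
    meta: LogisticRegression
    threshold: float = 0.5

    def meta_features(self, smiles: Sequence[str]) -> np.ndarray:
        cols = []
        for spec in self.base_specs:
            X = featurize_many(smiles, spec.fingerprint)
            cols.append(spec.estimator.predict_proba(X)[:, 1])
        return np.column_stack(cols)

    def predict_proba(self, smiles: Sequence[str]) -> np.ndarray:
        """P(Ames positive) for each molecule."""
        return self.meta.predict_proba(self.meta_features(smiles))[:, 1]

    def predict_label(self, smiles: Sequence[str]) -> list[str]:
        from .chem_io import NEGATIVE

        probs = self.predict_proba(smiles)
        return [POSITIVE if p >= self.threshold else NEGATIVE for p in probs]

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "ConsensusModel":
        return joblib.load(path)


def stack_consensus(
    dataset: LabeledDataset,
    specs: Sequence[BaseClassifierSpec],
    folds: int = 5,
    seed: int = 0,
) -> ConsensusModel:
    """Fit the logistic meta-learner on out-of-fold base probabilities.

    Out-of-fold (rather than in-sample) probabilities keep the meta-learner
    from seeing its inputs' training labels through the base models.  Base
    estimators are refitted on the full training set afterwards.
    """
    if len(specs) < 2:
        raise ValueError("stacking needs at least 2 base classifiers")
    y = None
    cols = []
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for spec in specs:
        X, y = dataset_arrays(dataset, spec.fingerprint)
        est = make_estimator(spec.algorithm, spec.best_params, seed=seed)
        oof = cross_val_predict(est, X, y, cv=cv, method="predict_proba", n_jobs=1)
        cols.append(oof[:, 1])
        if spec.estimator is None:
            spec.estimator = make_estimator(spec.algorithm, spec.best_params, seed=seed)
            spec.estimator.fit(X, y)
    meta_X = np.column_stack(cols)
    meta = LogisticRegression(max_iter=1000, random_state=seed)
    meta.fit(meta_X, y)
    return ConsensusModel(list(specs), meta)


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class ModelMetrics:
    """AUC plus confusion-matrix derived scores, all in [0, 1]."""

    auc: float | None
    acc: float
    se: float
    sp: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {
            "AUC": self.auc,
            "ACC": self.acc,
            "SE": self.se,
            "SP": self.sp,
            "F1": self.f1,
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
        }


def metrics_from_confusion(
    tp: int, fp: int, tn: int, fn: int, auc: float | None = None
) -> ModelMetrics:
    """SE = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/N, F1 = 2TP/(2TP+FP+FN)."""
    n = tp + fp + tn + fn
    se = tp / (tp + fn) if tp + fn else float("nan")
    sp = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / n if n else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    return ModelMetrics(auc, acc, se, sp, f1, tp, fp, tn, fn)


def evaluate(
    model: ConsensusModel, dataset: LabeledDataset, threshold: float | None = None
) -> ModelMetrics:
    """Score a fitted model on a labeled dataset.

    AUC is the rank statistic over predicted probabilities (mid-rank on
    ties); it is reported as ``None`` when only one class is present.
    """
    thr = model.threshold if threshold is None else threshold
    probs = model.predict_proba([r.smiles for r in dataset])
    y = np.array([1 if r.label == POSITIVE else 0 for r in dataset])
    pred = (probs >= thr).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    auc = float(roc_auc_score(y, probs)) if len(np.unique(y)) == 2 else None
    return metrics_from_confusion(tp, fp, tn, fn, auc=auc)


def default_specs(
    roster: Sequence[tuple[str, str]] = DEFAULT_ROSTER,
    grids: Mapping[str, dict] | None = None,
) -> list[BaseClassifierSpec]:
    grids = grids or {}
    return [
        BaseClassifierSpec(alg, fp, grid=dict(grids.get(alg, DEFAULT_GRIDS.get(alg, {}))))
        for alg, fp in roster
    ]
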