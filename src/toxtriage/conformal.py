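"""Mondrian inductive conformal classification over random forests.

The central predictive engine: a random forest wrapped in a Mondrian
(class-conditional) inductive conformal predictor.  Training data is
split into a proper training set and a calibration set; the
nonconformity score of an example for class *c* is one minus the
forest's estimated probability of *c*.  For a query, the p-value of
class *c* is the (smoothed) fraction of same-class calibration scores
at least as nonconforming as the query's:

    p_c = (#{calibration scores of class c >= query score_c} + 1) / (n_c + 1)

At significance level ``s`` the prediction set contains every class
with p > 1 - s; a singleton set is a definite (positive or negative)
call, both-or-neither is *uncertain*.  This guarantees that at most a
fraction 1 - s of predictions exclude the true class, per class,
up to finite-sample fluctuation.

Per-prediction reliability summaries follow the conformal-QSAR
convention:

* significance = 1 - min(p0, p1)
* confidence (%) = 100 x max(p0, p1)

The estimator follows scikit-learn conventions (``fit`` /
``predict`` / ``get_params``) and composes with sklearn tooling;
:class:`ConformalEnsemble` majority-votes several such models trained
on balanced data subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import train_test_split

POSITIVE = "positive"
NEGATIVE = "negative"
UNCERTAIN = "uncertain"

_FP_SIZE = 2048
_fp_generator = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=_FP_SIZE)


class FeaturizationError(ValueError):
    """The structure could not be parsed into a fingerprint."""


def featurize(smiles_or_mol) -> np.ndarray:
    """2048-bit hashed topological-path fingerprint as a binary vector.

    The same representation serves both QSAR modelling and read-across,
    so one structure encoding covers the whole pipeline.
    """
    if isinstance(smiles_or_mol, Chem.Mol):
        mol = smiles_or_mol
    else:
        mol = Chem.MolFromSmiles(str(smiles_or_mol))
    if mol is None:
        raise FeaturizationError(f"unparseable structure: {smiles_or_mol!r}")
    fp = _fp_generator.GetFingerprint(mol)
    arr = np.zeros(_FP_SIZE, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def featurize_many(smiles: Iterable[str]) -> np.ndarray:
    return np.vstack([featurize(s) for s in smiles])


class MondrianConformalForest(BaseEstimator):
    """Random forest wrapped in a Mondrian inductive conformal predictor.

    Parameters
    ----------
    n_estimators, max_features, max_depth
        Forest settings.  Defaults (500 trees, sqrt features, unlimited
        depth) are deliberately plain: hyperparameter tuning buys little
        on these fingerprint datasets.
    calibration_fraction
        Share of the training data held out for calibration
        (stratified), default 0.3.
    significance_level
        Default level used by :meth:`predict`, default 0.8.
    random_state
        Seed for the split and the forest; fitting twice with the same
        seed reproduces the calibration lists exactly.

    Attributes (after ``fit``)
    --------------------------
    forest_ : the fitted RandomForestClassifier
    classes_ : ndarray [0, 1]
    calibration_scores_ : dict class -> sorted ndarray of scores
    n_features_in_ : int
    """

    def __init__(
        self,
        n_estimators: int = 500,
        max_features: str = "sqrt",
        max_depth: Optional[int] = None,
        calibration_fraction: float = 0.3,
        significance_level: float = 0.8,
        random_state: Optional[int] = None,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.max_depth = max_depth
        self.calibration_fraction = calibration_fraction
        self.significance_level = significance_level
        self.random_state = random_state

    def fit(self, X, y) -> "MondrianConformalForest":
        X = np.asarray(X)
        y = np.asarray(y).astype(int)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly two classes, got {classes}")
        X_train, X_cal, y_train, y_cal = train_test_split(
            X, y,
            test_size=self.calibration_fraction,
            stratify=y,
            random_state=self.random_state,
        )
        if len(np.unique(y_cal)) != 2 or len(np.unique(y_train)) != 2:
            raise ValueError("a class vanished from the proper/calibration split")
        forest = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            max_depth=self.max_depth,
            random_state=self.random_state,
            n_jobs=1,
        )
        forest.fit(X_train, y_train)
        proba = forest.predict_proba(X_cal)
        col = {c: i for i, c in enumerate(forest.classes_)}
        self.calibration_scores_ = {
            int(c): np.sort(1.0 - proba[y_cal == c, col[c]]) for c in (0, 1)
        }
        for c, scores in self.calibration_scores_.items():
            if len(scores) == 0:
                raise ValueError(f"empty calibration list for class {c}")
        self.forest_ = forest
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "forest_"):
            raise RuntimeError("model is not fitted")

    def predict_p(self, X) -> np.ndarray:
        """Per-class conformal p-values, shape (n, 2): columns p0, p1."""
        self._check_fitted()
        X = np.asarray(X)
        proba = self.forest_.predict_proba(X)
        col = {c: i for i, c in enumerate(self.forest_.classes_)}
        out = np.empty((X.shape[0], 2))
        for c in (0, 1):
            scores = 1.0 - proba[:, col[c]]
            out[:, c] = conformal_p_value(self.calibration_scores_[c], scores)
        return out

    def predict(self, X, level: Optional[float] = None) -> np.ndarray:
        """Definite/uncertain class calls at the given significance level."""
        level = self.significance_level if level is None else level
        p = self.predict_p(X)
        return np.array([assign_label(p0, p1, level) for p0, p1 in p])

    def prediction_sets(self, X, level: Optional[float] = None) -> list:
        """Per-query set of included classes (subset of {0, 1})."""
        level = self.significance_level if level is None else level
        p = self.predict_p(X)
        return [
            frozenset(c for c in (0, 1) if row[c] > 1.0 - level) for row in p
        ]


def conformal_p_value(calibration_scores: np.ndarray, query_scores) -> np.ndarray:
    """Rank-counting p-value with ties counted as `>=`.

    ``p = (#{calibration >= query} + 1) / (n + 1)``.
    """
    cal = np.asarray(calibration_scores, dtype=float)
    q = np.atleast_1d(np.asarray(query_scores, dtype=float))
    n = len(cal)
    # count calibration scores >= q via searchsorted on the sorted list;
    # the 1e-12 slack keeps ties ties across serialization round-trips
    counts = n - np.searchsorted(np.sort(cal), q - 1e-12, side="left")
    return (counts + 1) / (n + 1)


def assign_label(p0: float, p1: float, level: float) -> str:
    """Prediction-set interpretation at a significance level.

    Class *c* is included iff ``p_c > 1 - level`` (strict).  A set
    containing only class 1 is positive, only class 0 negative, and
    both-or-neither uncertain.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    threshold = 1.0 - level
    in0, in1 = p0 > threshold, p1 > threshold
    if in1 and not in0:
        return POSITIVE
    if in0 and not in1:
        return NEGATIVE
    return UNCERTAIN


def significance_confidence(p0: float, p1: float) -> tuple[float, float]:
    """Reliability summaries of a conformal prediction.

    significance = 1 - min(p0, p1); confidence (%) = 100 x max(p0, p1).
    """
    return 1.0 - min(p0, p1), 100.0 * max(p0, p1)


def ensemble_vote(predictions: Sequence) -> str:
    """Majority vote over per-model predictions.

    Each model contributes +1 to the count of every class in its
    prediction set.  Inputs may be prediction sets (subsets of {0, 1})
    or label strings, where ``positive`` = {1}, ``negative`` = {0} and
    ``uncertain`` = {0, 1}.  Strictly more class-1 counts -> positive;
    strictly more class-0 -> negative; equal -> uncertain.  The vote is
    permutation-invariant.
    """
    label_sets = {
        POSITIVE: frozenset({1}),
        NEGATIVE: frozenset({0}),
        UNCERTAIN: frozenset({0, 1}),
    }
    count0 = count1 = 0
    for pred in predictions:
        pset = label_sets[pred] if isinstance(pred, str) else frozenset(pred)
        count0 += 0 in pset
        count1 += 1 in pset
    if count1 > count0:
        return POSITIVE
    if count0 > count1:
        return NEGATIVE
    return UNCERTAIN


class ConformalEnsemble(BaseEstimator):
    """Majority-vote ensemble of Mondrian conformal forests.

    Fitted on an :class:`~toxtriage.datasets.EnsemblePartition`-style
    list of balanced datasets; the vote combines the members'
    prediction sets.  Reported p-values are the member means (used only
    for significance/confidence reporting, not for the vote).
    """

    def __init__(self, members: Optional[list] = None, significance_level: float = 0.8):
        self.members = members
        self.significance_level = significance_level

    def fit(self, datasets: Sequence[tuple], **forest_params) -> "ConformalEnsemble":
        """Fit one member per (X, y) pair."""
        self.members_ = []
        for i, (X, y) in enumerate(datasets):
            seed = forest_params.pop("random_state", None)
            model = MondrianConformalForest(
                significance_level=self.significance_level,
                random_state=None if seed is None else seed + i,
                **forest_params,
            )
            forest_params["random_state"] = seed
            self.members_.append(model.fit(X, y))
        return self

    @property
    def _fitted_members(self):
        members = getattr(self, "members_", None) or self.members
        if not members:
            raise RuntimeError("ensemble has no fitted members")
        return members

    def predict_p(self, X) -> np.ndarray:
        return np.mean([m.predict_p(X) for m in self._fitted_members], axis=0)

    def predict(self, X, level: Optional[float] = None) -> np.ndarray:
        level = self.significance_level if level is None else level
        member_sets = [m.prediction_sets(X, level) for m in self._fitted_members]
        return np.array(
            [ensemble_vote(sets) for sets in zip(*member_sets)]
        )


def save_bundle(model: "MondrianConformalForest", directory) -> None:
    """Persist a fitted model as a directory bundle.

    Layout: ``manifest.json`` (constructor params + feature dialect),
    ``forest.joblib`` and per-class calibration score CSVs.
    """
    import json
    import os

    import joblib
    import pandas as pd

    model._check_fitted()
    os.makedirs(directory, exist_ok=True)
    manifest = {
        "params": model.get_params(),
        "feature_dialect": {
            "kind": "rdkit_topological_path",
            "n_bits": _FP_SIZE,
        },
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    joblib.dump(model.forest_, os.path.join(directory, "forest.joblib"))
    for c, scores in model.calibration_scores_.items():
        pd.DataFrame({"score": scores}).to_csv(
            os.path.join(directory, f"calibration_class{c}.csv"),
            index=False, float_format="%.17g",  # ties must survive round-trip
        )


def load_bundle(directory) -> "MondrianConformalForest":
    import json
    import os

    import joblib
    import pandas as pd

    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    model = MondrianConformalForest(**manifest["params"])
    model.forest_ = joblib.load(os.path.join(directory, "forest.joblib"))
    model.calibration_scores_ = {
        c: pd.read_csv(
            os.path.join(directory, f"calibration_class{c}.csv")
        )["score"].to_numpy()
        for c in (0, 1)
    }
    model.classes_ = np.array([0, 1])
    model.n_features_in_ = model.forest_.n_features_in_
    return model


@dataclass
class ModelMetrics:
    """Definite-prediction quality plus conformal coverage.

    ``conformal_coverage`` is the fraction of non-uncertain predictions;
    the remaining metrics are computed over that definite subset only
    and are ``None`` when no prediction is definite.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    mcc: Optional[float]
    conformal_coverage: float
    conformal_accuracy: Optional[float]


def evaluate(y_true, labels) -> ModelMetrics:
    """Score definite/uncertain predictions against known labels."""
    y_true = np.asarray(y_true).astype(int)
    labels = np.asarray(labels)
    if len(y_true) == 0:
        raise ValueError("test set is empty")
    definite = labels != UNCERTAIN
    coverage = float(definite.mean())
    if not definite.any():
        return ModelMetrics(None, None, None, 0.0, None)
    y_def = y_true[definite]
    pred = (labels[definite] == POSITIVE).astype(int)
    tp = int(((pred == 1) & (y_def == 1)).sum())
    tn = int(((pred == 0) & (y_def == 0)).sum())
    fp = int(((pred == 1) & (y_def == 0)).sum())
    fn = int(((pred == 0) & (y_def == 1)).sum())
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mcc = float(matthews_corrcoef(y_def, pred)) if len(np.unique(y_def)) > 0 else None
    accuracy = (tp + tn) / len(y_def)
    return ModelMetrics(
        sensitivity=sens,
        specificity=spec,
        mcc=mcc,
        conformal_coverage=coverage,
        conformal_accuracy=accuracy,
    )
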