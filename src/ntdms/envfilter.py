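"""Spectrum-specific supervised envelope filtering with a two-model veto.

A logistic-regression and a gradient-boosting classifier are trained on a
small, manually (or simulator-) labelled set of envelopes from the same
spectrum, each tuned by cross-validation to maximise recall on the positive
class.  An envelope is discarded only when *both* models call it false:
losing a real fragment ion is considered more harmful than keeping a few
artifacts, so the veto's false-negative rate can never exceed that of either
model alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .envdetect import EnvelopeCandidate, FeatureVector

MODEL_FORMAT_VERSION = 1


@dataclass
class LabeledEnvelope:
    candidate: EnvelopeCandidate
    features: FeatureVector
    label: bool


def features_matrix(candidates, features) -> np.ndarray:
    return np.vstack(
        [
            f.as_array(c.charge, c.total_intensity)
            for c, f in zip(candidates, features)
        ]
    )


class EnvelopeVetoClassifier(BaseEstimator, ClassifierMixin):
    """Recall-optimised logistic-regression + gradient-boosting veto pair.

    ``predict`` returns the veto decision: an envelope is predicted *false*
    (0) only when both member models predict false.  Fitted attributes:
    ``model_a_`` (scaled logistic regression), ``model_b_`` (gradient
    boosting), ``recall_a_``/``recall_b_`` (cross-validated training recall).
    """

    def __init__(self, cv: int = 5, random_state: int = 0):
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if len(X) < 20:
            raise ValueError("need at least 20 labelled envelopes to train")
        if len(np.unique(y)) < 2:
            raise ValueError(
                "training set contains a single class: label more envelopes "
                "(both real and artifactual examples are required)"
            )
        n_min = int(np.bincount(y).min())
        cv = StratifiedKFold(
            n_splits=max(2, min(self.cv, n_min)), shuffle=True,
            random_state=self.random_state,
        )
        grid_a = GridSearchCV(
            Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("clf", LogisticRegression(max_iter=2000)),
                ]
            ),
            {"clf__C": np.logspace(-2, 2, 5)},
            scoring="recall",
            cv=cv,
        )
        grid_a.fit(X, y)
        grid_b = GridSearchCV(
            GradientBoostingClassifier(random_state=self.random_state),
            {
                "max_depth": [2, 3, 4],
                "learning_rate": [0.05, 0.1, 0.2],
                "n_estimators": [100, 300],
            },
            scoring="recall",
            cv=cv,
        )
        grid_b.fit(X, y)
        self.model_a_ = grid_a.best_estimator_
        self.model_b_ = grid_b.best_estimator_
        self.recall_a_ = float(grid_a.best_score_)
        self.recall_b_ = float(grid_b.best_score_)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        return self

    def _check_X(self, X):
        check_is_fitted(self, "model_a_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension mismatch: got {X.shape[1]}, "
                f"expected {self.n_features_in_}"
            )
        return X

    def predict_members(self, X):
        """(predictions_a, predictions_b) of the two member models."""
        X = self._check_X(X)
        return self.model_a_.predict(X).astype(bool), self.model_b_.predict(X).astype(bool)

    def predict(self, X):
        a, b = self.predict_members(X)
        return (a | b).astype(int)  # discarded only if both say false

    def save(self, path: str | Path) -> None:
        joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": self}, path)

    @classmethod
    def load(cls, path: str | Path) -> "EnvelopeVetoClassifier":
        bundle = joblib.load(path)
        if bundle.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model file version {bundle.get('format_version')!r}"
            )
        return bundle["model"]


def train_voting_classifier(data: list[LabeledEnvelope], seed: int = 0) -> EnvelopeVetoClassifier:
    """Fit the veto pair on labelled envelopes (deterministic given ``seed``)."""
    X = features_matrix([d.candidate for d in data], [d.features for d in data])
    y = np.array([d.label for d in data], dtype=int)
    return EnvelopeVetoClassifier(random_state=seed).fit(X, y)


def apply_veto_filter(
    candidates: list[EnvelopeCandidate],
    features: list[FeatureVector],
    model: EnvelopeVetoClassifier,
) -> tuple[list[EnvelopeCandidate], list[EnvelopeCandidate]]:
    """(kept, discarded): discarded iff both member models predict false."""
    if not candidates:
        return [], []
    X = features_matrix(candidates, features)
    keep = model.predict(X).astype(bool)
    kept = [c for c, k in zip(candidates, keep) if k]
    discarded = [c for c, k in zip(candidates, keep) if not k]
    return kept, discarded
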