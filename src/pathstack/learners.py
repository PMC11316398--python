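"""Registry of supervised base learners for both stages.

Every learner is a scikit-learn estimator (or a thin wrapper) that emits a
class-1 probability via ``predict_proba``. Margin-only learners (SVM) are
wrapped with a monotone sigmoid link on their decision values: downstream
use of the scores (ranking for AUC / correlation, the [0,1] matrix
invariant) needs monotone [0,1] outputs, not calibrated probabilities.

No hyper-parameter optimisation is performed; each learner runs at fixed,
conventional settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = ["LearnerSpec", "make_learner", "LEARNER_IDS", "SigmoidLinkSVC"]


class SigmoidLinkSVC(BaseEstimator, ClassifierMixin):
    """SVC whose decision values are mapped to (0,1) by a sigmoid link."""

    def __init__(self, C: float = 1.0, kernel: str = "rbf", gamma="scale"):
        self.C = C
        self.kernel = kernel
        self.gamma = gamma

    def fit(self, X, y):
        self._svc = SVC(C=self.C, kernel=self.kernel, gamma=self.gamma)
        self._svc.fit(X, y)
        self.classes_ = self._svc.classes_
        return self

    def predict_proba(self, X):
        p1 = expit(self._svc.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _registry() -> dict:
    return {
        "tree": lambda: DecisionTreeClassifier(),
        "svm": lambda: SigmoidLinkSVC(),
        "rf": lambda: RandomForestClassifier(n_estimators=100),
        "nb": lambda: GaussianNB(),
        "logistic": lambda: LogisticRegression(C=np.inf, max_iter=1000),
        "ridge": lambda: LogisticRegression(C=1.0, max_iter=1000),
        "knn": lambda: KNeighborsClassifier(n_neighbors=5),
        "gbm": lambda: GradientBoostingClassifier(),
        "gp": lambda: GaussianProcessClassifier(),
        "elasticnet": lambda: LogisticRegression(
            solver="saga", l1_ratio=0.5, C=1.0, max_iter=2000
        ),
        # input-independent reference model: predicts the training class prior
        "prior": lambda: DummyClassifier(strategy="prior"),
    }


LEARNER_IDS = tuple(_registry())


@dataclass(frozen=True)
class LearnerSpec:
    """A base learner by registry id plus hyper-parameter overrides."""

    learner_id: str = "ridge"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.learner_id not in LEARNER_IDS:
            raise ValueError(
                f"unknown learner {self.learner_id!r}; known: {sorted(LEARNER_IDS)}"
            )


def make_learner(spec: LearnerSpec, random_state: int | None = None):
    """Instantiate a fresh estimator for ``spec``, seeded when supported."""
    est = _registry()[spec.learner_id]()
    if spec.hyperparameters:
        est.set_params(**spec.hyperparameters)
    if random_state is not None and "random_state" in est.get_params():
        est.set_params(random_state=random_state)
    return clone(est)
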