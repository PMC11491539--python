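"""STEMI/NSTEMI classification and infarction-territory localization.

Two pathways are provided over the detection encodings:

* an explicit guideline pathway — the lead-set criteria used clinically to
  localize the infarct (anterior: >= 2 of V1-V4 with STE; lateral: >= 2 of
  V5, V6, I, aVL; inferior: >= 2 of II, III, aVF; suspected left-main
  disease: STE in aVR), with STEMI called whenever any territory fires;
* a trainable pathway — scikit-learn-compatible classifiers fit on any of
  the six encodings, including a validation-weighted heterogeneous ensemble
  mirroring the weighted-ensemble concept of AutoML stacks.

Territory prediction is multi-label (one binary head per territory), since
a single patient can have multiple coronary occlusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import ExtraTreesClassifier, GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.utils.validation import check_is_fitted

from .detector import Detection
from .encoder import EncodingScheme, EncodingVector, encode
from .layout import LeadID
from .synthgen import TERRITORIES, TERRITORY_LEADS, TERRITORY_MIN_LEADS

__all__ = [
    "TerritoryCall",
    "Diagnosis",
    "ClassifierModel",
    "territory_rules",
    "classify_rule",
    "fit_classifier",
    "predict",
    "fit_territory_classifier",
    "StemiClassifier",
    "TerritoryClassifier",
    "WeightedEnsembleClassifier",
]


@dataclass(frozen=True)
class TerritoryCall:
    """Territories whose rule fired, with the qualifying leads as evidence."""

    territories: frozenset[str]
    evidence: dict[str, tuple[LeadID, ...]] = field(default_factory=dict)


@dataclass(frozen=True)
class Diagnosis:
    label: str  # "STEMI" | "NSTEMI"
    score: float  # probability-like, higher = STEMI
    method: str  # "rule" | "trained"


def territory_rules(
    lead_ste_presence: np.ndarray,
    anterior_min: int = 2,
) -> TerritoryCall:
    """Apply the guideline lead-set criteria to a 12-dim STE presence vector.

    The vector is indexed by canonical lead order.  ``anterior_min`` encodes
    the "more than one lead among V1-V4" reading (>= 2 by default), kept
    configurable because the anterior criterion is phrased differently from
    the others.
    """
    presence = np.asarray(lead_ste_presence)
    if presence.shape != (12,):
        raise ValueError(f"expected a 12-dim presence vector, got shape {presence.shape}")
    mins = dict(TERRITORY_MIN_LEADS, anterior=anterior_min)
    fired: set[str] = set()
    evidence: dict[str, tuple[LeadID, ...]] = {}
    for terr in TERRITORIES:
        leads = tuple(l for l in TERRITORY_LEADS[terr] if presence[int(l)])
        if len(leads) >= mins[terr]:
            fired.add(terr)
            evidence[terr] = leads
    return TerritoryCall(frozenset(fired), evidence)


def _lead_presence(dets: list[Detection], cls: str) -> np.ndarray:
    p = np.zeros(12, dtype=int)
    for d in dets:
        if d.cls == cls:
            p[int(d.lead)] = 1
    return p


def classify_rule(dets: list[Detection], anterior_min: int = 2) -> tuple[Diagnosis, TerritoryCall]:
    """Guideline diagnosis: STEMI iff any territory rule fires on STE leads.

    The score is 1 when a territory fires; otherwise a sub-threshold
    evidence score that grows with the number of STE / lesser-STE leads
    (monotone, capped below the 0.5 decision threshold), 0 with no
    detections at all.
    """
    ste = _lead_presence(dets, "STE")
    lesser = _lead_presence(dets, "lesser_STE")
    call = territory_rules(ste, anterior_min=anterior_min)
    if call.territories:
        score = 1.0
    else:
        score = min(0.49, 0.15 * int(ste.sum()) + 0.05 * int(lesser.sum()))
    label = "STEMI" if score >= 0.5 else "NSTEMI"
    return Diagnosis(label=label, score=score, method="rule"), call


# ---------------------------------------------------------------------------
# trainable pathway
# ---------------------------------------------------------------------------


class WeightedEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Heterogeneous base learners combined by validation-weighted averaging.

    Each base learner is fit on a stratified training split and weighted by
    its AUROC on the held-out validation split (chance-level learners get
    zero weight), then refit on the full data; ``predict_proba`` is the
    weighted average of the base probabilities.
    """

    def __init__(self, val_fraction: float = 0.25, random_state: int | None = None):
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _base_learners(self):
        rs = self.random_state
        return [
            ("logistic", LogisticRegression(max_iter=2000)),
            ("knn", KNeighborsClassifier(n_neighbors=5)),
            ("random_forest", RandomForestClassifier(n_estimators=100, random_state=rs)),
            ("extra_trees", ExtraTreesClassifier(n_estimators=100, random_state=rs)),
            ("gboost", GradientBoostingClassifier(random_state=rs)),
        ]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("ensemble requires at least two classes")
        X_tr, X_val, y_tr, y_val = train_test_split(
            X, y, test_size=self.val_fraction, stratify=y, random_state=self.random_state
        )
        weights = []
        names_models = self._base_learners()
        for _, model in names_models:
            m = clone(model).fit(X_tr, y_tr)
            proba = m.predict_proba(X_val)[:, 1]
            auc = roc_auc_score(y_val == self.classes_[1], proba)
            weights.append(max(auc - 0.5, 0.0))
        weights = np.asarray(weights)
        if weights.sum() == 0:
            weights = np.ones_like(weights)
        self.weights_ = weights / weights.sum()
        self.estimators_ = [clone(m).fit(X, y) for _, m in names_models]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        proba = np.zeros((X.shape[0], len(self.classes_)))
        for w, m in zip(self.weights_, self.estimators_):
            proba += w * m.predict_proba(X)
        return proba

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


class StemiClassifier(ClassifierMixin, BaseEstimator):
    """STEMI-vs-NSTEMI classifier over one detection encoding.

    Parameters
    ----------
    learner : {"logistic", "ensemble"}
        Regularized logistic regression (default) or the validation-weighted
        heterogeneous ensemble.
    scheme : EncodingScheme or str, optional
        Recorded for provenance and input checking; ``fit``/``predict``
        operate on plain arrays of that encoding.
    threshold : float
        Decision threshold on the STEMI probability.
    """

    def __init__(
        self,
        learner: str = "logistic",
        scheme: EncodingScheme | str | None = None,
        C: float = 1.0,
        threshold: float = 0.5,
        random_state: int | None = None,
    ):
        self.learner = learner
        self.scheme = scheme
        self.C = C
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (n_cases, encoding_dim)")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training labels contain a single class")
        if self.learner == "logistic":
            model = LogisticRegression(C=self.C, max_iter=2000, random_state=self.random_state)
        elif self.learner == "ensemble":
            model = WeightedEnsembleClassifier(random_state=self.random_state)
        else:
            raise ValueError(f"unknown learner {self.learner!r}")
        self.model_ = model.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        proba = self.predict_proba(X)[:, -1]
        return np.where(proba >= self.threshold, self.classes_[-1], self.classes_[0])


class TerritoryClassifier(ClassifierMixin, BaseEstimator):
    """Multi-label territory prediction: one binary head per territory.

    ``fit`` takes an ``(n, 4)`` 0/1 matrix with columns in territory order
    (anterior, lateral, inferior, suspected_LM); territories co-occur, so
    heads are independent.  A head whose training column is single-class
    raises, as it cannot be calibrated.
    """

    territories = TERRITORIES

    def __init__(self, learner: str = "logistic", C: float = 1.0, random_state: int | None = None):
        self.learner = learner
        self.C = C
        self.random_state = random_state

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=int)
        if Y.ndim != 2 or Y.shape[1] != len(self.territories):
            raise ValueError(f"Y must be (n, {len(self.territories)}) multi-label matrix")
        self.heads_ = {}
        for j, terr in enumerate(self.territories):
            if len(np.unique(Y[:, j])) < 2:
                raise ValueError(f"territory {terr!r} is single-class in the training data")
            head = StemiClassifier(
                learner=self.learner, C=self.C, random_state=self.random_state
            )
            self.heads_[terr] = head.fit(X, Y[:, j])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "heads_")
        return np.column_stack(
            [self.heads_[t].predict_proba(X)[:, -1] for t in self.territories]
        )

    def predict(self, X):
        return (self.predict_proba(X) >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------


@dataclass
class ClassifierModel:
    """Fitted classifier plus its training provenance."""

    scheme: EncodingScheme
    estimator: StemiClassifier
    n_train: int
    seed: int | None


def _as_matrix(X, scheme: EncodingScheme) -> np.ndarray:
    rows = []
    for x in X:
        if isinstance(x, EncodingVector):
            if x.scheme is not scheme:
                raise ValueError(f"encoding scheme mismatch: {x.scheme} != {scheme}")
            rows.append(x.values)
        else:
            rows.append(np.asarray(x))
    return np.asarray(rows, dtype=float)


def fit_classifier(
    X,
    y,
    scheme: EncodingScheme = EncodingScheme.LEAD_DETAILED_PRESENCE,
    seed: int | None = None,
    learner: str = "logistic",
) -> ClassifierModel:
    """Fit the STEMI classifier on encoding vectors; deterministic given seed."""
    mat = _as_matrix(X, scheme)
    est = StemiClassifier(learner=learner, scheme=scheme, random_state=seed).fit(mat, np.asarray(y))
    return ClassifierModel(scheme=scheme, estimator=est, n_train=len(mat), seed=seed)


def predict(model: ClassifierModel, x) -> Diagnosis:
    """Diagnose one case from its encoding vector."""
    if isinstance(x, EncodingVector):
        if x.scheme is not model.scheme:
            raise ValueError(f"encoding scheme mismatch: {x.scheme} != {model.scheme}")
        x = x.values
    proba = model.estimator.predict_proba(np.asarray(x, dtype=float)[None, :])
    classes = list(model.estimator.classes_)
    score = float(proba[0, classes.index("STEMI")]) if "STEMI" in classes else float(proba[0, -1])
    label = "STEMI" if score >= model.estimator.threshold else "NSTEMI"
    return Diagnosis(label=label, score=score, method="trained")


def fit_territory_classifier(
    X,
    Y,
    scheme: EncodingScheme = EncodingScheme.LEAD_DETAILED_PRESENCE,
    seed: int | None = None,
    learner: str = "logistic",
) -> TerritoryClassifier:
    """Fit the four one-vs-rest territory heads on encoding vectors."""
    mat = _as_matrix(X, scheme)
    return TerritoryClassifier(learner=learner, random_state=seed).fit(mat, np.asarray(Y))
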