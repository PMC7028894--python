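"""One-vs-rest cellulite-stage classification with best-probability fusion.

For each of the four severity stages a binary scorer is fitted (positive =
"belongs to this stage"); a test image is assigned the stage whose scorer
emits the highest probability score, ties going to the lowest stage index.
The reference scorer is a three-layer perceptron (input, one sigmoid hidden
layer, one sigmoid output unit) trained by full-batch gradient descent on
binary cross-entropy — written out explicitly below so the training
procedure is fully inspectable.  Eight further classical families (MinDist,
KNN, NB, LogReg, SVM, LDA, DT, RF) plug into the same harness.

The module is organised around a model/results pair: build an
:class:`OvRStageModel` from a feature matrix and stage labels, call
``fit()``, and work with the returned :class:`OvRStageResults`.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluate import MetricsReport, evaluate_predictions
from .io import STAGES

logger = logging.getLogger(__name__)

FAMILIES = ("mindist", "knn", "nb", "logreg", "svm", "lda", "dt", "rf", "ann")

SERIALIZATION_VERSION = 1


class TrainingError(RuntimeError):
    pass


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class ANNConfig:
    """Three-layer perceptron hyper-parameters.

    One hidden layer of ``hidden_units`` sigmoid units and a single sigmoid
    output; full-batch gradient descent on binary cross-entropy for
    ``epochs`` passes at a fixed ``learning_rate``.  Weights start uniform
    in [-0.5, 0.5] from ``seed``.
    """

    hidden_units: int = 20
    learning_rate: float = 0.05
    epochs: int = 500
    activation: str = "sigmoid"
    seed: int = 17

    def __post_init__(self):
        if self.hidden_units < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("invalid ANN configuration")
        if self.activation != "sigmoid":
            raise ValueError("only the sigmoid activation is supported")


class ThreeLayerPerceptron:
    """Binary feed-forward network: input -> sigmoid hidden -> sigmoid output."""

    def __init__(self, config: ANNConfig = ANNConfig()):
        self.config = config
        self.w1: np.ndarray | None = None  # (d+1, h), row -1 is the bias
        self.w2: np.ndarray | None = None  # (h+1, 1)
        self.loss_history: list[float] = []

    def _forward(self, X: np.ndarray):
        xb = np.hstack([X, np.ones((X.shape[0], 1))])
        h = _sigmoid(xb @ self.w1)
        hb = np.hstack([h, np.ones((h.shape[0], 1))])
        o = _sigmoid(hb @ self.w2).ravel()
        return xb, h, hb, o

    def fit(self, X, y, sample_weight=None) -> "ThreeLayerPerceptron":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in the feature matrix")
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("targets must be binary 0/1")
        n, d = X.shape
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        w = w / w.mean()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.w1 = rng.uniform(-0.5, 0.5, size=(d + 1, cfg.hidden_units))
        self.w2 = rng.uniform(-0.5, 0.5, size=(cfg.hidden_units + 1, 1))
        self.loss_history = []
        eps = 1e-12
        for _ in range(cfg.epochs):
            xb, h, hb, o = self._forward(X)
            loss = -np.mean(w * (y * np.log(o + eps) + (1 - y) * np.log(1 - o + eps)))
            if not np.isfinite(loss):
                raise TrainingError(
                    "training loss became non-finite; try a smaller learning rate"
                )
            self.loss_history.append(float(loss))
            delta_o = (w * (o - y))[:, None] / n          # d(loss)/d(pre-sigmoid out)
            grad_w2 = hb.T @ delta_o
            delta_h = (delta_o @ self.w2[:-1].T) * h * (1.0 - h)
            grad_w1 = xb.T @ delta_h
            self.w1 -= cfg.learning_rate * grad_w1
            self.w2 -= cfg.learning_rate * grad_w2
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self.w1 is None:
            raise RuntimeError("perceptron is not fitted")
        return self._forward(np.asarray(X, dtype=float))[3]


class MinDistScorer:
    """Minimum-distance scorer: softmin over distances to the two class
    centroids, so equal distances give exactly 0.5."""

    def fit(self, X, y, sample_weight=None) -> "MinDistScorer":
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
        self.centroids_ = {}
        for c in (0, 1):
            m = y == c
            self.centroids_[c] = np.average(X[m], axis=0, weights=w[m])
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        d0 = np.linalg.norm(X - self.centroids_[0], axis=1)
        d1 = np.linalg.norm(X - self.centroids_[1], axis=1)
        lo = np.minimum(d0, d1)
        e0, e1 = np.exp(-(d0 - lo)), np.exp(-(d1 - lo))
        return e1 / (e0 + e1)


class _SklearnScorer:
    """Adapter turning an sklearn binary classifier into a [0,1] scorer."""

    _SUPPORTS_WEIGHT = {"nb", "logreg", "svm", "dt", "rf", "lda"}

    def __init__(self, family: str, estimator):
        self.family = family
        self.estimator = estimator

    def fit(self, X, y, sample_weight=None):
        if sample_weight is not None and self.family in self._SUPPORTS_WEIGHT:
            self.estimator.fit(X, y, sample_weight=sample_weight)
        else:
            if sample_weight is not None:
                logger.warning("%s: sample weights unsupported, ignored", self.family)
            self.estimator.fit(X, y)
        return self

    def predict_proba(self, X) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        pos = list(self.estimator.classes_).index(1)
        return proba[:, pos]


def make_binary_scorer(family: str, seed: int = 17, **params):
    """Construct an unfitted binary scorer of the named family.

    Probability scores come from each family's native mechanism: class
    posteriors (NB, LogReg, LDA), neighbour/leaf fractions (KNN, DT), vote
    fractions (RF), Platt-calibrated decision values (SVM), softmin over
    centroid distances (MinDist), or the output sigmoid (ANN).
    """
    family = family.lower()
    if family == "ann":
        cfg = ANNConfig(seed=seed, **params)
        return ThreeLayerPerceptron(cfg)
    if family == "mindist":
        return MinDistScorer()
    if family == "knn":
        est = KNeighborsClassifier(n_neighbors=params.pop("n_neighbors", 5), **params)
    elif family == "nb":
        est = GaussianNB(**params)
    elif family == "logreg":
        est = LogisticRegression(max_iter=params.pop("max_iter", 1000), **params)
    elif family == "svm":
        est = SVC(kernel=params.pop("kernel", "rbf"), C=params.pop("C", 1.0),
                  gamma=params.pop("gamma", "auto"), probability=True,
                  random_state=seed, **params)
    elif family == "lda":
        est = LinearDiscriminantAnalysis(**params)
    elif family == "dt":
        est = DecisionTreeClassifier(criterion=params.pop("criterion", "gini"),
                                     random_state=seed, **params)
    elif family == "rf":
        est = RandomForestClassifier(n_estimators=params.pop("n_estimators", 100),
                                     random_state=seed, **params)
    else:
        raise ValueError(f"unknown classifier family {family!r}; "
                         f"choose from {FAMILIES}")
    return _SklearnScorer(family, est)


@dataclass
class FeatureScaler:
    """Per-dimension z-scaling with parameters from the training set only.
    Constant dimensions keep unit scale so they map to zero."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, float)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return cls(mean=X.mean(axis=0), sd=sd)

    def transform(self, X) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) / self.sd


class OvRStageModel:
    """One-vs-rest stage classifier specification, statsmodels-style.

    Parameters
    ----------
    X : (n, d) array
        Training feature matrix (any extractor's output, stacked).
    y : (n,) int array
        Stage labels 0-3.  At least two distinct stages are required.
    family : str
        One of :data:`FAMILIES`; default the three-layer perceptron.
    feature_method : str
        Name of the extractor that produced ``X`` (metadata only).
    class_weight : None or "balanced"
        "balanced" applies inverse-prevalence sample weights in each binary
        fit, countering class imbalance at the cost of distorting the
        scorers' base rates under uninformative features.
    seed : int
        Seeds every stochastic fit (ANN init, RF bootstrap, SVM Platt CV);
        scorer s uses seed + s.
    """

    def __init__(self, X, y, family: str = "ann", feature_method: str = "",
                 class_weight: str | None = None, seed: int = 17,
                 params: dict | None = None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be (n, d) with one label per row")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite feature values")
        if np.unique(self.y).size < 2:
            raise ValueError("one-vs-rest needs at least two stages in training")
        if class_weight not in (None, "balanced"):
            raise ValueError("class_weight must be None or 'balanced'")
        self.family = family.lower()
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
        self.feature_method = feature_method
        self.class_weight = class_weight
        self.seed = int(seed)
        self.params = dict(params or {})

    def fit(self) -> "OvRStageResults":
        scaler = FeatureScaler.fit(self.X)
        Xs = scaler.transform(self.X)
        scorers: dict[int, object] = {}
        for s in STAGES:
            yb = (self.y == s).astype(int)
            if yb.sum() == 0:
                logger.warning("stage %d has no positive training examples; "
                               "scorer untrainable, never selected", s)
                scorers[s] = None
                continue
            weight = None
            if self.class_weight == "balanced":
                prev = yb.mean()
                weight = np.where(yb == 1, 0.5 / prev, 0.5 / (1.0 - prev))
            scorer = make_binary_scorer(self.family, seed=self.seed + s, **self.params)
            scorers[s] = scorer.fit(Xs, yb, sample_weight=weight)
        return OvRStageResults(model=self, scaler=scaler, scorers=scorers)


@dataclass
class OvRStageResults:
    """Fitted one-vs-rest stage classifier."""

    model: OvRStageModel
    scaler: FeatureScaler
    scorers: dict[int, object] = field(default_factory=dict)

    @property
    def trainable(self) -> dict[int, bool]:
        return {s: self.scorers[s] is not None for s in STAGES}

    def scores(self, X) -> np.ndarray:
        """(n, 4) matrix of per-stage probability scores in [0, 1];
        untrainable stages score 0 everywhere."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.model.X.shape[1]:
            raise ValueError(
                f"feature length {X.shape[1]} does not match the model's "
                f"{self.model.X.shape[1]}"
            )
        Xs = self.scaler.transform(X)
        out = np.zeros((X.shape[0], len(STAGES)))
        for s in STAGES:
            if self.scorers[s] is not None:
                out[:, s] = np.clip(self.scorers[s].predict_proba(Xs), 0.0, 1.0)
        return out

    def predict(self, X) -> np.ndarray:
        """Fused prediction: argmax of the four probability scores, ties
        broken toward the lowest stage index; untrainable stages are masked
        out and can never be selected."""
        sc = self.scores(X)
        masked = sc.copy()
        for s in STAGES:
            if self.scorers[s] is None:
                masked[:, s] = -np.inf
        return np.argmax(masked, axis=1)

    def predict_one(self, x) -> tuple[int, np.ndarray]:
        """Predicted stage and the length-4 score vector for one feature vector."""
        x = np.asarray(x, dtype=float)[None, :]
        return int(self.predict(x)[0]), self.scores(x)[0]

    def evaluate(self, X_test, y_test) -> MetricsReport:
        """Per-stage one-vs-rest metrics of the fused predictions, with
        ROC/AUC from each stage's score column."""
        sc = self.scores(X_test)
        pred = self.predict(X_test)
        return evaluate_predictions(y_test, pred, scores=sc)

    def summary(self) -> str:
        m = self.model
        lines = [
            "One-vs-rest cellulite stage classifier",
            "=" * 54,
            f"classifier family : {m.family}",
            f"feature method    : {m.feature_method or '(unspecified)'}",
            f"feature dimension : {m.X.shape[1]}",
            f"training samples  : {m.X.shape[0]}",
            f"class counts      : "
            + ", ".join(f"{s}: {int(np.sum(m.y == s))}" for s in STAGES),
            f"class weighting   : {m.class_weight or 'none'}",
            f"seed              : {m.seed}",
            "scorers           : "
            + ", ".join(f"stage {s} {'fitted' if ok else 'UNTRAINABLE'}"
                        for s, ok in self.trainable.items()),
            "=" * 54,
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialise to a versioned binary blob (not stable across versions)."""
        blob = {
            "format_version": SERIALIZATION_VERSION,
            "family": self.model.family,
            "feature_method": self.model.feature_method,
            "class_weight": self.model.class_weight,
            "seed": self.model.seed,
            "params": self.model.params,
            "n_features": self.model.X.shape[1],
            "scaler": (self.scaler.mean, self.scaler.sd),
            "scorers": self.scorers,
            "train_class_counts": {s: int(np.sum(self.model.y == s)) for s in STAGES},
        }
        with open(path, "wb") as fh:
            pickle.dump(blob, fh)

    @classmethod
    def load(cls, path) -> "OvRStageResults":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        if blob.get("format_version") != SERIALIZATION_VERSION:
            raise ValueError(
                f"unsupported model format version {blob.get('format_version')}"
            )
        # rebuild a minimal model shell carrying the metadata
        d = blob["n_features"]
        shell = OvRStageModel.__new__(OvRStageModel)
        shell.X = np.zeros((0, d))
        shell.y = np.zeros(0, dtype=int)
        shell.family = blob["family"]
        shell.feature_method = blob["feature_method"]
        shell.class_weight = blob["class_weight"]
        shell.seed = blob["seed"]
        shell.params = blob["params"]
        mean, sd = blob["scaler"]
        results = cls(model=shell, scaler=FeatureScaler(mean, sd),
                      scorers=blob["scorers"])
        return results


def train_ovr(X, y, family: str = "ann", seed: int = 17,
              class_weight: str | None = None, feature_method: str = "",
              **params) -> OvRStageResults:
    """Functional shorthand: build an :class:`OvRStageModel` and fit it."""
    return OvRStageModel(X, y, family=family, feature_method=feature_method,
                         class_weight=class_weight, seed=seed, params=params).fit()


def design_grid_size(n_extractors: int = 9, n_families: int = 9) -> int:
    """Number of recognition systems in a full extractor x classifier sweep."""
    return n_extractors * n_families
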