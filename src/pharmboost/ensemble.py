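"""AdaBoost-boosted RBF-SVM ensembles for active/decoy pose classification.

The headline classifier boosts soft-margin RBF support-vector machines:

    initialise sample weights D_1(i) = 1/n;
    for t = 1..T:
        train an SVM whose per-sample misclassification cost is C*n*D_t(i)
        on the weight-trimmed sample set, with the kernel width sigma taken
        from the current sample set (adaptive mode) or fixed;
        eps_t = sum_i D_t(i) * 1[h_t(x_i) != y_i];  stop if eps_t >= 1/2;
        a_t = (1/2) ln((1 - eps_t)/eps_t);
        D_{t+1}(i) proportional to D_t(i) exp(-+ a_t), renormalised to 1;
    score(x) = sum_t a_t sign(f_t(x)),  predict = sign(score), ties -> decoy.

Boosting re-concentrates weight on misclassified samples, which is what gives
the ensemble its robustness to a minority of mislabeled (wrong-docking-pose)
positives mixed into a heavily imbalanced active/decoy training set.

The adaptive kernel width reads "the standard deviation of the sample set" as
the standard deviation of the samples as vectors: sigma = sqrt(trace of the
feature covariance), i.e. the RMS distance of samples from their mean.  For
independent samples E||x - z||^2 = 2 sigma^2 under this definition, so the
kernel sits at e^-1 for a typical pair and the width self-tunes to the data
scale regardless of dimensionality.  (Pooling the entries of the feature
matrix into one scalar std instead — sigma_scope="entrywise" — makes
E||x - z||^2/(2 sigma^2) equal the feature count, which saturates the kernel
for any high-dimensional fingerprint; it is kept as an option, as is the mean
of the per-feature stds.)

Plain-SVM and Random-Forest baselines expose the same score/predict contract.
Model classes follow the Model -> fit() -> Results pattern: construct from
arrays (or `from_samples` / `from_dataframe`), call ``fit()``, and use the
Results object for scoring, diagnostics and `summary()`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .errors import TrainingError

__all__ = [
    "LabeledSample",
    "BoostConfig",
    "SVMModel",
    "WeakLearner",
    "CascadeLayer",
    "AdaBoostSVM",
    "AdaBoostSVMResults",
    "PlainSVM",
    "PlainSVMResults",
    "RandomForestScreen",
    "RandomForestResults",
    "rbf_kernel",
    "compute_sigma",
    "train_weighted_svm",
    "weighted_error",
    "learner_weight",
    "update_weights",
    "trim_weights",
    "load_model",
]

SIGMA_FLOOR = 1e-12
EPSILON_MIN = 1e-10

SERIAL_FORMAT = "pharmboost-model"
SERIAL_VERSION = 1


@dataclass(frozen=True)
class LabeledSample:
    """A fingerprint row with its pose label (+1 active, -1 decoy)."""

    features: np.ndarray
    label: int
    sample_id: str = ""

    def __post_init__(self):
        if self.label not in (+1, -1):
            raise ValueError("label must be +1 or -1")


@dataclass(frozen=True)
class BoostConfig:
    """Ensemble hyperparameters.

    Defaults follow the reference settings for this screening protocol:
    5 boosting iterations, weight trim rate 0.9, up to 100 learners per
    cascade layer with max false-alarm 0.5 and min hit rate 0.9, SVM cost 5,
    and the fixed-sigma fallback 0.001.
    """

    n_iterations: int = 5
    max_learners_per_layer: int = 100
    weight_trim_rate: float = 0.9
    max_false_alarm: float = 0.5
    min_hit_rate: float = 0.9
    cost: float = 5.0
    sigma_mode: str = "adaptive_std"      # "adaptive_std" | "fixed"
    sigma_scope: str = "vector"           # "vector" | "entrywise" | "featurewise_mean"
    fixed_sigma: float = 0.001
    mode: str = "flat"                    # "flat" | "cascade"
    weak_learner: str = "full"            # "full" | "per_feature"
    seed: int = 0

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        for name in ("weight_trim_rate", "max_false_alarm", "min_hit_rate"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.cost <= 0 or self.fixed_sigma <= 0:
            raise ValueError("cost and fixed_sigma must be > 0")
        if self.sigma_mode not in ("adaptive_std", "fixed"):
            raise ValueError("sigma_mode must be 'adaptive_std' or 'fixed'")
        if self.mode not in ("flat", "cascade"):
            raise ValueError("mode must be 'flat' or 'cascade'")


# ---------------------------------------------------------------------------
# kernel / boosting primitives


def rbf_kernel(x: np.ndarray, z: np.ndarray, sigma: float) -> float:
    """Gaussian kernel K(x, z) = exp(-||x - z||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x = np.asarray(x, float).ravel()
    z = np.asarray(z, float).ravel()
    if x.shape != z.shape:
        raise ValueError("vectors must have equal length")
    return float(np.exp(-np.sum((x - z) ** 2) / (2.0 * sigma ** 2)))


def compute_sigma(X: np.ndarray, scope: str = "vector",
                  floor: float = SIGMA_FLOOR) -> float:
    """Kernel width from the sample set's standard deviation.

    scope="vector" (default): sqrt(sum of per-feature population variances) =
    RMS distance of samples from the mean vector.  "entrywise": population
    std of all matrix entries pooled.  "featurewise_mean": mean of the
    per-feature population stds.  Clamped below by ``floor``.
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if scope == "vector":
        sigma = float(np.sqrt(np.var(X, axis=0).sum()))
    elif scope == "entrywise":
        sigma = float(np.std(X))
    elif scope == "featurewise_mean":
        sigma = float(np.mean(np.std(X, axis=0)))
    else:
        raise ValueError(f"unknown sigma scope {scope!r}")
    if sigma < floor:
        warnings.warn("constant feature matrix: sigma clamped to floor",
                      stacklevel=2)
        sigma = floor
    return sigma


@dataclass
class SVMModel:
    """A fitted RBF-SVM in dual form: f(x) = sum_i a_i y_i K(x_i, x) + b."""

    support_vectors: np.ndarray
    dual_coefs: np.ndarray       # a_i * y_i
    bias: float
    sigma: float
    cost: float

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.support_vectors.shape[1]:
            raise ValueError(
                f"feature length {X.shape[1]} does not match "
                f"training length {self.support_vectors.shape[1]}")
        sq = cdist(X, self.support_vectors, metric="sqeuclidean")
        K = np.exp(-sq / (2.0 * self.sigma ** 2))
        return K @ self.dual_coefs + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Sign of the decision value; exact ties go to the decoy class."""
        return np.where(self.decision_function(X) > 0, 1, -1)


def train_weighted_svm(X: np.ndarray, y: np.ndarray,
                       weights: np.ndarray, sigma: float,
                       cost: float, n_total: int | None = None) -> SVMModel:
    """Soft-margin RBF-SVM with per-sample cost C * n * D(i).

    ``n_total`` is the size of the full boosting sample set; weight-trimmed
    subsets keep their original D(i) so trimming never rescales costs.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    weights = np.asarray(weights, float)
    if len(np.unique(y)) < 2:
        raise TrainingError("weighted SVM needs both classes present")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise TrainingError("sample weights must be non-negative with positive sum")
    n = n_total if n_total is not None else len(y)
    svc = SVC(C=cost, kernel="rbf", gamma=1.0 / (2.0 * sigma ** 2),
              tol=1e-3, cache_size=500)
    svc.fit(X, y, sample_weight=n * weights)
    return SVMModel(
        support_vectors=svc.support_vectors_.copy(),
        dual_coefs=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        sigma=float(sigma),
        cost=float(cost),
    )


def weighted_error(predictions: np.ndarray, labels: np.ndarray,
                   weights: np.ndarray) -> float:
    """eps = sum_i D(i) * 1[pred_i != y_i] (weighted indicator error)."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    weights = np.asarray(weights, float)
    if not predictions.shape == labels.shape == weights.shape:
        raise ValueError("predictions, labels and weights must share a shape")
    return float(weights[predictions != labels].sum())


def learner_weight(epsilon: float, epsilon_min: float = EPSILON_MIN) -> float:
    """a_t = (1/2) ln((1 - eps)/eps); eps = 0 is capped via epsilon_min."""
    if epsilon >= 0.5:
        if epsilon == 0.5:
            return 0.0
        raise ValueError("learner with eps > 0.5 carries no valid weight")
    eps = max(epsilon, epsilon_min)
    return 0.5 * np.log((1.0 - eps) / eps)


def update_weights(weights: np.ndarray, predictions: np.ndarray,
                   labels: np.ndarray, alpha: float) -> np.ndarray:
    """D_{t+1}(i) ~ D_t(i) exp(-a_t y_i h_t(x_i)), renormalised to sum 1."""
    weights = np.asarray(weights, float)
    correct = np.asarray(predictions) == np.asarray(labels)
    mult = np.where(correct, np.exp(-alpha), np.exp(alpha))
    new = weights * mult
    return new / new.sum()


def trim_weights(weights: np.ndarray, trim_rate: float) -> np.ndarray:
    """Boolean mask keeping the largest-weight samples whose cumulative
    weight first reaches ``trim_rate``; the rest sit out the next learner."""
    weights = np.asarray(weights, float)
    if not 0 < trim_rate <= 1:
        raise ValueError("trim_rate must be in (0, 1]")
    if trim_rate == 1.0:
        return np.ones(len(weights), bool)
    order = np.argsort(-weights, kind="stable")
    cum = np.cumsum(weights[order])
    # number of samples needed to reach the cumulative target
    k = int(np.searchsorted(cum, trim_rate * weights.sum() - 1e-15)) + 1
    mask = np.zeros(len(weights), bool)
    mask[order[:k]] = True
    return mask


# ---------------------------------------------------------------------------
# model classes


@dataclass
class WeakLearner:
    """One boosted component: SVM, its vote weight a_t and training error."""

    model: SVMModel
    alpha: float
    train_error: float
    iteration: int
    feature_subset: np.ndarray | None = None   # per-feature weak learner mode

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.feature_subset is not None:
            X = np.atleast_2d(np.asarray(X, float))[:, self.feature_subset]
        return self.model.predict(X)


@dataclass
class CascadeLayer:
    learners: list[WeakLearner]
    threshold: float

    def margin(self, X: np.ndarray) -> np.ndarray:
        return np.sum([w.alpha * w.predict(X) for w in self.learners], axis=0)


class _ArrayModelBase:
    """Shared constructors for array-backed models."""

    @classmethod
    def from_samples(cls, samples: Sequence[LabeledSample], **kwargs):
        X = np.vstack([s.features for s in samples])
        y = np.array([s.label for s in samples], int)
        return cls(X, y, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label", **kwargs):
        y = df[label_col].to_numpy(int)
        X = df.drop(columns=[label_col]).to_numpy(float)
        return cls(X, y, **kwargs)

    @staticmethod
    def _validate(X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if not set(np.unique(y)) <= {-1, 1}:
            raise ValueError("labels must be +1/-1")
        if len(np.unique(y)) < 2:
            raise TrainingError("both classes must be present")
        return X, y


class AdaBoostSVM(_ArrayModelBase):
    """AdaBoost over weighted RBF-SVM weak learners.

    Parameters
    ----------
    X, y : training feature matrix (fingerprint rows) and +1/-1 pose labels.
    config : BoostConfig, optional; keyword overrides are applied on top.
    """

    def __init__(self, X, y, config: BoostConfig | None = None, **overrides):
        self.X, self.y = self._validate(X, y)
        self.config = replace(config or BoostConfig(), **overrides)

    def fit(self) -> "AdaBoostSVMResults":
        if self.config.mode == "cascade":
            layers, history = self._fit_cascade()
            learners = [w for layer in layers for w in layer.learners]
        else:
            learners, history = self._fit_flat()
            layers = None
        if not learners:
            raise TrainingError(
                "no weak learner achieved eps < 0.5; training failed "
                f"(first eps: {history[0]['epsilon'] if history else 'n/a'})")
        return AdaBoostSVMResults(self, learners, layers, history)

    # -- flat (default) boosting loop

    def _fit_flat(self):
        cfg = self.config
        n = len(self.y)
        D = np.full(n, 1.0 / n)
        learners: list[WeakLearner] = []
        history: list[dict] = []
        for t in range(1, cfg.n_iterations + 1):
            mask = trim_weights(D, cfg.weight_trim_rate)
            learner, pred = self._train_weak(self.X, self.y, D, mask, t)
            eps = weighted_error(pred, self.y, D)
            history.append({"iteration": t, "epsilon": float(eps),
                            "sigma": learner.model.sigma,
                            "n_trained": int(mask.sum()),
                            "alpha": None})
            if eps >= 0.5:
                break
            alpha = learner_weight(eps)
            learner.alpha = alpha
            learner.train_error = eps
            history[-1]["alpha"] = float(alpha)
            learners.append(learner)
            if eps == 0.0:
                break               # perfect learner; no weight left to move
            D = update_weights(D, pred, self.y, alpha)
            history[-1]["weight_sum_after_update"] = float(D.sum())
            assert abs(D.sum() - 1.0) < 1e-9
        return learners, history

    def _train_weak(self, X, y, D, mask, iteration):
        cfg = self.config
        n = len(y)
        if len(np.unique(y[mask])) < 2:
            mask = np.ones(n, bool)     # trimming removed a class: train on all
        Xm, ym, Dm = X[mask], y[mask], D[mask]
        if cfg.weak_learner == "per_feature":
            best = None
            for j in range(X.shape[1]):
                sigma = self._sigma_for(Xm[:, [j]])
                try:
                    m = train_weighted_svm(Xm[:, [j]], ym, Dm, sigma,
                                           cfg.cost, n_total=n)
                except TrainingError:
                    continue
                pred = m.predict(X[:, [j]])
                eps = weighted_error(pred, y, D)
                if best is None or eps < best[0]:
                    best = (eps, j, m, pred)
            if best is None:
                raise TrainingError("no trainable feature column")
            _, j, m, pred = best
            learner = WeakLearner(m, 0.0, 1.0, iteration,
                                  feature_subset=np.array([j]))
            return learner, pred
        sigma = self._sigma_for(Xm)
        m = train_weighted_svm(Xm, ym, Dm, sigma, cfg.cost, n_total=n)
        pred = m.predict(X)
        return WeakLearner(m, 0.0, 1.0, iteration), pred

    def _sigma_for(self, Xm) -> float:
        cfg = self.config
        if cfg.sigma_mode == "fixed":
            return cfg.fixed_sigma
        return compute_sigma(Xm, scope=cfg.sigma_scope)

    # -- rejection cascade (optional mode)

    def _fit_cascade(self):
        cfg = self.config
        X, y = self.X, self.y
        active = np.ones(len(y), bool)
        layers: list[CascadeLayer] = []
        history: list[dict] = []
        for layer_idx in range(1, cfg.n_iterations + 1):
            if len(np.unique(y[active])) < 2:
                break
            Xa, ya = X[active], y[active]
            n = len(ya)
            D = np.full(n, 1.0 / n)
            learners: list[WeakLearner] = []
            margin = np.zeros(n)
            threshold, hit_rate, false_alarm = 0.0, 1.0, 1.0
            for t in range(1, cfg.max_learners_per_layer + 1):
                mask = trim_weights(D, cfg.weight_trim_rate)
                learner, pred = self._train_weak(Xa, ya, D, mask, t)
                eps = weighted_error(pred, ya, D)
                if eps >= 0.5:
                    break
                alpha = learner_weight(eps)
                learner.alpha, learner.train_error = alpha, eps
                learners.append(learner)
                margin = margin + alpha * pred
                if eps > 0.0:
                    D = update_weights(D, pred, ya, alpha)
                # layer threshold: keep at least min_hit_rate of actives
                pos = margin[ya == 1]
                threshold = float(np.quantile(pos, 1.0 - cfg.min_hit_rate,
                                              method="lower"))
                neg = margin[ya == -1]
                false_alarm = float(np.mean(neg >= threshold)) if len(neg) else 0.0
                hit_rate = float(np.mean(pos >= threshold))
                done = false_alarm <= cfg.max_false_alarm
                if done or eps == 0.0:
                    break
            if not learners:
                break
            layers.append(CascadeLayer(learners, threshold))
            history.append({"layer": layer_idx, "n_learners": len(learners),
                            "threshold": threshold, "hit_rate": hit_rate,
                            "false_alarm": false_alarm})
            passed = margin >= threshold
            new_active = np.zeros(len(y), bool)
            new_active[np.flatnonzero(active)[passed]] = True
            active = new_active
            if not np.any(active & (y == -1)):
                break
        return layers, history


class AdaBoostSVMResults:
    """Fitted boosted ensemble: learners, diagnostics, scoring, persistence."""

    def __init__(self, model: AdaBoostSVM, learners: list[WeakLearner],
                 layers: list[CascadeLayer] | None, history: list[dict]):
        self.model = model
        self.config = model.config
        self.learners = learners
        self.layers = layers
        self.history = history

    # -- scoring

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        """Screening margin sum_t a_t h_t(x) (cascade: cumulative margin over
        threshold, frozen at the rejecting layer)."""
        X = np.atleast_2d(np.asarray(X, float))
        if self.layers is None:
            return np.sum([w.alpha * w.predict(X) for w in self.learners], axis=0)
        score = np.zeros(len(X))
        alive = np.ones(len(X), bool)
        for layer in self.layers:
            if not alive.any():
                break
            m = layer.margin(X[alive]) - layer.threshold
            score[alive] += m
            keep = m >= 0
            alive[np.flatnonzero(alive)[~keep]] = False
        return score

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class prediction; margin 0 counts as decoy (conservative screening)."""
        if self.layers is None:
            return np.where(self.score_samples(X) > 0, 1, -1)
        X = np.atleast_2d(np.asarray(X, float))
        alive = np.ones(len(X), bool)
        for layer in self.layers:
            if not alive.any():
                break
            keep = layer.margin(X[alive]) - layer.threshold >= 0
            alive[np.flatnonzero(alive)[~keep]] = False
        return np.where(alive, 1, -1)

    # -- diagnostics

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([w.train_error for w in self.learners])

    @property
    def alphas(self) -> np.ndarray:
        return np.array([w.alpha for w in self.learners])

    def training_error(self) -> float:
        return float(np.mean(self.predict(self.model.X) != self.model.y))

    def training_error_bound(self) -> float:
        """AdaBoost bound prod_t 2 sqrt(eps_t (1 - eps_t)) on the training error."""
        eps = self.epsilons
        return float(np.prod(2.0 * np.sqrt(eps * (1.0 - eps))))

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "AdaBoost-SVM screening model",
            "=" * 64,
            f"mode: {cfg.mode}    weak learner: {cfg.weak_learner}    "
            f"sigma: {cfg.sigma_mode}/{cfg.sigma_scope}",
            f"samples: {len(self.model.y)} "
            f"({int((self.model.y == 1).sum())} active / "
            f"{int((self.model.y == -1).sum())} decoy)    "
            f"features: {self.model.X.shape[1]}",
            f"learners: {len(self.learners)}    cost C: {cfg.cost}",
            "-" * 64,
            f"{'t':>3} {'sigma':>12} {'eps_t':>10} {'a_t':>10} {'n_SV':>8}",
        ]
        for w in self.learners:
            lines.append(
                f"{w.iteration:>3} {w.model.sigma:>12.5g} "
                f"{w.train_error:>10.5f} {w.alpha:>10.5f} "
                f"{len(w.model.dual_coefs):>8d}")
        lines += [
            "-" * 64,
            f"training error: {self.training_error():.5f}   "
            f"(bound {self.training_error_bound():.5f})",
        ]
        return "\n".join(lines)

    # -- persistence (single self-describing JSON file)

    def save(self, path) -> None:
        doc = {
            "format": SERIAL_FORMAT,
            "version": SERIAL_VERSION,
            "kind": "adaboost_svm",
            "config": asdict(self.config),
            "history": self.history,
            "layers": (None if self.layers is None
                       else [{"n_learners": len(l.learners),
                              "threshold": l.threshold} for l in self.layers]),
            "learners": [_weak_to_doc(w) for w in self.learners],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def _from_doc(cls, doc) -> "AdaBoostSVMResults":
        learners = [_weak_from_doc(d) for d in doc["learners"]]
        layers = None
        if doc.get("layers") is not None:
            layers, i = [], 0
            for meta in doc["layers"]:
                n = meta["n_learners"]
                layers.append(CascadeLayer(learners[i:i + n], meta["threshold"]))
                i += n
        out = cls.__new__(cls)
        out.model = None
        out.config = BoostConfig(**doc["config"])
        out.learners = learners
        out.layers = layers
        out.history = doc["history"]
        return out


def _weak_to_doc(w: WeakLearner) -> dict:
    return {
        "alpha": w.alpha,
        "train_error": w.train_error,
        "iteration": w.iteration,
        "feature_subset": (None if w.feature_subset is None
                           else w.feature_subset.tolist()),
        "sigma": w.model.sigma,
        "cost": w.model.cost,
        "bias": w.model.bias,
        "dual_coefs": w.model.dual_coefs.tolist(),
        "support_vectors": w.model.support_vectors.tolist(),
    }


def _weak_from_doc(d: dict) -> WeakLearner:
    model = SVMModel(
        support_vectors=np.array(d["support_vectors"], float),
        dual_coefs=np.array(d["dual_coefs"], float),
        bias=d["bias"], sigma=d["sigma"], cost=d["cost"])
    subset = None if d["feature_subset"] is None else np.array(d["feature_subset"])
    return WeakLearner(model, d["alpha"], d["train_error"], d["iteration"],
                       feature_subset=subset)


# ---------------------------------------------------------------------------
# baselines


class PlainSVM(_ArrayModelBase):
    """Single C-SVM baseline (RBF kernel, cost 5, termination tolerance 1e-3).

    The reference parameterisation fixes sigma at 0.001; that width saturates
    the kernel on fingerprint-scale data, so the default here is the same
    adaptive width the ensemble uses, with ``sigma_mode="fixed"`` restoring
    the fixed value.
    """

    def __init__(self, X, y, cost: float = 5.0,
                 sigma_mode: str = "adaptive_std", fixed_sigma: float = 0.001,
                 sigma_scope: str = "vector"):
        self.X, self.y = self._validate(X, y)
        self.cost = cost
        self.sigma_mode = sigma_mode
        self.fixed_sigma = fixed_sigma
        self.sigma_scope = sigma_scope

    def fit(self) -> "PlainSVMResults":
        sigma = (self.fixed_sigma if self.sigma_mode == "fixed"
                 else compute_sigma(self.X, scope=self.sigma_scope))
        weights = np.full(len(self.y), 1.0 / len(self.y))
        svm = train_weighted_svm(self.X, self.y, weights, sigma, self.cost)
        return PlainSVMResults(self, svm)


class PlainSVMResults:
    def __init__(self, model: PlainSVM, svm: SVMModel):
        self.model = model
        self.svm = svm
        self.sigma = svm.sigma

    def score_samples(self, X) -> np.ndarray:
        return self.svm.decision_function(X)

    def predict(self, X) -> np.ndarray:
        return self.svm.predict(X)

    def training_error(self) -> float:
        return float(np.mean(self.predict(self.model.X) != self.model.y))

    def summary(self) -> str:
        return (
            "Plain RBF-SVM screening model\n"
            + "=" * 48 + "\n"
            f"samples: {len(self.model.y)}    features: {self.model.X.shape[1]}\n"
            f"cost C: {self.svm.cost}    sigma: {self.svm.sigma:.5g} "
            f"({self.model.sigma_mode})\n"
            f"support vectors: {len(self.svm.dual_coefs)}\n"
            f"training error: {self.training_error():.5f}"
        )

    def save(self, path) -> None:
        doc = {
            "format": SERIAL_FORMAT, "version": SERIAL_VERSION, "kind": "svm",
            "config": {"cost": self.model.cost,
                       "sigma_mode": self.model.sigma_mode,
                       "fixed_sigma": self.model.fixed_sigma,
                       "sigma_scope": self.model.sigma_scope},
            "svm": {"sigma": self.svm.sigma, "cost": self.svm.cost,
                    "bias": self.svm.bias,
                    "dual_coefs": self.svm.dual_coefs.tolist(),
                    "support_vectors": self.svm.support_vectors.tolist()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def _from_doc(cls, doc) -> "PlainSVMResults":
        s = doc["svm"]
        svm = SVMModel(np.array(s["support_vectors"], float),
                       np.array(s["dual_coefs"], float),
                       s["bias"], s["sigma"], s["cost"])
        out = cls.__new__(cls)
        out.model = None
        out.svm = svm
        out.sigma = svm.sigma
        return out


class RandomForestScreen(_ArrayModelBase):
    """Random-Forest baseline: 1000 trees, node size 5, 50 descriptors per split."""

    def __init__(self, X, y, n_trees: int = 1000, node_size: int = 5,
                 max_features: int = 50, seed: int = 0):
        self.X, self.y = self._validate(X, y)
        self.n_trees = n_trees
        self.node_size = node_size
        self.max_features = max_features
        self.seed = seed

    def fit(self) -> "RandomForestResults":
        forest = RandomForestClassifier(
            n_estimators=self.n_trees,
            min_samples_leaf=self.node_size,
            max_features=min(self.max_features, self.X.shape[1]),
            random_state=self.seed,
            n_jobs=1,
        )
        forest.fit(self.X, self.y)
        return RandomForestResults(self, forest)


class RandomForestResults:
    def __init__(self, model: RandomForestScreen, forest: RandomForestClassifier):
        self.model = model
        self.forest = forest

    def score_samples(self, X) -> np.ndarray:
        """Fraction of trees voting for the active class."""
        X = np.atleast_2d(np.asarray(X, float))
        active_col = int(np.flatnonzero(self.forest.classes_ == 1)[0])
        votes = np.zeros(len(X))
        for tree in self.forest.estimators_:
            votes += tree.predict(X) == self.forest.classes_[active_col]
        return votes / len(self.forest.estimators_)

    def predict(self, X) -> np.ndarray:
        return np.where(self.score_samples(X) > 0.5, 1, -1)

    def training_error(self) -> float:
        return float(np.mean(self.predict(self.model.X) != self.model.y))

    def summary(self) -> str:
        return (
            "Random-Forest screening baseline\n"
            + "=" * 48 + "\n"
            f"samples: {len(self.model.y)}    features: {self.model.X.shape[1]}\n"
            f"trees: {self.model.n_trees}    node size: {self.model.node_size}    "
            f"features/split: {self.model.max_features}\n"
            f"training error: {self.training_error():.5f}"
        )


def load_model(path):
    """Load a serialized AdaBoost-SVM or plain-SVM model file."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != SERIAL_FORMAT:
        raise ValueError(f"{path} is not a pharmboost model file")
    if doc["kind"] == "adaboost_svm":
        return AdaBoostSVMResults._from_doc(doc)
    if doc["kind"] == "svm":
        return PlainSVMResults._from_doc(doc)
    raise ValueError(f"unknown model kind {doc['kind']!r}")
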