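"""L2-penalized logistic regression trained by Newton/IRLS.

The classifier minimizes the summed negative log-likelihood plus
(l2/2)·||w||² with an unpenalized intercept.  The L2 constant is selected by
repeated random sub-sampling validation (five 90/10 inner splits per
candidate, argmax of mean validation accuracy, ties broken toward stronger
regularization).  Implemented as a scikit-learn estimator so it composes with
pipelines and model selection; the module-level functions mirror the
pipeline-stage surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted

from .features import ScalingParams
from .io import read_model_json, write_model_json

L2_CANDIDATES = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class ModelConfig:
    train_fraction: float = 0.9
    l2_candidates: tuple[float, ...] = L2_CANDIDATES
    tuning_repeats: int = 5
    inner_train_fraction: float = 0.9
    max_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.train_fraction, self.inner_train_fraction):
            if not 0 < f < 1:
                raise ValueError(f"fraction {f} outside (0, 1)")
        if any(c <= 0 for c in self.l2_candidates):
            raise ValueError("L2 candidates must be positive")


# ---------------------------------------------------------------------------
# Newton / IRLS logistic regression
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def penalized_nll(theta: np.ndarray, X: np.ndarray, y: np.ndarray, l2: float) -> float:
    """Summed negative log-likelihood + (l2/2)||w||²; theta = (w, b)."""
    w, b = theta[:-1], theta[-1]
    z = X @ w + b
    # log(1 + e^z) - y z, computed stably
    nll = np.logaddexp(0.0, z) - y * z
    return float(nll.sum() + 0.5 * l2 * (w @ w))


class NewtonLogisticClassifier(ClassifierMixin, BaseEstimator):
    """Binary logistic regression fit by damped Newton iterations.

    Parameters
    ----------
    l2 : quadratic penalty constant on the weights (intercept unpenalized),
        applied to the *summed* negative log-likelihood.
    max_iter : Newton iteration cap.
    tol : convergence threshold on the gradient norm.
    """

    def __init__(self, l2: float = 1.0, max_iter: int = 100, tol: float = 1e-8):
        self.l2 = l2
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in feature matrix")
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be 0/1")
        n, p = X.shape
        theta = np.zeros(p + 1)          # (w, b)
        penalty = np.full(p + 1, float(self.l2))
        penalty[-1] = 0.0                # intercept unpenalized
        obj = penalized_nll(theta, X, y, self.l2)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            z = X @ theta[:-1] + theta[-1]
            prob = _sigmoid(z)
            grad = np.empty(p + 1)
            resid = prob - y
            grad[:-1] = X.T @ resid + self.l2 * theta[:-1]
            grad[-1] = resid.sum()
            if np.linalg.norm(grad) < self.tol:
                converged = True
                break
            wgt = np.clip(prob * (1.0 - prob), 1e-12, None)
            Xw = X * wgt[:, None]
            hess = np.empty((p + 1, p + 1))
            hess[:-1, :-1] = X.T @ Xw
            hess[:-1, -1] = Xw.sum(axis=0)
            hess[-1, :-1] = hess[:-1, -1]
            hess[-1, -1] = wgt.sum()
            hess[np.diag_indices(p + 1)] += penalty
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(hess, grad, rcond=None)[0]
            # step halving keeps the objective monotone
            alpha = 1.0
            for _ in range(30):
                candidate = theta - alpha * step
                new_obj = penalized_nll(candidate, X, y, self.l2)
                if new_obj <= obj + 1e-12:
                    break
                alpha *= 0.5
            theta = theta - alpha * step
            obj = penalized_nll(theta, X, y, self.l2)
        else:
            it = self.max_iter
        # final gradient check when the loop ran out
        if not converged:
            z = X @ theta[:-1] + theta[-1]
            prob = _sigmoid(z)
            grad = np.empty(p + 1)
            grad[:-1] = X.T @ (prob - y) + self.l2 * theta[:-1]
            grad[-1] = (prob - y).sum()
            converged = bool(np.linalg.norm(grad) < self.tol)
        self.coef_ = theta[:-1]
        self.intercept_ = float(theta[-1])
        self.n_iter_ = it
        self.converged_ = converged
        self.classes_ = np.array([0.0, 1.0])
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        p1 = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(float)


# ---------------------------------------------------------------------------
# Trained-model container and persistence
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    weights: np.ndarray
    intercept: float
    l2: float
    feature_names: list[str]
    scaling: ScalingParams | None = None
    spec_checksum: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.feature_names):
            raise ValueError("weight vector length != feature count")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite weights")

    def predict_proba(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Per-row (P(derived), P(simulated)); columns must match training
        (any order; aligned by name)."""
        if set(matrix.columns) != set(self.feature_names):
            raise KeyError("feature columns do not match the trained model")
        if list(matrix.columns) != self.feature_names:
            matrix = matrix[self.feature_names]
        z = matrix.to_numpy(dtype=float) @ self.weights + self.intercept
        p_derived = _sigmoid(z)
        return pd.DataFrame(
            {"P_derived": p_derived, "P_simulated": 1.0 - p_derived},
            index=matrix.index,
        )

    def save(self, path) -> None:
        artifact = {
            "weights": list(map(float, self.weights)),
            "intercept": self.intercept,
            "l2": self.l2,
            "feature_names": self.feature_names,
            "scaling": self.scaling.to_dict() if self.scaling else None,
            "spec_checksum": self.spec_checksum,
            "metadata": self.metadata,
        }
        write_model_json(artifact, path)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        d = read_model_json(path)
        return cls(
            weights=np.array(d["weights"]),
            intercept=float(d["intercept"]),
            l2=float(d["l2"]),
            feature_names=list(d["feature_names"]),
            scaling=ScalingParams.from_dict(d["scaling"]) if d.get("scaling") else None,
            spec_checksum=d.get("spec_checksum"),
            metadata=d.get("metadata", {}),
        )


# ---------------------------------------------------------------------------
# Pipeline-stage functions
# ---------------------------------------------------------------------------

def split_train_test(n_rows: int, fraction: float = 0.9, seed: int = 0):
    """Uniform random partition into (train indices, test indices)."""
    if not 0 < fraction < 1:
        raise ValueError(f"fraction {fraction} outside (0, 1)")
    if n_rows < 10:
        raise ValueError("need at least 10 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_rows)
    n_train = int(round(fraction * n_rows))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def select_best_l2(mean_accuracies: dict[float, float]) -> float:
    """Argmax of mean accuracy; ties broken toward the larger (more
    regularized) candidate."""
    best = max(mean_accuracies.items(), key=lambda kv: (kv[1], kv[0]))
    return best[0]


def tune_l2(matrix, labels, config: ModelConfig | None = None):
    """Repeated random sub-sampling validation over the L2 candidates.

    Returns (best_l2, {candidate: mean accuracy}, {candidate: per-split
    accuracies}).
    """
    config = config or ModelConfig()
    if len(config.l2_candidates) < 2:
        if len(config.l2_candidates) == 1:
            only = config.l2_candidates[0]
            return only, {only: float("nan")}, {only: []}
        raise ValueError("need at least one L2 candidate")
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels, dtype=float)
    rng = np.random.default_rng(config.seed)
    split_seeds = rng.integers(0, 2**31 - 1, size=config.tuning_repeats)
    per_split: dict[float, list[float]] = {c: [] for c in config.l2_candidates}
    for split_seed in split_seeds:
        tr, va = split_train_test(len(y), config.inner_train_fraction, int(split_seed))
        for cand in config.l2_candidates:
            clf = NewtonLogisticClassifier(l2=cand, max_iter=config.max_iterations)
            clf.fit(X[tr], y[tr])
            if not clf.converged_:
                import warnings

                warnings.warn(
                    f"L2={cand}: Newton did not converge on an inner split; "
                    "accuracy recorded anyway"
                )
            acc = float((clf.predict(X[va]) == y[va]).mean())
            per_split[cand].append(acc)
    means = {c: float(np.mean(a)) for c, a in per_split.items()}
    return select_best_l2(means), means, per_split


def train_logistic(matrix, labels, l2: float = 1.0, max_iter: int = 100,
                   feature_names: list[str] | None = None,
                   scaling: ScalingParams | None = None,
                   spec_checksum: str | None = None,
                   seed: int | None = None) -> TrainedModel:
    if feature_names is None and isinstance(matrix, pd.DataFrame):
        feature_names = list(matrix.columns)
    clf = NewtonLogisticClassifier(l2=l2, max_iter=max_iter)
    clf.fit(np.asarray(matrix, dtype=float), np.asarray(labels, dtype=float))
    return TrainedModel(
        weights=clf.coef_,
        intercept=clf.intercept_,
        l2=l2,
        feature_names=feature_names or [f"f{i}" for i in range(matrix.shape[1])],
        scaling=scaling,
        spec_checksum=spec_checksum,
        metadata={
            "n_iterations": clf.n_iter_,
            "converged": clf.converged_,
            "seed": seed,
            "n_train_rows": int(np.asarray(matrix).shape[0]),
        },
    )


@dataclass
class EvaluationMetrics:
    accuracy: float
    roc_auc: float
    confusion: dict[str, int]


def evaluate(model: TrainedModel, matrix: pd.DataFrame, labels) -> EvaluationMetrics:
    """Held-out accuracy (0.5 threshold) and rank-based ROC-AUC (ties ½)."""
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: test labels contain a single class")
    proba = model.predict_proba(matrix)["P_derived"].to_numpy()
    pred = (proba >= 0.5).astype(float)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return EvaluationMetrics(
        accuracy=(tp + tn) / len(y),
        roc_auc=float(roc_auc_score(y, proba)),
        confusion={"TP": tp, "TN": tn, "FP": fp, "FN": fn},
    )


def feature_weight_report(model: TrainedModel, top_k: int | None = None) -> pd.DataFrame:
    """Features ranked by |weight|.  The sign is retained but carries no
    biological directionality (it reflects the feature encoding)."""
    df = pd.DataFrame({"feature": model.feature_names, "weight": model.weights})
    df["abs_weight"] = df["weight"].abs()
    df = df.sort_values(["abs_weight", "feature"], ascending=[False, True])
    df = df.drop(columns="abs_weight").reset_index(drop=True)
    return df.head(top_k) if top_k else df
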