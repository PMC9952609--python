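"""SVM muscle-fatigue classification on spectral EMG features.

A binary support-vector machine separates fatigued from fresh muscle using
the per-window mean frequency (MNF) and mean power (MNP).  Features are
z-scored with training-set statistics; the default kernel is RBF.  The
classifier's decision feeds a simple fatigue-torque mapping used by the
rehabilitation controller: when fatigue is detected a configurable fraction
of the subject's peak active torque is attributed to fatigue and subtracted
from the model torque.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import InputError, NotFittedError, ParameterError

__all__ = [
    "NONFATIGUE",
    "FATIGUE",
    "FatigueModel",
    "EvaluationReport",
    "train_svm",
    "predict_fatigue",
    "evaluate_classifier",
    "rank_features",
    "estimate_fatigue_torque",
    "save_model",
    "load_model",
]

NONFATIGUE = 0
FATIGUE = 1


@dataclass
class FatigueModel:
    """Fitted fatigue classifier: z-score scaler + SVM."""

    pipeline: Pipeline | None
    kernel: str
    params: dict
    feature_names: list

    @property
    def fitted(self) -> bool:
        return self.pipeline is not None and hasattr(
            self.pipeline.named_steps["svc"], "support_vectors_"
        )


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion-matrix metrics, percentages."""

    tp: int
    fp: int
    tn: int
    fn: int
    split: str = ""

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return 100.0 * (self.tp + self.tn) / total if total else float("nan")


def train_svm(
    features: np.ndarray,
    labels: np.ndarray,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma="scale",
    degree: int = 3,
    seed: int = 0,
    feature_names: list | None = None,
) -> FatigueModel:
    """Fit a max-margin classifier on standardized features.

    ``features`` is (n, d); ``labels`` binary (0 = nonfatigue, 1 = fatigue).
    Deterministic given the inputs and ``seed``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int).reshape(-1)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise InputError("features must be (n, d) with one label per row")
    if np.unique(y).size < 2:
        raise InputError("training set must contain both classes")
    pipe = Pipeline(
        [
            ("scaler", StandardScaler()),
            ("svc", SVC(kernel=kernel, C=C, gamma=gamma, degree=degree, random_state=seed)),
        ]
    )
    pipe.fit(X, y)
    names = list(feature_names) if feature_names else [f"f{i}" for i in range(X.shape[1])]
    return FatigueModel(
        pipeline=pipe,
        kernel=kernel,
        params={"C": C, "gamma": gamma, "degree": degree, "seed": seed},
        feature_names=names,
    )


def predict_fatigue(model: FatigueModel, features: np.ndarray):
    """Predict labels and decision margins for feature rows.

    Returns ``(labels, margins)``; positive margin means the fatigue side of
    the hyperplane.
    """
    if not model.fitted:
        raise NotFittedError("fatigue model has not been fitted")
    X = np.atleast_2d(np.asarray(features, dtype=float))
    labels = model.pipeline.predict(X)
    margins = model.pipeline.decision_function(X)
    return labels, margins


def evaluate_classifier(predictions, truth, split: str = "") -> EvaluationReport:
    """Exact confusion-matrix metrics (fatigue = positive class)."""
    pred = np.asarray(predictions).astype(int).reshape(-1)
    true = np.asarray(truth).astype(int).reshape(-1)
    if pred.size == 0:
        raise InputError("cannot evaluate on empty inputs")
    if pred.size != true.size:
        raise InputError("predictions and truth must have equal length")
    tp = int(np.sum((pred == FATIGUE) & (true == FATIGUE)))
    tn = int(np.sum((pred == NONFATIGUE) & (true == NONFATIGUE)))
    fp = int(np.sum((pred == FATIGUE) & (true == NONFATIGUE)))
    fn = int(np.sum((pred == NONFATIGUE) & (true == FATIGUE)))
    return EvaluationReport(tp=tp, fp=fp, tn=tn, fn=fn, split=split)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def rank_features(
    features: np.ndarray,
    labels: np.ndarray,
    n_bins: int = 10,
    feature_names: list | None = None,
):
    """Information-gain feature ranking.

    Each feature is quantile-binned into ``n_bins`` bins and scored by the
    reduction in label entropy; a constant feature scores 0.  Deterministic
    given the binning configuration.  Returns a list of ``(name, score)``
    sorted by decreasing score.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels).astype(int).reshape(-1)
    if X.shape[1] < 1:
        raise InputError("at least one feature required")
    names = list(feature_names) if feature_names else [f"f{i}" for i in range(X.shape[1])]
    classes = np.unique(y)
    h_y = _entropy(np.array([np.sum(y == c) for c in classes], dtype=float))
    scores = []
    for j in range(X.shape[1]):
        col = X[:, j]
        uniq, inv = np.unique(col, return_inverse=True)
        if uniq.size == 1:  # constant feature
            scores.append((names[j], 0.0))
            continue
        if uniq.size <= n_bins:
            bins = inv  # few distinct values: bin by value
        else:
            edges = np.quantile(col, np.linspace(0, 1, n_bins + 1))[1:-1]
            bins = np.searchsorted(edges, col, side="right")
        h_cond = 0.0
        for b in np.unique(bins):
            mask = bins == b
            w = mask.mean()
            h_cond += w * _entropy(
                np.array([np.sum(y[mask] == c) for c in classes], dtype=float)
            )
        scores.append((names[j], h_y - h_cond))
    return sorted(scores, key=lambda kv: -kv[1])


def estimate_fatigue_torque(
    fatigued,
    active_torque_max: float,
    delta: float = 0.3,
    margin: float | None = None,
    mode: str = "binary",
) -> float:
    """Torque decrement attributed to muscle fatigue, Nm.

    In ``binary`` mode the decrement is ``delta * active_torque_max`` when
    fatigue is detected and 0 otherwise.  In ``proportional`` mode the
    decrement scales with the positive decision margin, saturating at
    ``delta * active_torque_max`` for margins >= 1.
    """
    if not 0.0 <= delta <= 1.0:
        raise ParameterError("delta must lie in [0, 1]")
    if active_torque_max < 0:
        raise ParameterError("active_torque_max must be non-negative")
    cap = delta * active_torque_max
    if mode == "binary":
        return cap if int(fatigued) == FATIGUE else 0.0
    if mode == "proportional":
        if margin is None:
            raise ParameterError("proportional mode requires a decision margin")
        return cap * float(np.clip(margin, 0.0, 1.0))
    raise ParameterError(f"unknown mode {mode!r}")


def held_out_accuracy(
    seed: int,
    n_subjects: int = 57,
    windows_per_subject: int = 4,
    test_size: float = 0.3,
    kernel: str = "rbf",
) -> float:
    """Grouped held-out accuracy (%) of the default fatigue pipeline.

    Generates the synthetic fatigue dataset for ``seed``, splits it
    subject-wise (70/30 by default, so no subject's windows leak across the
    split), trains the standardized SVM on (MNF, MNP) and evaluates on the
    held-out subjects.
    """
    from sklearn.model_selection import GroupShuffleSplit

    from .synthetic import generate_fatigue_dataset

    df = generate_fatigue_dataset(
        n_subjects=n_subjects, windows_per_subject=windows_per_subject, seed=seed
    )
    X = df[["mnf_hz", "mnp"]].to_numpy()
    y = df["label"].to_numpy()
    groups = df["subject"].to_numpy()
    splitter = GroupShuffleSplit(n_splits=1, test_size=test_size, random_state=seed)
    train_idx, test_idx = next(splitter.split(X, y, groups))
    model = train_svm(X[train_idx], y[train_idx], kernel=kernel, seed=seed,
                      feature_names=["mnf_hz", "mnp"])
    pred, _ = predict_fatigue(model, X[test_idx])
    return evaluate_classifier(pred, y[test_idx], split="grouped 70/30").accuracy


# ---------------------------------------------------------------------------
# JSON persistence
# ---------------------------------------------------------------------------

def save_model(model: FatigueModel, path) -> None:
    """Persist a fitted model as JSON (scaler stats + support-vector data)."""
    if not model.fitted:
        raise NotFittedError("cannot save an unfitted model")
    scaler = model.pipeline.named_steps["scaler"]
    svc = model.pipeline.named_steps["svc"]
    doc = {
        "kernel": model.kernel,
        "params": {k: v for k, v in model.params.items()},
        "feature_names": model.feature_names,
        "scaler_mean": scaler.mean_.tolist(),
        "scaler_scale": scaler.scale_.tolist(),
        "support_vectors": svc.support_vectors_.tolist(),
        "dual_coef": svc.dual_coef_.tolist(),
        "intercept": svc.intercept_.tolist(),
        "gamma_value": float(svc._gamma),
        "coef0": float(svc.coef0),
        "degree": int(svc.degree),
        "classes": svc.classes_.tolist(),
        "n_support": svc.n_support_.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


class _FrozenSVM:
    """Decision function reconstructed from persisted support-vector data."""

    def __init__(self, doc):
        self.kernel = doc["kernel"]
        self.sv = np.asarray(doc["support_vectors"], dtype=float)
        self.dual = np.asarray(doc["dual_coef"], dtype=float)[0]
        self.b = float(doc["intercept"][0])
        self.gamma = float(doc["gamma_value"])
        self.coef0 = float(doc["coef0"])
        self.degree = int(doc["degree"])
        self.mean = np.asarray(doc["scaler_mean"], dtype=float)
        self.scale = np.asarray(doc["scaler_scale"], dtype=float)
        self.classes = np.asarray(doc["classes"], dtype=int)
        self.support_vectors_ = self.sv  # marks the model as fitted

    def _kernel(self, X):
        if self.kernel == "linear":
            return X @ self.sv.T
        if self.kernel == "rbf":
            d2 = (
                np.sum(X**2, axis=1)[:, None]
                + np.sum(self.sv**2, axis=1)[None, :]
                - 2 * X @ self.sv.T
            )
            return np.exp(-self.gamma * d2)
        if self.kernel == "poly":
            return (self.gamma * (X @ self.sv.T) + self.coef0) ** self.degree
        raise ParameterError(f"unsupported persisted kernel {self.kernel!r}")

    def decision_function(self, X):
        Z = (np.atleast_2d(np.asarray(X, dtype=float)) - self.mean) / self.scale
        return self._kernel(Z) @ self.dual + self.b

    def predict(self, X):
        df = self.decision_function(X)
        return np.where(df > 0, self.classes[1], self.classes[0])


def load_model(path) -> FatigueModel:
    """Load a persisted model; predictions match the original fitted pipeline."""
    doc = json.loads(Path(path).read_text())
    frozen = _FrozenSVM(doc)

    class _FrozenPipeline:
        named_steps = {"svc": frozen}

        @staticmethod
        def predict(X):
            return frozen.predict(X)

        @staticmethod
        def decision_function(X):
            return frozen.decision_function(X)

    model = FatigueModel(
        pipeline=None,
        kernel=doc["kernel"],
        params=doc["params"],
        feature_names=doc["feature_names"],
    )
    model.pipeline = _FrozenPipeline()  # type: ignore[assignment]
    return model
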