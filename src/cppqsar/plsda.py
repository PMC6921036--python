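"""PLS discriminant analysis for CPP/non-CPP classification.

PLS-DA regresses a 0/1 dummy response on the (autoscaled) descriptor
matrix via partial least squares and thresholds the continuous
prediction to assign a class.  Latent components are computed by the
NIPALS algorithm with deflation; predictive power is assessed by
cross-validated Q^2 (1 - PRESS/TSS) and, on held-out data, by
sensitivity, specificity, accuracy and Matthews correlation coefficient,
each expressed on a 0-100 scale.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

#: NIPALS convergence tolerance on the change in the weight vector.
NIPALS_TOL = 1e-10
#: NIPALS iteration cap per component.
NIPALS_MAX_ITER = 500
#: Default classification threshold on the continuous 0/1-coded response.
DEFAULT_THRESHOLD = 0.5


class SchemaError(ValueError):
    """Descriptor columns at prediction time do not match training."""


@dataclass
class ConfusionCounts:
    """2x2 confusion-matrix counts for binary classification."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        if yt.shape != yp.shape:
            raise ValueError("label arrays differ in shape")
        return cls(
            tp=int(np.sum((yt == 1) & (yp == 1))),
            tn=int(np.sum((yt == 0) & (yp == 0))),
            fp=int(np.sum((yt == 0) & (yp == 1))),
            fn=int(np.sum((yt == 1) & (yp == 0))),
        )


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, accuracy and MCC, each scaled to 0-100.

    sensitivity = 100 TP/(TP+FN); specificity = 100 TN/(TN+FP);
    accuracy = 100 (TP+TN)/total; MCC = 100 (TP TN - FP FN) /
    sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).  A metric whose denominator is
    zero is flagged undefined (NaN), never raised.
    """
    def _ratio(num: float, den: float) -> float:
        return math.nan if den == 0 else 100.0 * num / den

    mcc_den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    return {
        "sensitivity": _ratio(c.tp, c.tp + c.fn),
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "accuracy": _ratio(c.tp + c.tn, c.total),
        "mcc": math.nan if mcc_den == 0
        else 100.0 * (c.tp * c.tn - c.fp * c.fn) / mcc_den,
    }


# ---------------------------------------------------------------- NIPALS core


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """NIPALS PLS with deflation on centered X and centered univariate y.

    Returns weights W, X-loadings P and y-loadings q (one column/entry
    per component).  The start score vector is the X column of maximal
    variance; iteration stops when successive weight vectors differ by
    less than NIPALS_TOL in norm (for a univariate response this
    converges immediately, but the general loop is kept).
    """
    Xw = X.copy()
    yw = y.astype(float).copy()
    n_feat = X.shape[1]
    W = np.zeros((n_feat, n_components))
    P = np.zeros((n_feat, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        u = yw.copy()
        if not np.any(u):
            u = Xw[:, int(np.argmax(Xw.var(axis=0)))].copy()
        w_old = np.zeros(n_feat)
        for _ in range(NIPALS_MAX_ITER):
            w = Xw.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ArithmeticError(
                    f"NIPALS component {a + 1}: X carries no remaining signal"
                )
            w /= norm
            t = Xw @ w
            tt = t @ t
            if tt == 0:
                raise ArithmeticError(f"NIPALS component {a + 1}: zero score vector")
            qa = (yw @ t) / tt
            u = yw * qa if qa != 0 else t
            if np.linalg.norm(w - w_old) < NIPALS_TOL:
                break
            w_old = w
        else:
            raise ArithmeticError(
                f"NIPALS did not converge for component {a + 1} "
                f"within {NIPALS_MAX_ITER} iterations"
            )
        p = (Xw.T @ t) / tt
        W[:, a], P[:, a], q[a] = w, p, qa
        Xw -= np.outer(t, p)
        yw -= qa * t
    return W, P, q


@dataclass
class PLSDAModel:
    """Fitted PLS-DA classifier state.

    Stores everything prediction needs: per-component weights and
    loadings from NIPALS, the training-data centering/scaling statistics
    (frozen at fit time), the regression coefficients derived from them,
    the decision threshold and the training sequences (for test-set
    disjointness checks).
    """

    n_components: int
    feature_names: list[str]
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    coef: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    threshold: float = DEFAULT_THRESHOLD
    training_sequences: frozenset[str] = field(default_factory=frozenset)
    training_meta: dict = field(default_factory=dict)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise SchemaError(
                f"descriptor matrix has {X.shape[-1] if X.ndim == 2 else 'no'} "
                f"columns; model expects {len(self.feature_names)}: "
                f"{self.feature_names}"
            )
        Xs = (X - self.x_mean) / self.x_scale
        return self.y_mean + Xs @ self.coef

    def to_json(self, path) -> None:
        state = {
            "n_components": self.n_components,
            "feature_names": self.feature_names,
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "threshold": self.threshold,
            "training_sequences": sorted(self.training_sequences),
            "training_meta": self.training_meta,
        }
        with open(path, "w") as fh:
            json.dump(state, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PLSDAModel":
        with open(path) as fh:
            s = json.load(fh)
        return cls(
            n_components=s["n_components"],
            feature_names=list(s["feature_names"]),
            x_weights=np.array(s["x_weights"]),
            x_loadings=np.array(s["x_loadings"]),
            y_loadings=np.array(s["y_loadings"]),
            coef=np.array(s["coef"]),
            x_mean=np.array(s["x_mean"]),
            x_scale=np.array(s["x_scale"]),
            y_mean=s["y_mean"],
            threshold=s["threshold"],
            training_sequences=frozenset(s["training_sequences"]),
            training_meta=s["training_meta"],
        )


def fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    feature_names: list[str] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    training_sequences=(),
    autoscale: bool = True,
) -> PLSDAModel:
    """Fit a PLS-DA model on a descriptor matrix and 0/1 labels.

    X is centered and (by default) scaled to unit variance using training
    statistics only; constant descriptor columns are kept but given unit
    scale and a warning (their weight is necessarily zero after
    centering).  y is 0/1-coded and centered.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows and y length differ")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in training data")
    if n_components < 1 or n_components > min(X.shape):
        raise ValueError(f"n_components={n_components} out of range for shape {X.shape}")
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1) if autoscale else np.ones(X.shape[1])
    constant = x_scale == 0
    if np.any(constant):
        warnings.warn(
            "constant descriptor column(s) carry no information: "
            + ", ".join(np.asarray(feature_names)[constant]),
            stacklevel=2,
        )
        x_scale = np.where(constant, 1.0, x_scale)
    Xs = (X - x_mean) / x_scale
    y_mean = float(y.mean())

    W, P, q = _nipals_pls1(Xs, y - y_mean, n_components)
    # regression vector in the scaled X space: B = W (P'W)^-1 q
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSDAModel(
        n_components=n_components,
        feature_names=list(feature_names),
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=coef,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        threshold=threshold,
        training_sequences=frozenset(training_sequences),
        training_meta={"n_samples": int(X.shape[0]), "autoscale": autoscale},
    )


def predict(model: PLSDAModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous scores and thresholded class labels for new rows."""
    scores = model.decision_function(X)
    return scores, (scores >= model.threshold).astype(int)


def q2(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    folds: int = 7,
    seed: int = 0,
) -> float:
    """Cross-validated Q^2 = 1 - PRESS/TSS of the 0/1 response.

    Folds are assigned by a seeded shuffle; PRESS accumulates squared
    out-of-fold prediction errors, and TSS is the total sum of squares of
    y about its overall mean.  Every fold's training part must contain
    both classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if folds < 2 or folds > n:
        raise ValueError(f"folds must be in 2..{n}, got {folds}")
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(n) % folds
    press = 0.0
    for k in range(folds):
        test = assignment == k
        if not test.any():
            raise ValueError(f"fold {k} is empty")
        y_train = y[~test]
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"fold {k}: training part lacks one class")
        model = fit(X[~test], y_train, n_components)
        press += float(np.sum((y[test] - model.decision_function(X[test])) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss


def select_n_components(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 10,
    folds: int = 7,
    seed: int = 0,
) -> tuple[int, list[float]]:
    """Pick the component count maximizing Q^2 over 1..max_components."""
    cap = min(max_components, min(np.asarray(X).shape))
    trace = [q2(X, y, a, folds=folds, seed=seed) for a in range(1, cap + 1)]
    return int(np.argmax(trace)) + 1, trace


def evaluate(
    model: PLSDAModel,
    X_test: np.ndarray,
    y_test: np.ndarray,
    test_sequences=(),
) -> dict:
    """Confusion counts and the four performance metrics on held-out data.

    If ``test_sequences`` are supplied they are checked for overlap with
    the model's training sequences; any shared sequence is an evaluation
    protocol violation and raises.
    """
    overlap = model.training_sequences & frozenset(test_sequences)
    if overlap:
        raise ValueError(
            "test set overlaps training set: " + ", ".join(sorted(overlap)[:10])
        )
    _, labels = predict(model, X_test)
    counts = ConfusionCounts.from_labels(y_test, labels)
    return {"counts": asdict(counts), "metrics": confusion_metrics(counts)}
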