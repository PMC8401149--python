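"""Binary logistic regression, ROC/AUC and confusion-matrix metrics.

The solver is a self-contained iteratively reweighted least squares (Newton)
fit with internal z-score standardization, automatic ridge fallback on
detected separation, and an instrumented fit counter so elimination loops can
verify their iteration accounting exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .errors import ConvergenceError, DegenerateLabelsError, ValidationError

__all__ = [
    "LogisticModel",
    "ConfusionCounts",
    "MetricSet",
    "fit_logistic",
    "predict_proba",
    "roc_auc",
    "confusion_metrics",
    "score_reference",
    "fit_counter",
    "REFERENCE_INTERCEPT",
    "REFERENCE_COEFFICIENTS",
]

#: divergence guard on the standardized coefficient scale
SEPARATION_LIMIT = 15.0
RIDGE_LAMBDA = 1e-3
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 100


class _FitCounter:
    """Counts calls to :func:`fit_logistic`; reset/read from analysis loops."""

    def __init__(self) -> None:
        self.count = 0

    def reset(self) -> None:
        self.count = 0


fit_counter = _FitCounter()


@dataclass
class LogisticModel:
    """A fitted (or fixed-coefficient) binary logistic model.

    ``beta0``/``betas`` are on the standardized scale when ``standardization``
    is present; :attr:`raw_intercept`/:attr:`raw_coefficients` always give the
    raw-input-scale parameterization.
    """

    feature_names: Tuple[str, ...]
    beta0: float
    betas: np.ndarray
    standardization: Optional[Tuple[np.ndarray, np.ndarray]] = None
    converged: bool = True
    n_iterations: int = 0
    ridged: bool = False

    @property
    def raw_coefficients(self) -> np.ndarray:
        if self.standardization is None:
            return np.asarray(self.betas, dtype=float)
        _, scale = self.standardization
        return np.asarray(self.betas, dtype=float) / scale

    @property
    def raw_intercept(self) -> float:
        if self.standardization is None:
            return float(self.beta0)
        center, scale = self.standardization
        return float(self.beta0 - np.sum(self.betas * center / scale))

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.betas):
            raise ValidationError(
                f"expected {len(self.betas)} feature columns, got {X.shape[1]}"
            )
        if self.standardization is not None:
            center, scale = self.standardization
            X = (X - center) / scale
        return self.beta0 + X @ self.betas

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _expit(self.linear_predictor(X))

    def to_dict(self) -> dict:
        d = {
            "feature_names": list(self.feature_names),
            "intercept": float(self.raw_intercept),
            "coefficients": [float(b) for b in self.raw_coefficients],
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "ridged": bool(self.ridged),
        }
        if self.standardization is not None:
            center, scale = self.standardization
            d["standardization"] = {
                "center": [float(c) for c in center],
                "scale": [float(s) for s in scale],
            }
        return d


def _expit(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -35.0, 35.0)))


class _Separation(Exception):
    pass


def _irls(design, y, lam, tol, max_iter, guard):
    n, k = design.shape
    beta = np.zeros(k)
    ybar = min(max(float(y.mean()), 1e-6), 1.0 - 1e-6)
    beta[0] = math.log(ybar / (1.0 - ybar))
    penalty = np.full(k, lam)
    penalty[0] = 0.0  # never penalize the intercept
    for it in range(1, max_iter + 1):
        p = _expit(design @ beta)
        w = np.clip(p * (1.0 - p), 1e-10, None)
        grad = design.T @ (y - p) - penalty * beta
        H = (design * w[:, None]).T @ design + np.diag(penalty)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta += step
        if guard and np.max(np.abs(beta[1:])) > SEPARATION_LIMIT:
            raise _Separation
        if np.max(np.abs(step)) < tol:
            return beta, it, True
    return beta, max_iter, False


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Optional[Sequence[str]] = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    standardize: bool = True,
) -> LogisticModel:
    """Maximum-likelihood logistic fit via iteratively reweighted least squares.

    Features are z-scored on the training data before fitting.  If any
    standardized coefficient diverges past :data:`SEPARATION_LIMIT` (a
    separation signature), the model is refit with a small ridge penalty
    (lambda = 1e-3) and flagged ``ridged``.
    """
    fit_counter.count += 1
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ValidationError("X must be a 2-D case-by-feature matrix")
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y have different numbers of cases")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValidationError("labels must be binary 0/1")
    if len(classes) < 2:
        raise DegenerateLabelsError("labels contain a single class")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValidationError("need at least 2 cases of each class")

    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{i}" for i in range(X.shape[1])
    )
    if len(names) != X.shape[1]:
        raise ValidationError("feature_names length does not match X")

    standardization = None
    Xs = X
    if standardize:
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        if np.any(scale == 0.0):
            bad = [names[i] for i in np.nonzero(scale == 0.0)[0]]
            raise ValidationError(f"constant (zero-variance) feature(s): {bad}")
        Xs = (X - center) / scale
        standardization = (center, scale)

    design = np.hstack([np.ones((Xs.shape[0], 1)), Xs])
    ridged = False
    try:
        beta, n_iter, converged = _irls(design, y, 0.0, tol, max_iter, guard=True)
    except _Separation:
        beta, n_iter, converged = _irls(
            design, y, RIDGE_LAMBDA, tol, max_iter, guard=False
        )
        ridged = True
    if not converged:
        if not ridged:
            raise ConvergenceError(
                f"IRLS did not converge in {max_iter} iterations"
            )
        warnings.warn("ridge-penalized refit stopped at max_iter", RuntimeWarning)
    return LogisticModel(
        feature_names=names,
        beta0=float(beta[0]),
        betas=beta[1:],
        standardization=standardization,
        converged=converged,
        n_iterations=n_iter,
        ridged=ridged,
    )


def predict_proba(model: LogisticModel, X: np.ndarray) -> np.ndarray:
    """Probabilities from a fitted model (applies stored standardization)."""
    return model.predict_proba(X)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney) formulation; ties count one half.

    Equivalent to trapezoidal integration of the ROC curve over all
    thresholds.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels differ in length")
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise DegenerateLabelsError("AUC undefined: labels contain a single class")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    """Classification metrics as proportions in [0, 1]; ``None`` marks a
    metric whose denominator was zero (absent, never reported as 0)."""

    auc: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    accuracy: Optional[float] = None
    ppv: Optional[float] = None
    npv: Optional[float] = None

    METRICS = ("auc", "sensitivity", "specificity", "accuracy", "ppv", "npv")

    def as_percent(self) -> Dict[str, Optional[float]]:
        return {
            m: (None if getattr(self, m) is None else 100.0 * getattr(self, m))
            for m in self.METRICS
        }


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def confusion_metrics(
    probabilities: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
) -> Tuple[ConfusionCounts, MetricSet]:
    """Threshold probabilities and compute the six classification metrics.

    PPV = tp/(tp+fp) and NPV = tn/(tn+fn) (rendered x100 in reports); AUC is
    computed from the raw probabilities when both classes are present.
    """
    p = np.asarray(probabilities, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if p.size == 0:
        raise ValidationError("empty input")
    if p.shape != y.shape:
        raise ValidationError("probabilities and labels differ in length")
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValidationError("probabilities outside [0, 1]")
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must be in (0, 1)")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    counts = ConfusionCounts(tp, fp, tn, fn)
    try:
        auc = roc_auc(p, y)
    except DegenerateLabelsError:
        auc = None
    metrics = MetricSet(
        auc=auc,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        accuracy=_ratio(tp + tn, counts.total),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )
    return counts, metrics


# ---------------------------------------------------------------------------
# fixed-coefficient four-feature scorer
# ---------------------------------------------------------------------------

#: externally derived raw-scale coefficients of the four-feature frailty model
REFERENCE_INTERCEPT = 6.1883
REFERENCE_COEFFICIENTS: Dict[str, float] = {
    "standing_pct": -0.0885,
    "walking_pct": -0.1405,
    "walking_cadence": -0.0003,
    "longest_walking_bout": -0.0341,
}

_PLAUSIBLE_RANGES = {
    "standing_pct": (0.0, 100.0),
    "walking_pct": (0.0, 100.0),
    "walking_cadence": (0.0, 250.0),
    "longest_walking_bout": (0.0, 50000.0),
}


def reference_model() -> LogisticModel:
    """The fixed four-feature scorer as a raw-scale :class:`LogisticModel`."""
    return LogisticModel(
        feature_names=tuple(REFERENCE_COEFFICIENTS),
        beta0=REFERENCE_INTERCEPT,
        betas=np.array(list(REFERENCE_COEFFICIENTS.values())),
        standardization=None,
    )


def score_reference(
    standing_pct: float,
    walking_pct: float,
    cadence: float,
    longest_bout: float,
) -> float:
    """Frailty probability from the fixed-coefficient four-feature model.

    Inputs are raw (unstandardized) physical values: % of time standing, % of
    time walking, walking cadence in steps/min, and the longest walking bout
    in steps.  Out-of-range inputs trigger a warning but are still scored.
    """
    values = {
        "standing_pct": standing_pct,
        "walking_pct": walking_pct,
        "walking_cadence": cadence,
        "longest_walking_bout": longest_bout,
    }
    for name, v in values.items():
        lo, hi = _PLAUSIBLE_RANGES[name]
        if not lo <= v <= hi:
            warnings.warn(
                f"{name}={v} outside plausible range [{lo}, {hi}]", UserWarning
            )
    eta = REFERENCE_INTERCEPT + sum(
        REFERENCE_COEFFICIENTS[n] * values[n] for n in REFERENCE_COEFFICIENTS
    )
    return float(_expit(np.array(eta)))
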