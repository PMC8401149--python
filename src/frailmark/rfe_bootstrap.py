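"""Balanced bootstrap resampling and AUC-driven recursive feature elimination.

The analysis loop:

1. Build B balanced training/validation pairs: the majority class is
   subsampled without replacement to the minority size, the balanced pool is
   resampled with replacement to form the training set, and the pool's
   out-of-bag rows form the validation set.
2. With k active features, fit k candidate logistic models per pair, average
   each candidate's training AUC over pairs, and remove one feature per loop
   until ``l_stop`` features remain; the removal order fixes the ranking.
3. Re-fit the top-k sets along the ranking to trace metric curves (training
   and out-of-bag surfaces, mean with a 95% normal CI of the mean over pairs)
   and to validate the selected feature set out-of-bag.

The number of logistic fits is counted and must equal
``B * sum_{k=l_stop}^{a} k`` exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import DegenerateLabelsError, ValidationError
from .logit_core import MetricSet, confusion_metrics, fit_counter, fit_logistic, roc_auc
from .phenotype_models import SIGNIFICANT_FEATURES
from .synthetic_cohort import Cohort

__all__ = [
    "BootstrapPair",
    "EliminationTrace",
    "CurvePoint",
    "MetricSummary",
    "make_bootstrap_pairs",
    "run_rfe",
    "performance_curve",
    "select_optimal",
    "validate_final",
    "expected_fit_count",
]

log = logging.getLogger(__name__)

MAX_PAIR_REDRAWS = 100


@dataclass
class BootstrapPair:
    pair_id: int
    training: np.ndarray  # cohort row indices, resampled with replacement
    validation: np.ndarray  # out-of-bag rows of the balanced pool
    seed_state: Tuple[int, int]  # (seed, pair_id) reproducibility token
    n_redraws: int = 0


def expected_fit_count(a: int, l_stop: int, B: int) -> int:
    """Closed-form total fits: B * n * (a + l) / 2 with n = a - l + 1 loops."""
    n_loops = a - l_stop + 1
    return B * n_loops * (a + l_stop) // 2


def make_bootstrap_pairs(
    cohort: Cohort, B: int, seed: int = 0
) -> List[BootstrapPair]:
    """Create B balanced training/out-of-bag validation pairs.

    Whichever class is larger is subsampled (without replacement) down to the
    size of the smaller class before the with-replacement training draw, so
    every training set is exactly 50/50.  Pairs whose out-of-bag set is empty
    or single-class are redrawn, up to :data:`MAX_PAIR_REDRAWS` times.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    y = cohort.labels()
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    if len(idx0) == 0 or len(idx1) == 0:
        raise DegenerateLabelsError("cohort must contain both classes")
    if len(idx0) <= len(idx1):
        small, big = idx0, idx1
    else:
        small, big = idx1, idx0

    rng = np.random.default_rng(seed)
    pairs: List[BootstrapPair] = []
    for pair_id in range(B):
        for attempt in range(MAX_PAIR_REDRAWS + 1):
            sub = rng.choice(big, size=len(small), replace=False)
            pool = np.concatenate([small, sub])
            # stratified with-replacement draw keeps training exactly 50/50
            training = np.concatenate(
                [
                    rng.choice(small, size=len(small), replace=True),
                    rng.choice(sub, size=len(sub), replace=True),
                ]
            )
            oob = np.setdiff1d(pool, training)
            if len(oob) > 0 and len(np.unique(y[oob])) == 2:
                break
            log.debug("pair %d: degenerate out-of-bag set, redrawing", pair_id)
        else:
            raise ValidationError(
                f"pair {pair_id}: no valid out-of-bag split after "
                f"{MAX_PAIR_REDRAWS} redraws"
            )
        pairs.append(
            BootstrapPair(
                pair_id=pair_id,
                training=training,
                validation=oob,
                seed_state=(seed, pair_id),
                n_redraws=attempt,
            )
        )
    return pairs


@dataclass
class LoopRecord:
    active_features: Tuple[str, ...]
    mean_aucs: Dict[str, float]
    removed_feature: str


@dataclass
class EliminationTrace:
    loop_records: List[LoopRecord]
    final_ranking: Dict[str, int]  # feature -> rank, 1 = best
    fit_count: int
    criterion: str

    def ranked_features(self) -> List[str]:
        return sorted(self.final_ranking, key=self.final_ranking.get)


def run_rfe(
    cohort: Cohort,
    pairs: Sequence[BootstrapPair],
    features: Optional[Sequence[str]] = None,
    criterion: str = "leave_one_out",
    l_stop: int = 2,
) -> EliminationTrace:
    """Recursive feature elimination by mean training AUC over bootstrap pairs.

    criterion:
        ``"leave_one_out"`` (default): candidate model i omits feature i; the
        feature whose omission yields the *highest* mean AUC (the least-needed
        feature) is removed.
        ``"univariate"``: candidate model i contains only feature i; the
        feature with the *lowest* mean AUC is removed.

    Each loop with k active features performs exactly ``k * len(pairs)``
    logistic fits; the trace's ``fit_count`` is checked against the closed
    form.  Ties on mean AUC remove the feature with the larger input index.
    """
    if features is None:
        cols = tuple(cohort[0].features) if len(cohort) else ()
        if set(SIGNIFICANT_FEATURES) <= set(cols):
            features = list(SIGNIFICANT_FEATURES)
        else:
            features = list(cols)
    else:
        features = list(features)
    if len(set(features)) != len(features):
        raise ValidationError("duplicate feature names")
    if criterion not in ("leave_one_out", "univariate"):
        raise ValidationError(f"unknown criterion {criterion!r}")
    if not 2 <= l_stop <= len(features):
        raise ValidationError("need |features| >= l_stop >= 2")

    y = cohort.labels()
    X = cohort.feature_matrix(features)
    a = len(features)
    B = len(pairs)

    start_count = fit_counter.count
    active = list(range(a))
    records: List[LoopRecord] = []
    removal_order: List[int] = []

    while len(active) >= l_stop:
        k = len(active)
        sums = np.zeros(k)
        for pair in pairs:
            Xtr = X[pair.training]
            ytr = y[pair.training]
            for j, f in enumerate(active):
                if criterion == "leave_one_out":
                    cols = [c for c in active if c != f]
                else:
                    cols = [f]
                model = fit_logistic(Xtr[:, cols], ytr)
                sums[j] += roc_auc(model.predict_proba(Xtr[:, cols]), ytr)
        means = sums / B
        if criterion == "leave_one_out":
            best = means.max()
            candidates = [j for j in range(k) if means[j] >= best - 1e-15]
        else:
            worst = means.min()
            candidates = [j for j in range(k) if means[j] <= worst + 1e-15]
        # deterministic tie-break: drop the feature with the larger input index
        drop_pos = max(candidates, key=lambda j: active[j])
        removed = active[drop_pos]
        records.append(
            LoopRecord(
                active_features=tuple(features[i] for i in active),
                mean_aucs={features[i]: float(means[j]) for j, i in enumerate(active)},
                removed_feature=features[removed],
            )
        )
        log.info(
            "loop with %d features: removed %r (mean AUC %.4f)",
            k, features[removed], float(means[drop_pos]),
        )
        active.remove(removed)
        removal_order.append(removed)

    fits = fit_counter.count - start_count
    expected = expected_fit_count(a, l_stop, B)
    if fits != expected:
        raise RuntimeError(
            f"fit accounting mismatch: {fits} fits performed, expected {expected}"
        )

    # survivors (l_stop - 1 of them) outrank removals; later removal = better
    ranking: Dict[str, int] = {}
    rank = 1
    for i in active:
        ranking[features[i]] = rank
        rank += 1
    for i in reversed(removal_order):
        ranking[features[i]] = rank
        rank += 1
    return EliminationTrace(
        loop_records=records,
        final_ranking=ranking,
        fit_count=fits,
        criterion=criterion,
    )


@dataclass
class MetricSummary:
    """Mean and 95% CI of the mean, per metric, over bootstrap pairs."""

    mean: Dict[str, float]
    ci_lower: Dict[str, float]
    ci_upper: Dict[str, float]
    n_pairs: int
    n_skipped: int = 0


@dataclass
class CurvePoint:
    n_features: int
    features: Tuple[str, ...]
    training: MetricSummary
    validation: MetricSummary


def _summarize(per_pair: Dict[str, List[float]], n_pairs: int, n_skipped: int) -> MetricSummary:
    mean: Dict[str, float] = {}
    lo: Dict[str, float] = {}
    hi: Dict[str, float] = {}
    for metric, vals in per_pair.items():
        arr = np.array([v for v in vals if v is not None], dtype=float)
        if len(arr) == 0:
            continue
        m = float(arr.mean())
        half = 1.96 * float(arr.std(ddof=1)) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
        mean[metric], lo[metric], hi[metric] = m, m - half, m + half
    return MetricSummary(mean, lo, hi, n_pairs=n_pairs, n_skipped=n_skipped)


def _pair_metrics(model, X, y, idx, threshold) -> Dict[str, Optional[float]]:
    probs = model.predict_proba(X[idx])
    _, ms = confusion_metrics(probs, y[idx], threshold=threshold)
    return {m: getattr(ms, m) for m in MetricSet.METRICS}


def _evaluate_feature_set(
    X: np.ndarray,
    y: np.ndarray,
    cols: Sequence[int],
    pairs: Sequence[BootstrapPair],
    threshold: float,
) -> Tuple[MetricSummary, MetricSummary]:
    train_vals: Dict[str, List[float]] = {m: [] for m in MetricSet.METRICS}
    val_vals: Dict[str, List[float]] = {m: [] for m in MetricSet.METRICS}
    skipped = 0
    cols = list(cols)
    for pair in pairs:
        try:
            model = fit_logistic(X[pair.training][:, cols], y[pair.training])
        except (ValidationError, DegenerateLabelsError) as exc:
            log.warning("pair %d skipped: %s", pair.pair_id, exc)
            skipped += 1
            continue
        tm = _pair_metrics(model, X[:, cols], y, pair.training, threshold)
        vm = _pair_metrics(model, X[:, cols], y, pair.validation, threshold)
        for m in MetricSet.METRICS:
            train_vals[m].append(tm[m])
            val_vals[m].append(vm[m])
    n = len(pairs)
    return (
        _summarize(train_vals, n, skipped),
        _summarize(val_vals, n, skipped),
    )


def performance_curve(
    cohort: Cohort,
    pairs: Sequence[BootstrapPair],
    ranking: Dict[str, int],
    threshold: float = 0.5,
) -> List[CurvePoint]:
    """Metric curves along the ranking: top-k models for k = 1 .. |ranking|.

    Each point reports all six metrics on the training sets and on the
    out-of-bag validation sets, as mean and 95% CI of the mean over pairs.
    """
    ordered = sorted(ranking, key=ranking.get)
    y = cohort.labels()
    X = cohort.feature_matrix(ordered)
    points: List[CurvePoint] = []
    for k in range(1, len(ordered) + 1):
        train, val = _evaluate_feature_set(X, y, range(k), pairs, threshold)
        points.append(
            CurvePoint(
                n_features=k,
                features=tuple(ordered[:k]),
                training=train,
                validation=val,
            )
        )
    return points


def validate_final(
    cohort: Cohort,
    pairs: Sequence[BootstrapPair],
    feature_set: Sequence[str],
    threshold: float = 0.5,
) -> MetricSummary:
    """Out-of-bag validation of one feature set: fit per training set,
    evaluate on its held-out rows, summarize over pairs."""
    if len(feature_set) == 0:
        raise ValidationError("feature set must be non-empty")
    y = cohort.labels()
    X = cohort.feature_matrix(list(feature_set))
    _, val = _evaluate_feature_set(X, y, range(X.shape[1]), pairs, threshold)
    return val


def select_optimal(
    curve: Sequence[CurvePoint],
    ranking: Dict[str, int],
    auc_band: Tuple[float, float] = (0.7, 0.8),
    phenotype_coverage: bool = True,
    feature_classes: Optional[Dict[str, str]] = None,
) -> List[str]:
    """Smallest top-k feature set whose mean training AUC falls in the band.

    With ``phenotype_coverage`` on, the set must additionally contain at
    least one feature from every phenotype class present in the ranking.  If
    no k satisfies both constraints, the AUC-only solution is returned with a
    warning logged.
    """
    lo, hi = auc_band
    if not lo < hi:
        raise ValidationError("auc_band lower bound must be below upper bound")
    if feature_classes is None:
        from .synthetic_cohort import DEFAULT_FEATURES

        feature_classes = {f.name: f.phenotype_class for f in DEFAULT_FEATURES}
    classes_needed = {
        feature_classes[f] for f in ranking if f in feature_classes
    }
    ordered = sorted(ranking, key=ranking.get)

    auc_only: Optional[List[str]] = None
    for point in sorted(curve, key=lambda p: p.n_features):
        auc = point.training.mean.get("auc")
        if auc is None or not lo <= auc <= hi:
            continue
        top = list(ordered[: point.n_features])
        if auc_only is None:
            auc_only = top
        if not phenotype_coverage:
            return top
        covered = {feature_classes.get(f) for f in top}
        if classes_needed <= covered:
            return top
    if auc_only is not None:
        log.warning(
            "no feature count satisfies both the AUC band and phenotype "
            "coverage; returning the AUC-only solution"
        )
        return auc_only
    raise ValidationError(
        f"no point on the curve has mean training AUC within {auc_band}"
    )
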