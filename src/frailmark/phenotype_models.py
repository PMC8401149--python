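"""Fixed-feature-set logistic models for frailty and its phenotypes."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .errors import DegenerateLabelsError
from .logit_core import LogisticModel, fit_logistic, roc_auc
from .synthetic_cohort import Cohort

__all__ = [
    "PhenotypeModelSpec",
    "FittedPhenotypeModel",
    "PhenotypeFitResults",
    "model_feature_sets",
    "fit_phenotype_models",
    "SLOWNESS_WEAKNESS_FEATURES",
    "EXHAUSTION_FEATURES",
    "INACTIVITY_FEATURES",
    "SIGNIFICANT_FEATURES",
]

log = logging.getLogger(__name__)

SLOWNESS_WEAKNESS_FEATURES: Tuple[str, ...] = (
    "walking_cadence",
    "stand_to_sit_count",
    "stand_to_sit_duration",
    "sit_to_stand_count",
    "sit_to_stand_duration",
)
EXHAUSTION_FEATURES: Tuple[str, ...] = (
    "longest_walking_bout",
    "walking_steps_per_episode",
)
INACTIVITY_FEATURES: Tuple[str, ...] = (
    "walking_steps",
    "sitting_pct",
    "standing_pct",
    "walking_pct",
)

#: the eleven features that separate the groups; excludes ``lying_pct``,
#: the sole feature whose group difference is not significant
SIGNIFICANT_FEATURES: Tuple[str, ...] = (
    SLOWNESS_WEAKNESS_FEATURES + EXHAUSTION_FEATURES + INACTIVITY_FEATURES
)


@dataclass(frozen=True)
class PhenotypeModelSpec:
    model_name: str
    dependent: str  # outcome column: "frailty_status" or a phenotype flag
    features: Tuple[str, ...]


def model_feature_sets() -> Tuple[PhenotypeModelSpec, ...]:
    """The five fixed model definitions (outcome + feature list)."""
    return (
        PhenotypeModelSpec("physical_frailty", "frailty_status", SIGNIFICANT_FEATURES),
        PhenotypeModelSpec("slowness", "slowness", SLOWNESS_WEAKNESS_FEATURES),
        PhenotypeModelSpec("weakness", "weakness", SLOWNESS_WEAKNESS_FEATURES),
        PhenotypeModelSpec("exhaustion", "exhaustion", EXHAUSTION_FEATURES),
        PhenotypeModelSpec("inactivity", "inactivity", INACTIVITY_FEATURES),
    )


@dataclass
class FittedPhenotypeModel:
    spec: PhenotypeModelSpec
    model: LogisticModel
    auc: float  # in-sample


@dataclass
class PhenotypeFitResults:
    models: Dict[str, FittedPhenotypeModel]
    skipped: Dict[str, str]  # model name -> reason

    def auc_table(self) -> Dict[str, float]:
        return {name: fm.auc for name, fm in self.models.items()}


def fit_phenotype_models(
    cohort: Cohort,
    specs: Optional[Sequence[PhenotypeModelSpec]] = None,
) -> PhenotypeFitResults:
    """Fit each fixed model on the full cohort and report in-sample AUC.

    Phenotype outcomes are contrasted over all participants: robust rows
    count as phenotype-absent.  Outcomes with a single class are skipped with
    a logged reason rather than raising.
    """
    specs = tuple(specs) if specs is not None else model_feature_sets()
    models: Dict[str, FittedPhenotypeModel] = {}
    skipped: Dict[str, str] = {}
    for spec in specs:
        y = cohort.phenotype(spec.dependent)
        if len(np.unique(y)) < 2:
            reason = f"outcome {spec.dependent!r} has a single class"
            log.warning("skipping model %s: %s", spec.model_name, reason)
            skipped[spec.model_name] = reason
            continue
        X = cohort.feature_matrix(spec.features)
        try:
            model = fit_logistic(X, y, feature_names=spec.features)
        except DegenerateLabelsError as exc:  # pragma: no cover - guarded above
            skipped[spec.model_name] = str(exc)
            continue
        auc = roc_auc(model.predict_proba(X), y)
        models[spec.model_name] = FittedPhenotypeModel(spec, model, auc)
    return PhenotypeFitResults(models=models, skipped=skipped)
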