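"""Seedable synthetic cohorts of pendant-sensor physical-activity features.

The generator produces participant tables with a configurable two-group
structure (robust vs pre-frail/frail), five binary phenotype flags, and
twelve activity features whose per-group means and standard deviations match
the configured targets.  The four posture percentages are generated on the
compositional simplex (they sum to at most 100), and phenotype flags are
coupled to the features of their phenotype class so that phenotype-level
classifiers are learnable from synthetic data.

Distributional choices
----------------------
* Non-posture features with moderate coefficient of variation are drawn from
  moment-matched truncated normals (truncation at the support bounds).
* Heavily right-skewed count features (``longest_walking_bout``,
  ``walking_steps``) are drawn from moment-matched log-normals; their
  coefficient of variation exceeds 1, which a zero-truncated normal cannot
  reach.
* The four posture percentages are drawn jointly from a degenerate Gaussian
  whose per-feature deviations close a (folded) polygon, so the row sum is
  constant and the marginal moments are exact despite the simplex constraint.

Phenotype coupling is mean-preserving within the frail group: members whose
class flag is on are shifted further from the robust mean, members whose flag
is off are shifted back toward it, and the base spread is shrunk so the
frail-group mixture keeps the configured mean and SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Dict, Iterator, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ValidationError

__all__ = [
    "FeatureSpec",
    "CohortSpec",
    "Participant",
    "Cohort",
    "PHENOTYPES",
    "POSTURE_FEATURES",
    "FEATURE_NAMES",
    "CLASS_PHENOTYPES",
    "default_cohort_spec",
    "generate_cohort",
    "phenotype_coupling",
    "canonical_feature_name",
]

PHENOTYPES: Tuple[str, ...] = (
    "slowness",
    "weakness",
    "exhaustion",
    "weight_loss",
    "inactivity",
)

#: phenotype flags that activate each feature class
CLASS_PHENOTYPES: Dict[str, Tuple[str, ...]] = {
    "slowness_weakness": ("slowness", "weakness"),
    "exhaustion": ("exhaustion",),
    "inactivity": ("inactivity",),
}

POSTURE_FEATURES: Tuple[str, ...] = (
    "sitting_pct",
    "standing_pct",
    "walking_pct",
    "lying_pct",
)


@dataclass(frozen=True)
class FeatureSpec:
    """Per-feature generation parameters: units, class, and group moments."""

    name: str
    unit: str
    phenotype_class: str
    rg_mean: float
    rg_sd: float
    fg_mean: float
    fg_sd: float
    support: str = "nonnegative"  # "nonnegative" | "percentage"
    distribution: str = "truncnorm"  # "truncnorm" | "lognormal"

    def validate(self) -> None:
        if self.rg_sd <= 0 or self.fg_sd <= 0:
            raise ValidationError(f"{self.name}: standard deviations must be > 0")
        if self.phenotype_class not in CLASS_PHENOTYPES:
            raise ValidationError(
                f"{self.name}: unknown phenotype class {self.phenotype_class!r}"
            )
        if self.support not in ("nonnegative", "percentage"):
            raise ValidationError(f"{self.name}: unknown support {self.support!r}")
        if self.distribution not in ("truncnorm", "lognormal"):
            raise ValidationError(
                f"{self.name}: unknown distribution {self.distribution!r}"
            )
        if self.support == "percentage":
            for m in (self.rg_mean, self.fg_mean):
                if not 0.0 <= m <= 100.0:
                    raise ValidationError(
                        f"{self.name}: percentage mean {m} outside [0, 100]"
                    )

    @property
    def bounds(self) -> Tuple[float, float]:
        return (0.0, 100.0) if self.support == "percentage" else (0.0, math.inf)


def _fs(name, unit, cls, rgm, rgs, fgm, fgs, support="nonnegative", dist="truncnorm"):
    return FeatureSpec(name, unit, cls, rgm, rgs, fgm, fgs, support, dist)


DEFAULT_FEATURES: Tuple[FeatureSpec, ...] = (
    _fs("walking_cadence", "steps/min", "slowness_weakness", 115.3, 9.0, 108.8, 16.2),
    _fs("stand_to_sit_count", "n", "slowness_weakness", 134.2, 70.8, 114.3, 59.9),
    _fs("stand_to_sit_duration", "s", "slowness_weakness", 3.9, 0.6, 4.3, 1.2),
    _fs("sit_to_stand_count", "n", "slowness_weakness", 137.0, 66.0, 117.1, 59.0),
    _fs("sit_to_stand_duration", "s", "slowness_weakness", 3.9, 0.6, 4.6, 1.5),
    _fs("longest_walking_bout", "steps", "exhaustion", 1372.7, 1702.5, 472.9, 749.8,
        dist="lognormal"),
    _fs("walking_steps_per_episode", "steps", "exhaustion", 32.5, 18.9, 25.4, 13.8),
    _fs("walking_steps", "steps", "inactivity", 4788.5, 2667.6, 3004.6, 2531.5,
        dist="lognormal"),
    _fs("sitting_pct", "%", "inactivity", 34.3, 11.0, 37.6, 13.9, support="percentage"),
    _fs("standing_pct", "%", "inactivity", 17.9, 4.8, 13.7, 5.5, support="percentage"),
    _fs("walking_pct", "%", "inactivity", 6.8, 3.1, 4.3, 3.0, support="percentage"),
    _fs("lying_pct", "%", "inactivity", 41.0, 12.3, 44.4, 16.4, support="percentage"),
)

FEATURE_NAMES: Tuple[str, ...] = tuple(f.name for f in DEFAULT_FEATURES)

_DISPLAY_ALIASES: Dict[str, str] = {
    "walking cadence": "walking_cadence",
    "number of stand-to-sit": "stand_to_sit_count",
    "duration of stand-to-sit": "stand_to_sit_duration",
    "number of sit-to-stand": "sit_to_stand_count",
    "duration of sit-to-stand": "sit_to_stand_duration",
    "longest walking bout": "longest_walking_bout",
    "walking steps per episode": "walking_steps_per_episode",
    "walking steps": "walking_steps",
    "% of sitting": "sitting_pct",
    "% of standing": "standing_pct",
    "% of walking": "walking_pct",
    "% of lying": "lying_pct",
}


def canonical_feature_name(name: str, known: Sequence[str] = ()) -> str:
    """Map a display name like ``"% of sitting"`` to its snake_case column.

    ``known`` extends the default feature registry with additional valid
    names (e.g. the columns of a custom cohort specification).
    """
    if name in known:
        return name
    key = name.strip().lower()
    if key in _DISPLAY_ALIASES:
        return _DISPLAY_ALIASES[key]
    snake = key.replace(" ", "_").replace("-", "_")
    if snake in FEATURE_NAMES or snake in known:
        return snake
    raise KeyError(f"unknown feature name: {name!r}")


DEFAULT_PREVALENCE: Dict[str, float] = {
    "slowness": 0.694,
    "weakness": 0.640,
    "exhaustion": 0.301,
    "weight_loss": 0.091,
    "inactivity": 0.403,
}

# (mean, sd) pairs for continuous demographics, female fraction for gender
DEFAULT_DEMOGRAPHICS: Dict[str, Dict[str, object]] = {
    "rg": {
        "age": (74.4, 6.6),
        "height_cm": (165.1, 8.9),
        "weight_kg": (74.8, 19.0),
        "bmi": (24.6, 8.0),
        "female_fraction": 0.726,
    },
    "fg": {
        "age": (76.6, 8.4),
        "height_cm": (163.3, 10.1),
        "weight_kg": (79.2, 17.9),
        "bmi": (29.1, 8.0),
        "female_fraction": 0.618,
    },
}


@dataclass
class CohortSpec:
    """Full parameterization of a synthetic cohort."""

    n_robust: int = 73
    n_frail: int = 186
    phenotype_prevalence: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    feature_specs: Tuple[FeatureSpec, ...] = DEFAULT_FEATURES
    within_group_correlation: float = 0.3
    coupling_strength: float = 0.35
    seed: int = 0
    demographics: Dict[str, Dict[str, object]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_DEMOGRAPHICS.items()}
    )

    def validate(self) -> None:
        if self.n_robust < 0 or self.n_frail < 0:
            raise ValidationError("group counts must be >= 0")
        for name, p in self.phenotype_prevalence.items():
            if name not in PHENOTYPES:
                raise ValidationError(f"unknown phenotype {name!r}")
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"prevalence for {name} outside [0, 1]: {p}")
        if not 0.0 <= self.within_group_correlation < 1.0:
            raise ValidationError("within_group_correlation must be in [0, 1)")
        if self.coupling_strength < 0.0:
            raise ValidationError("coupling_strength must be >= 0")
        seen = set()
        for fs in self.feature_specs:
            fs.validate()
            if fs.name in seen:
                raise ValidationError(f"duplicate feature {fs.name!r}")
            seen.add(fs.name)
        _coupling_table(self)  # raises if coupling is infeasible for any feature

    @property
    def feature_names(self) -> Tuple[str, ...]:
        return tuple(fs.name for fs in self.feature_specs)

    def feature(self, name: str) -> FeatureSpec:
        canon = canonical_feature_name(name, known=self.feature_names)
        for fs in self.feature_specs:
            if fs.name == canon:
                return fs
        raise KeyError(f"feature {name!r} not in spec")

    def to_dict(self) -> dict:
        return {
            "n_robust": self.n_robust,
            "n_frail": self.n_frail,
            "phenotype_prevalence": dict(self.phenotype_prevalence),
            "within_group_correlation": self.within_group_correlation,
            "coupling_strength": self.coupling_strength,
            "seed": self.seed,
            "demographics": {g: dict(v) for g, v in self.demographics.items()},
            "feature_specs": [
                {
                    "name": fs.name,
                    "unit": fs.unit,
                    "phenotype_class": fs.phenotype_class,
                    "rg_mean": fs.rg_mean,
                    "rg_sd": fs.rg_sd,
                    "fg_mean": fs.fg_mean,
                    "fg_sd": fs.fg_sd,
                    "support": fs.support,
                    "distribution": fs.distribution,
                }
                for fs in self.feature_specs
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        d = dict(d)
        feats = d.pop("feature_specs", None)
        spec = cls(**{k: v for k, v in d.items() if k != "feature_specs"})
        if feats is not None:
            spec.feature_specs = tuple(FeatureSpec(**f) for f in feats)
        # demographics tuples survive YAML round-trips as lists
        spec.demographics = {
            g: {k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in dd.items()}
            for g, dd in spec.demographics.items()
        }
        return spec


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Cohort spec with the default two-group feature moments and prevalences."""
    return CohortSpec(seed=seed)


@dataclass
class Participant:
    id: str
    age: float
    gender: str
    height: float
    weight: float
    bmi: float
    frailty_status: int
    phenotypes: Dict[str, int]
    features: Dict[str, float]

    def validate(self) -> None:
        n_flags = sum(self.phenotypes.get(p, 0) for p in PHENOTYPES)
        if self.frailty_status != int(n_flags >= 1):
            raise ValidationError(
                f"{self.id}: frailty_status inconsistent with phenotype flags"
            )
        posture = [self.features[f] for f in POSTURE_FEATURES if f in self.features]
        if posture:
            if any(not 0.0 <= v <= 100.0 for v in posture):
                raise ValidationError(f"{self.id}: posture percentage outside [0, 100]")
            if sum(posture) > 100.0 + 1e-9:
                raise ValidationError(f"{self.id}: posture percentages sum above 100")
        for name, v in self.features.items():
            if v < 0:
                raise ValidationError(f"{self.id}: negative feature {name}")


DEMOGRAPHIC_COLUMNS = ("id", "age", "gender", "height_cm", "weight_kg", "bmi")
COHORT_COLUMNS = DEMOGRAPHIC_COLUMNS + ("frailty_status",) + PHENOTYPES + FEATURE_NAMES


@dataclass
class Cohort:
    """An ordered collection of participants with array/table accessors."""

    participants: list

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self) -> Iterator[Participant]:
        return iter(self.participants)

    def __getitem__(self, i):
        return self.participants[i]

    def labels(self) -> np.ndarray:
        return np.array([p.frailty_status for p in self.participants], dtype=int)

    def phenotype(self, name: str) -> np.ndarray:
        if name == "frailty_status" or name == "physical_frailty":
            return self.labels()
        if name not in PHENOTYPES:
            raise KeyError(f"unknown phenotype {name!r}")
        return np.array([p.phenotypes[name] for p in self.participants], dtype=int)

    def _feature_columns(self) -> Tuple[str, ...]:
        return tuple(self.participants[0].features) if self.participants else ()

    def feature_matrix(self, names: Sequence[str]) -> np.ndarray:
        known = self._feature_columns()
        names = [canonical_feature_name(n, known=known) for n in names]
        return np.array(
            [[p.features[n] for n in names] for p in self.participants], dtype=float
        )

    def values(self, feature: str, group: Optional[int] = None) -> np.ndarray:
        name = canonical_feature_name(feature, known=self._feature_columns())
        vals = np.array([p.features[name] for p in self.participants], dtype=float)
        if group is None:
            return vals
        return vals[self.labels() == group]

    def to_frame(self) -> pd.DataFrame:
        feature_names = (
            tuple(self.participants[0].features) if self.participants else FEATURE_NAMES
        )
        rows = []
        for p in self.participants:
            row = {
                "id": p.id,
                "age": p.age,
                "gender": p.gender,
                "height_cm": p.height,
                "weight_kg": p.weight,
                "bmi": p.bmi,
                "frailty_status": p.frailty_status,
            }
            row.update({ph: p.phenotypes[ph] for ph in PHENOTYPES})
            row.update({f: p.features[f] for f in feature_names})
            rows.append(row)
        cols = DEMOGRAPHIC_COLUMNS + ("frailty_status",) + PHENOTYPES + feature_names
        return pd.DataFrame(rows, columns=list(cols))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, validate: bool = True) -> "Cohort":
        feature_cols = [c for c in df.columns if c in FEATURE_NAMES]
        participants = []
        for _, r in df.iterrows():
            p = Participant(
                id=str(r["id"]),
                age=float(r["age"]),
                gender=str(r["gender"]),
                height=float(r["height_cm"]),
                weight=float(r["weight_kg"]),
                bmi=float(r["bmi"]),
                frailty_status=int(r["frailty_status"]),
                phenotypes={ph: int(r[ph]) for ph in PHENOTYPES},
                features={f: float(r[f]) for f in feature_cols},
            )
            if validate:
                p.validate()
            participants.append(p)
        return cls(participants)


# ---------------------------------------------------------------------------
# distribution fitting helpers
# ---------------------------------------------------------------------------

_TRUNCNORM_CACHE: Dict[Tuple[float, float, float, float], Tuple[float, float]] = {}


def _truncnorm_params(mean: float, sd: float, lo: float, hi: float) -> Tuple[float, float]:
    """Underlying (mu, sigma) so the [lo, hi]-truncated normal has the target moments."""
    key = (round(mean, 10), round(sd, 10), lo, hi)
    if key in _TRUNCNORM_CACHE:
        return _TRUNCNORM_CACHE[key]
    lo_z = (mean - lo) / sd
    hi_z = (hi - mean) / sd if math.isfinite(hi) else math.inf
    if lo_z > 6.0 and hi_z > 6.0:  # truncation mass is negligible
        _TRUNCNORM_CACHE[key] = (mean, sd)
        return mean, sd
    if sd / max(mean - lo, 1e-12) > 0.99 and not math.isfinite(hi):
        raise ValidationError(
            f"coefficient of variation {sd / (mean - lo):.2f} unreachable for a "
            "zero-truncated normal; use a log-normal distribution"
        )

    def residual(x):
        mu, log_sigma = x
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma if math.isfinite(hi) else math.inf
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.root(residual, [mean, math.log(sd)], method="hybr")
    if not sol.success or max(abs(r) for r in residual(sol.x)) > 1e-6 * max(sd, 1.0):
        raise ValidationError(
            f"could not moment-match truncated normal for mean={mean}, sd={sd}"
        )
    out = (float(sol.x[0]), float(math.exp(sol.x[1])))
    _TRUNCNORM_CACHE[key] = out
    return out


_CENSNORM_CACHE: Dict[Tuple[float, float], Tuple[float, float]] = {}


def _censored_normal_params(mean: float, sd: float) -> Tuple[float, float]:
    """Latent (mu, sigma) so that max(N(mu, sigma), 0) has the target moments.

    Used for posture percentages: the latent Gaussian keeps the compositional
    row sum exactly constant, while clipping at zero would otherwise bias the
    marginal moments of low-mean components.
    """
    key = (round(mean, 10), round(sd, 10))
    if key in _CENSNORM_CACHE:
        return _CENSNORM_CACHE[key]
    if mean / sd > 6.0:  # censoring mass is negligible
        _CENSNORM_CACHE[key] = (mean, sd)
        return mean, sd

    def moments(mu, sigma):
        a = mu / sigma
        phi, Phi = stats.norm.pdf(a), stats.norm.cdf(a)
        m1 = mu * Phi + sigma * phi
        m2 = (mu**2 + sigma**2) * Phi + mu * sigma * phi
        return m1, math.sqrt(max(m2 - m1**2, 1e-12))

    def residual(x):
        m1, s1 = moments(x[0], math.exp(x[1]))
        return [m1 - mean, s1 - sd]

    sol = optimize.root(residual, [mean, math.log(sd)], method="hybr")
    if not sol.success or max(abs(r) for r in residual(sol.x)) > 1e-8 * max(sd, 1.0):
        raise ValidationError(
            f"could not moment-match censored normal for mean={mean}, sd={sd}"
        )
    out = (float(sol.x[0]), float(math.exp(sol.x[1])))
    _CENSNORM_CACHE[key] = out
    return out


def _censored_mean_location(sigma: float, target_mean: float) -> float:
    """Latent location so that E[max(N(mu, sigma), 0)] equals ``target_mean``.

    The censored mean is strictly positive, so targets at or below zero are
    clamped to a small positive fraction of sigma.
    """
    target_mean = max(target_mean, 0.01 * sigma)
    if target_mean / sigma > 6.0:
        return target_mean

    def f(mu):
        a = mu / sigma
        return mu * stats.norm.cdf(a) + sigma * stats.norm.pdf(a) - target_mean

    lo = min(target_mean, 0.0) - 4.0 * sigma
    hi = target_mean + sigma
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def _lognormal_params(mean: float, sd: float) -> Tuple[float, float]:
    """(mu, sigma) of log X for a log-normal with the given mean and SD."""
    if mean <= 0:
        raise ValidationError("log-normal features require a positive mean")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _simplex_basis(sds: np.ndarray) -> np.ndarray:
    """Unit vectors b_i in R^3 with sum_i sd_i * b_i = 0 (a folded polygon).

    Feeding N(0, I_3) draws through ``sd_i * b_i`` yields deviations with the
    exact per-feature SDs and an exactly constant row sum: the posture block
    closes a skew quadrilateral with side lengths sd_i, folded 90 degrees
    along its diagonal so the deviations span the whole sum-zero subspace
    (a planar polygon would leave a degenerate linear functional that is
    constant within one group, an artifactual perfect separator).
    """
    v = np.asarray(sds, dtype=float)
    if len(v) != 4:
        raise ValidationError("simplex basis expects exactly four components")
    if v.max() >= v.sum() - v.max():
        raise ValidationError(
            "posture SDs cannot close the compositional constraint: one SD "
            "exceeds the sum of the others"
        )
    lo = max(abs(v[0] - v[1]), abs(v[2] - v[3]))
    hi = min(v[0] + v[1], v[2] + v[3])
    L = max(0.5 * (lo + hi), 1e-9)

    def _pair(va, vb, sign):
        # va*ba + vb*bb == (sign*L, 0) with unit ba, bb, off-axis in 2-D
        cos_a = np.clip((va**2 + L**2 - vb**2) / (2.0 * va * L), -1.0, 1.0)
        sin_a = math.sqrt(max(0.0, 1.0 - cos_a**2))
        ba = np.array([sign * cos_a, sin_a])
        bb = (np.array([sign * L, 0.0]) - va * ba) / vb
        return ba, bb / np.linalg.norm(bb)

    (a1, a2), (a3, a4) = _pair(v[0], v[1], +1), _pair(v[2], v[3], -1)
    # first triangle in the xy-plane, second folded into the xz-plane
    basis = np.array(
        [
            [a1[0], a1[1], 0.0],
            [a2[0], a2[1], 0.0],
            [a3[0], 0.0, a3[1]],
            [a4[0], 0.0, a4[1]],
        ]
    )
    closure = (v[:, None] * basis).sum(axis=0)
    if np.abs(closure).max() > 1e-6 * v.sum():
        raise ValidationError("posture polygon closure failed")
    return basis


# ---------------------------------------------------------------------------
# phenotype flags
# ---------------------------------------------------------------------------


def _flag_base_rates(prevalence: Mapping[str, float]) -> np.ndarray:
    """Unconditional Bernoulli rates whose at-least-one-flag conditional
    marginals equal the target prevalences (damped fixed-point iteration)."""
    targets = np.array([prevalence.get(p, 0.0) for p in PHENOTYPES], dtype=float)
    if targets.max() == 0.0:
        raise ValidationError(
            "all phenotype prevalences are zero: cannot force >= 1 flag per frail row"
        )
    p = targets.copy()
    for _ in range(200):
        p_none = np.prod(1.0 - p)
        new = np.clip(targets * (1.0 - p_none), 0.0, 1.0)
        p = 0.5 * p + 0.5 * new
    return p


def _class_rates(base_rates: np.ndarray) -> Dict[str, float]:
    """Exact P(any flag of the class is on | at least one flag on)."""
    p = base_rates
    prob_any = 0.0
    prob_class = {cls: 0.0 for cls in CLASS_PHENOTYPES}
    idx = {name: i for i, name in enumerate(PHENOTYPES)}
    for combo in product((0, 1), repeat=len(PHENOTYPES)):
        if not any(combo):
            continue
        pr = float(np.prod([p[i] if b else 1.0 - p[i] for i, b in enumerate(combo)]))
        prob_any += pr
        for cls, phens in CLASS_PHENOTYPES.items():
            if any(combo[idx[ph]] for ph in phens):
                prob_class[cls] += pr
    return {cls: prob_class[cls] / prob_any for cls in CLASS_PHENOTYPES}


def _draw_flags(rng: np.random.Generator, n: int, base_rates: np.ndarray) -> np.ndarray:
    flags = (rng.random((n, len(PHENOTYPES))) < base_rates).astype(int)
    for _ in range(1000):
        empty = flags.sum(axis=1) == 0
        if not empty.any():
            return flags
        k = int(empty.sum())
        flags[empty] = (rng.random((k, len(PHENOTYPES))) < base_rates).astype(int)
    # vanishing probability; force the most prevalent phenotype
    empty = flags.sum(axis=1) == 0
    flags[empty, int(np.argmax(base_rates))] = 1
    return flags


# ---------------------------------------------------------------------------
# phenotype coupling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _FeatureCoupling:
    base_sd: float  # shrunk frail-group spread
    shift_on: float  # additive shift when the class flag is on
    shift_off: float
    factor_on: float  # multiplicative analogues for log-normal features
    factor_off: float


def _coupling_table(spec: CohortSpec) -> Dict[str, _FeatureCoupling]:
    """Mean-preserving within-frail-group spread of each feature by flag state.

    For a class with conditional prevalence q and coupling strength c, flag-on
    members are shifted by (1-q)*c*gap and flag-off members by -q*c*gap
    (gap = frail mean - robust mean), keeping the mixture mean exact; the base
    draw's SD is shrunk so the mixture SD stays exact as well.
    """
    c = spec.coupling_strength
    base = _flag_base_rates(spec.phenotype_prevalence)
    q_class = _class_rates(base)
    table: Dict[str, _FeatureCoupling] = {}
    for fs in spec.feature_specs:
        q = q_class[fs.phenotype_class]
        gap = fs.fg_mean - fs.rg_mean
        shift_on = (1.0 - q) * c * gap
        shift_off = -q * c * gap
        if fs.distribution == "lognormal":
            factor_on = 1.0 + shift_on / fs.fg_mean
            factor_off = 1.0 + shift_off / fs.fg_mean
            if factor_on <= 0.0 or factor_off <= 0.0:
                raise ValidationError(
                    f"coupling_strength {c} too large for log-normal feature "
                    f"{fs.name}: flag subgroup mean would be non-positive"
                )
            var_r = q * (1.0 - q) * (c * gap / fs.fg_mean) ** 2
            base_var = (fs.fg_sd**2 + fs.fg_mean**2) / (1.0 + var_r) - fs.fg_mean**2
        else:
            factor_on = factor_off = 1.0
            base_var = fs.fg_sd**2 - q * (1.0 - q) * (c * gap) ** 2
        if base_var <= 0.0:
            raise ValidationError(
                f"coupling_strength {c} too large for feature {fs.name}: "
                "within-subgroup variance would be non-positive"
            )
        table[fs.name] = _FeatureCoupling(
            math.sqrt(base_var), shift_on, shift_off, factor_on, factor_off
        )
    return table


def _class_on(flags: np.ndarray, cls: str) -> np.ndarray:
    """Row mask: any phenotype flag of the class is set."""
    cols = [PHENOTYPES.index(ph) for ph in CLASS_PHENOTYPES[cls]]
    return flags[:, cols].max(axis=1).astype(bool)


def phenotype_coupling(spec: CohortSpec, participant: Participant) -> Participant:
    """Shift a frail participant's features according to its phenotype flags.

    Robust participants (all flags off) are returned unchanged, as is any
    participant when ``spec.coupling_strength`` is zero.  For frail
    participants, features of a class whose flag is on move further from the
    robust mean and features of a flag-off class move back toward it;
    log-normal features are scaled rather than shifted so they stay positive.
    """
    if participant.frailty_status == 0 or spec.coupling_strength == 0.0:
        return replace(participant, features=dict(participant.features))
    table = _coupling_table(spec)
    flags = np.array(
        [[participant.phenotypes.get(ph, 0) for ph in PHENOTYPES]], dtype=int
    )
    feats = dict(participant.features)
    for fs in spec.feature_specs:
        if fs.name not in feats:
            continue
        coup = table[fs.name]
        on = bool(_class_on(flags, fs.phenotype_class)[0])
        x = feats[fs.name]
        if fs.distribution == "lognormal":
            x *= coup.factor_on if on else coup.factor_off
        else:
            x += coup.shift_on if on else coup.shift_off
        lo, hi = fs.bounds
        feats[fs.name] = float(min(max(x, lo), hi) if math.isfinite(hi) else max(x, lo))
    out = replace(participant, features=feats)
    _project_participant_posture(out)
    return out


def _project_participant_posture(p: Participant) -> None:
    names = [f for f in POSTURE_FEATURES if f in p.features]
    if len(names) != 4:
        return
    vals = np.array([p.features[f] for f in names])
    vals = _project_simplex(vals[None, :])[0]
    for f, v in zip(names, vals):
        p.features[f] = float(v)


def _project_simplex(x: np.ndarray, total: float = 100.0) -> np.ndarray:
    """Clip to [0, total] and scale rows down so each row sums to <= total."""
    x = np.clip(x, 0.0, total)
    s = x.sum(axis=1)
    over = s > total
    if over.any():
        x[over] *= (total / s[over])[:, None]
    return x


def _latent_gaps(spec: CohortSpec) -> Dict[str, float]:
    """Signed standardized group gap of each non-posture feature on the
    latent normal scale (positive = enriched in the frail group).

    For log-normal features the gap is measured between the log-scale
    locations; for truncated normals between the solved underlying locations.
    These drive the severity-factor loadings.
    """
    gaps: Dict[str, float] = {}
    posture_joint = all(
        f in {fs.name for fs in spec.feature_specs} for f in POSTURE_FEATURES
    )
    for fs in spec.feature_specs:
        if posture_joint and fs.name in POSTURE_FEATURES:
            continue
        if fs.distribution == "lognormal":
            mu_r, s_r = _lognormal_params(fs.rg_mean, fs.rg_sd)
            mu_f, s_f = _lognormal_params(fs.fg_mean, fs.fg_sd)
        else:
            lo, hi = fs.bounds
            mu_r, s_r = _truncnorm_params(fs.rg_mean, fs.rg_sd, lo, hi)
            mu_f, s_f = _truncnorm_params(fs.fg_mean, fs.fg_sd, lo, hi)
        gaps[fs.name] = (mu_f - mu_r) / ((s_r + s_f) / 2.0)
    return gaps


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _draw_group_features(
    rng: np.random.Generator,
    spec: CohortSpec,
    group: str,
    flags: np.ndarray,
) -> np.ndarray:
    """Draw an (n, n_features) matrix for one group, flags already assigned."""
    n = flags.shape[0]
    names = list(spec.feature_names)
    out = np.empty((n, len(names)), dtype=float)
    if n == 0:
        return out
    coupling = _coupling_table(spec) if group == "fg" else None

    posture = [f for f in POSTURE_FEATURES if f in names]
    posture_joint = len(posture) == 4
    scalar_feats = [fs for fs in spec.feature_specs
                    if not (posture_joint and fs.name in posture)]

    # Shared "severity" factor g with loadings proportional to each feature's
    # signed latent-scale group gap.  Shared variance then lies along the
    # discriminant direction, so within_group_correlation genuinely caps the
    # joint separability of the feature set; rho is the severity-factor
    # variance share of the most group-separated feature.
    rho = spec.within_group_correlation
    gaps = _latent_gaps(spec)
    delta_max = max((abs(v) for v in gaps.values()), default=0.0)
    g = rng.standard_normal(n)
    eps = rng.standard_normal((n, len(scalar_feats)))
    if delta_max > 1e-12:
        lam = np.array(
            [math.sqrt(rho) * gaps[fs.name] / delta_max for fs in scalar_feats]
        )
    else:  # null spec (no group gaps): plain exchangeable correlation
        lam = np.full(len(scalar_feats), math.sqrt(rho))
    lam = np.clip(lam, -0.999, 0.999)
    z = lam[None, :] * g[:, None] + np.sqrt(1.0 - lam**2)[None, :] * eps

    for j, fs in enumerate(scalar_feats):
        col = names.index(fs.name)
        if group == "rg":
            mean, sd = fs.rg_mean, fs.rg_sd
        else:
            mean, sd = fs.fg_mean, coupling[fs.name].base_sd
        if fs.distribution == "lognormal":
            mu, sigma = _lognormal_params(mean, sd)
            out[:, col] = np.exp(mu + sigma * z[:, j])
        else:
            lo, hi = fs.bounds
            mu, sigma = _truncnorm_params(mean, sd, lo, hi)
            a = (lo - mu) / sigma
            b = (hi - mu) / sigma if math.isfinite(hi) else math.inf
            u = np.clip(stats.norm.cdf(z[:, j]), 1e-12, 1.0 - 1e-12)
            out[:, col] = stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)

    if posture_joint:
        specs = [spec.feature(f) for f in posture]
        if group == "rg":
            means = np.array([fs.rg_mean for fs in specs])
            sds = np.array([fs.rg_sd for fs in specs])
        else:
            means = np.array([fs.fg_mean for fs in specs])
            sds = np.array([coupling[fs.name].base_sd for fs in specs])
        if means.sum() > 100.0 + 1e-9:
            raise ValidationError("posture percentage means sum above 100")
        # latent Gaussian block: censored-normal matching undoes the bias the
        # later clip at zero would introduce for low-mean components
        latent = [_censored_normal_params(m, s) for m, s in zip(means, sds)]
        mus = np.array([m for m, _ in latent])
        sigmas = np.array([s for _, s in latent])
        basis = _simplex_basis(sigmas)
        A = sigmas[:, None] * basis  # (4, 3) latent loading matrix
        # couple the posture block to the same severity factor g along the
        # best latent representation of the group gap, keeping Cov(z2) = I so
        # the marginals stay exact
        gap4 = np.array([fs.fg_mean - fs.rg_mean for fs in specs])
        zstar, *_ = np.linalg.lstsq(A, gap4, rcond=None)
        if rho > 0.0 and np.linalg.norm(zstar) > 1e-12 and delta_max > 1e-12:
            u = zstar / np.linalg.norm(zstar)
            lam_p = min(
                math.sqrt(rho) * np.linalg.norm(zstar) / delta_max, 0.999
            )
            z2_raw = rng.standard_normal((n, 3))
            along = z2_raw @ u
            z2 = (
                lam_p * g[:, None] * u[None, :]
                + z2_raw
                - (1.0 - math.sqrt(1.0 - lam_p**2)) * along[:, None] * u[None, :]
            )
        else:
            z2 = rng.standard_normal((n, 3))
        dev = z2 @ A.T
        if group == "fg" and spec.coupling_strength > 0.0:
            locs = np.empty((n, 4))
            for k, fs in enumerate(specs):
                coup = coupling[fs.name]
                on = _class_on(flags, fs.phenotype_class)
                mu_on = _censored_mean_location(sigmas[k], means[k] + coup.shift_on)
                mu_off = _censored_mean_location(sigmas[k], means[k] + coup.shift_off)
                locs[:, k] = np.where(on, mu_on, mu_off)
        else:
            locs = np.broadcast_to(mus, (n, 4))
        block = locs + dev
        for k, f in enumerate(posture):
            out[:, names.index(f)] = block[:, k]

    if group == "fg" and spec.coupling_strength > 0.0:
        for fs in spec.feature_specs:
            if posture_joint and fs.name in posture:
                continue  # handled in latent space above
            col = names.index(fs.name)
            coup = coupling[fs.name]
            on = _class_on(flags, fs.phenotype_class)
            if fs.distribution == "lognormal":
                out[:, col] *= np.where(on, coup.factor_on, coup.factor_off)
            else:
                out[:, col] += np.where(on, coup.shift_on, coup.shift_off)

    # enforce supports
    for fs in spec.feature_specs:
        col = names.index(fs.name)
        lo, hi = fs.bounds
        out[:, col] = np.clip(out[:, col], lo, hi if math.isfinite(hi) else np.inf)
    if posture_joint:
        cols = [names.index(f) for f in posture]
        out[:, cols] = _project_simplex(out[:, cols])
    return out


def _draw_demographics(
    rng: np.random.Generator, spec: CohortSpec, group: str, n: int
) -> Dict[str, np.ndarray]:
    d = spec.demographics[group]
    out: Dict[str, np.ndarray] = {}
    for key in ("age", "height_cm", "weight_kg", "bmi"):
        m, s = d[key]
        out[key] = np.maximum(rng.normal(m, s, size=n), 1.0)
    out["gender"] = np.where(
        rng.random(n) < float(d["female_fraction"]), "female", "male"
    )
    return out


def generate_cohort(spec: CohortSpec, seed: Optional[int] = None) -> Cohort:
    """Generate a cohort deterministically from ``spec`` (and optional seed override).

    Robust rows carry zero phenotype flags; every frail row has at least one
    flag, drawn so the conditional per-phenotype prevalence matches the spec.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    flags_rg = np.zeros((spec.n_robust, len(PHENOTYPES)), dtype=int)
    if spec.n_frail > 0:
        base = _flag_base_rates(spec.phenotype_prevalence)
        flags_fg = _draw_flags(rng, spec.n_frail, base)
    else:
        flags_fg = np.zeros((0, len(PHENOTYPES)), dtype=int)

    demo_rg = _draw_demographics(rng, spec, "rg", spec.n_robust)
    demo_fg = _draw_demographics(rng, spec, "fg", spec.n_frail)
    feats_rg = _draw_group_features(rng, spec, "rg", flags_rg)
    feats_fg = _draw_group_features(rng, spec, "fg", flags_fg)

    names = spec.feature_names
    participants = []
    counter = 0
    for group, flags, demo, feats in (
        ("rg", flags_rg, demo_rg, feats_rg),
        ("fg", flags_fg, demo_fg, feats_fg),
    ):
        for i in range(flags.shape[0]):
            counter += 1
            participants.append(
                Participant(
                    id=f"P{counter:04d}",
                    age=float(demo["age"][i]),
                    gender=str(demo["gender"][i]),
                    height=float(demo["height_cm"][i]),
                    weight=float(demo["weight_kg"][i]),
                    bmi=float(demo["bmi"][i]),
                    frailty_status=int(group == "fg"),
                    phenotypes={ph: int(flags[i, k]) for k, ph in enumerate(PHENOTYPES)},
                    features={n: float(feats[i, j]) for j, n in enumerate(names)},
                )
            )
    cohort = Cohort(participants)
    for p in cohort:
        p.validate()
    return cohort
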