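import numpy as np
import pytest

from frailmark.synthetic_cohort import (
    CohortSpec,
    FeatureSpec,
    default_cohort_spec,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_spec():
    return default_cohort_spec(seed=1)


@pytest.fixture(scope="session")
def cohort(default_spec):
    """Default-size cohort (73 robust + 186 frail), seed 1."""
    return generate_cohort(default_spec)


def make_planted_spec(
    n_features: int = 6,
    strong: tuple = (0, 1),
    strong_effect: float = 1.0,
    weak_effect: float = 0.25,
    seed: int = 0,
    n_robust: int = 73,
    n_frail: int = 186,
) -> CohortSpec:
    """Spec with two designated strong features and weak remainders.

    Features are plain truncated normals far from their support bound, so the
    standardized group gap equals ``effect`` exactly; no posture block, no
    phenotype coupling, independent features.
    """
    specs = []
    for i in range(n_features):
        effect = strong_effect if i in strong else weak_effect
        specs.append(
            FeatureSpec(
                name=f"f{i}",
                unit="a.u.",
                phenotype_class="inactivity",
                rg_mean=100.0,
                rg_sd=10.0,
                fg_mean=100.0 - effect * 10.0,
                fg_sd=10.0,
            )
        )
    return CohortSpec(
        n_robust=n_robust,
        n_frail=n_frail,
        feature_specs=tuple(specs),
        within_group_correlation=0.0,
        coupling_strength=0.0,
        seed=seed,
    )


@pytest.fixture()
def planted_cohort():
    spec = make_planted_spec(seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def null_spec():
    """Spec whose two groups share identical feature distributions."""
    spec = default_cohort_spec(seed=7)
    spec.feature_specs = tuple(
        FeatureSpec(
            name=fs.name,
            unit=fs.unit,
            phenotype_class=fs.phenotype_class,
            rg_mean=fs.rg_mean,
            rg_sd=fs.rg_sd,
            fg_mean=fs.rg_mean,
            fg_sd=fs.rg_sd,
            support=fs.support,
            distribution=fs.distribution,
        )
        for fs in spec.feature_specs
    )
    spec.coupling_strength = 0.0
    return spec


@pytest.fixture(scope="session")
def null_cohort(null_spec):
    return generate_cohort(null_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
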