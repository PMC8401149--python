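import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from frailmark.errors import DegenerateLabelsError, ValidationError
from frailmark.rfe_bootstrap import (
    CurvePoint,
    MetricSummary,
    expected_fit_count,
    make_bootstrap_pairs,
    performance_curve,
    run_rfe,
    select_optimal,
    validate_final,
)
from frailmark.synthetic_cohort import generate_cohort
from tests.conftest import make_planted_spec


class TestBootstrapPairs:
    def test_training_sets_are_balanced(self, cohort):
        y = cohort.labels()
        for pair in make_bootstrap_pairs(cohort, B=25, seed=3):
            labels = y[pair.training]
            assert len(labels) == 146
            assert (labels == 0).sum() == 73
            assert (labels == 1).sum() == 73

    def test_out_of_bag_disjoint_from_training(self, cohort):
        for pair in make_bootstrap_pairs(cohort, B=25, seed=3):
            assert len(np.intersect1d(pair.training, pair.validation)) == 0
            assert len(pair.validation) > 0

    def test_out_of_bag_has_both_classes(self, cohort):
        y = cohort.labels()
        for pair in make_bootstrap_pairs(cohort, B=25, seed=3):
            assert len(np.unique(y[pair.validation])) == 2

    def test_deterministic(self, cohort):
        a = make_bootstrap_pairs(cohort, B=10, seed=5)
        b = make_bootstrap_pairs(cohort, B=10, seed=5)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.training, pb.training)
            np.testing.assert_array_equal(pa.validation, pb.validation)

    def test_b_zero_rejected(self, cohort):
        with pytest.raises(ValidationError):
            make_bootstrap_pairs(cohort, B=0)

    def test_single_class_cohort_rejected(self, null_cohort):
        from frailmark.synthetic_cohort import Cohort

        robust_only = Cohort([p for p in null_cohort if p.frailty_status == 0])
        with pytest.raises(DegenerateLabelsError):
            make_bootstrap_pairs(robust_only, B=2)

    def test_majority_class_side_swaps(self):
        # more robust than frail: the frail class becomes the reference size
        spec = make_planted_spec(n_robust=120, n_frail=40, seed=2)
        cohort = generate_cohort(spec)
        y = cohort.labels()
        for pair in make_bootstrap_pairs(cohort, B=5, seed=1):
            labels = y[pair.training]
            assert (labels == 0).sum() == (labels == 1).sum() == 40


class TestFitCount:
    def test_closed_form_small(self):
        assert expected_fit_count(5, 2, 10) == 140
        assert expected_fit_count(2, 2, 1) == 2
        assert expected_fit_count(11, 2, 2000) == 130_000

    @given(a=st.integers(2, 12), l=st.integers(2, 12), B=st.integers(1, 50))
    @settings(max_examples=60, deadline=None)
    def test_closed_form_matches_summation(self, a, l, B):
        if l > a:
            a, l = l, a
        assert expected_fit_count(a, l, B) == B * sum(range(l, a + 1))

    def test_instrumented_count_small_run(self, planted_cohort):
        pairs = make_bootstrap_pairs(planted_cohort, B=10, seed=0)
        features = [f"f{i}" for i in range(5)]
        trace = run_rfe(planted_cohort, pairs, features=features)
        assert trace.fit_count == 140

    def test_smallest_case(self, planted_cohort):
        pairs = make_bootstrap_pairs(planted_cohort, B=1, seed=0)
        trace = run_rfe(planted_cohort, pairs, features=["f0", "f1"])
        assert trace.fit_count == 2
        assert len(trace.loop_records) == 1


class TestRunRfe:
    def test_deterministic(self, planted_cohort):
        pairs = make_bootstrap_pairs(planted_cohort, B=15, seed=4)
        t1 = run_rfe(planted_cohort, pairs)
        t2 = run_rfe(planted_cohort, pairs)
        assert t1.final_ranking == t2.final_ranking
        for r1, r2 in zip(t1.loop_records, t2.loop_records):
            assert r1.mean_aucs == r2.mean_aucs

    def test_each_loop_removes_one_feature(self, planted_cohort):
        pairs = make_bootstrap_pairs(planted_cohort, B=5, seed=4)
        trace = run_rfe(planted_cohort, pairs)
        sizes = [len(r.active_features) for r in trace.loop_records]
        assert sizes == list(range(6, 1, -1))

    def test_ranking_is_a_permutation(self, planted_cohort):
        pairs = make_bootstrap_pairs(planted_cohort, B=5, seed=4)
        trace = run_rfe(planted_cohort, pairs)
        assert sorted(trace.final_ranking.values()) == list(range(1, 7))

    def test_planted_features_rank_first_most_runs(self):
        hits = 0
        runs = 5
        for seed in range(runs):
            cohort = generate_cohort(make_planted_spec(seed=100 + seed))
            pairs = make_bootstrap_pairs(cohort, B=60, seed=seed)
            trace = run_rfe(cohort, pairs)
            top2 = {f for f, r in trace.final_ranking.items() if r <= 2}
            hits += top2 == {"f0", "f1"}
        assert hits >= runs - 1

    def test_univariate_criterion(self, planted_cohort):
        pairs = make_bootstrap_pairs(planted_cohort, B=10, seed=4)
        trace = run_rfe(planted_cohort, pairs, criterion="univariate")
        assert trace.criterion == "univariate"
        assert trace.fit_count == expected_fit_count(6, 2, 10)
        top2 = {f for f, r in trace.final_ranking.items() if r <= 2}
        assert top2 == {"f0", "f1"}

    def test_duplicate_features_rejected(self, planted_cohort):
        pairs = make_bootstrap_pairs(planted_cohort, B=2, seed=0)
        with pytest.raises(ValidationError):
            run_rfe(planted_cohort, pairs, features=["f0", "f0", "f1"])

    def test_unknown_criterion_rejected(self, planted_cohort):
        pairs = make_bootstrap_pairs(planted_cohort, B=2, seed=0)
        with pytest.raises(ValidationError):
            run_rfe(planted_cohort, pairs, features=["f0", "f1"], criterion="bogus")

    def test_l_stop_bounds_checked(self, planted_cohort):
        pairs = make_bootstrap_pairs(planted_cohort, B=2, seed=0)
        with pytest.raises(ValidationError):
            run_rfe(planted_cohort, pairs, features=["f0", "f1"], l_stop=3)


@pytest.fixture(scope="module")
def curve_setup():
    # exactly two features carry all the signal; the rest are pure noise
    cohort = generate_cohort(make_planted_spec(seed=21, weak_effect=0.0))
    pairs = make_bootstrap_pairs(cohort, B=25, seed=21)
    trace = run_rfe(cohort, pairs)
    curve = performance_curve(cohort, pairs, trace.final_ranking)
    return cohort, pairs, trace, curve


class TestPerformanceCurve:

    def test_one_point_per_feature_count(self, curve_setup):
        *_, curve = curve_setup
        assert [p.n_features for p in curve] == list(range(1, 7))

    def test_ci_brackets_mean(self, curve_setup):
        *_, curve = curve_setup
        for point in curve:
            for summary in (point.training, point.validation):
                for metric, mean in summary.mean.items():
                    assert summary.ci_lower[metric] <= mean <= summary.ci_upper[metric]

    def test_full_model_point_matches_direct_validation(self, curve_setup):
        cohort, pairs, trace, curve = curve_setup
        ordered = trace.ranked_features()
        direct = validate_final(cohort, pairs, ordered)
        assert curve[-1].validation.mean["auc"] == pytest.approx(
            direct.mean["auc"], abs=1e-12
        )

    def test_signal_curve_plateaus_after_two_features(self, curve_setup):
        *_, curve = curve_setup
        k2 = curve[1].training.mean["auc"]
        kall = curve[-1]
        assert k2 >= kall.training.ci_lower["auc"] - 0.02

    def test_null_cohort_metrics_near_half(self, null_cohort):
        pairs = make_bootstrap_pairs(null_cohort, B=30, seed=2)
        summary = validate_final(
            null_cohort, pairs, ["walking_cadence", "standing_pct", "walking_steps"]
        )
        assert summary.mean["auc"] == pytest.approx(0.5, abs=0.07)
        assert summary.mean["accuracy"] == pytest.approx(0.5, abs=0.07)

    def test_ci_shrinks_with_more_pairs(self, cohort):
        feats = ["standing_pct", "walking_pct", "walking_cadence"]
        small = validate_final(
            cohort, make_bootstrap_pairs(cohort, B=40, seed=9), feats
        )
        large = validate_final(
            cohort, make_bootstrap_pairs(cohort, B=160, seed=9), feats
        )
        width_small = small.ci_upper["auc"] - small.ci_lower["auc"]
        width_large = large.ci_upper["auc"] - large.ci_lower["auc"]
        assert width_large < width_small * 1.1


class TestValidateFinal:
    def test_validation_below_training_on_average(self, cohort):
        pairs = make_bootstrap_pairs(cohort, B=60, seed=6)
        from frailmark.rfe_bootstrap import _evaluate_feature_set

        X = cohort.feature_matrix(["standing_pct", "walking_pct", "walking_cadence",
                                   "longest_walking_bout"])
        train, val = _evaluate_feature_set(
            X, cohort.labels(), range(4), pairs, threshold=0.5
        )
        assert val.mean["auc"] < train.mean["auc"]

    def test_saturated_cohort_near_perfect(self):
        spec = make_planted_spec(strong_effect=6.0, seed=13)
        cohort = generate_cohort(spec)
        pairs = make_bootstrap_pairs(cohort, B=20, seed=13)
        summary = validate_final(cohort, pairs, ["f0", "f1"])
        assert summary.mean["auc"] > 0.99
        assert summary.mean["accuracy"] > 0.97

    def test_empty_feature_set_rejected(self, cohort):
        pairs = make_bootstrap_pairs(cohort, B=2, seed=0)
        with pytest.raises(ValidationError):
            validate_final(cohort, pairs, [])


def _fake_curve(aucs):
    points = []
    for k, auc in enumerate(aucs, start=1):
        summary = MetricSummary(
            mean={"auc": auc},
            ci_lower={"auc": auc - 0.01},
            ci_upper={"auc": auc + 0.01},
            n_pairs=100,
        )
        points.append(
            CurvePoint(n_features=k, features=(), training=summary,
                       validation=summary)
        )
    return points


REFERENCE_RANKING = {
    "standing_pct": 1,
    "walking_pct": 2,
    "walking_cadence": 3,
    "longest_walking_bout": 4,
    "walking_steps_per_episode": 5,
    "sitting_pct": 6,
    "sit_to_stand_duration": 7,
    "walking_steps": 8,
    "sit_to_stand_count": 9,
    "stand_to_sit_count": 10,
    "stand_to_sit_duration": 11,
}


class TestSelectOptimal:
    def test_reference_ranking_selects_top_four(self):
        curve = _fake_curve(
            [0.66, 0.71, 0.74, 0.769, 0.775, 0.78, 0.785, 0.79, 0.792, 0.794, 0.795]
        )
        chosen = select_optimal(curve, REFERENCE_RANKING, auc_band=(0.7, 0.8))
        assert chosen == [
            "standing_pct", "walking_pct", "walking_cadence", "longest_walking_bout",
        ]

    def test_unconstrained_band_picks_one_feature(self):
        curve = _fake_curve([0.66, 0.71, 0.74, 0.769])
        chosen = select_optimal(
            curve, REFERENCE_RANKING, auc_band=(0.0, 1.0), phenotype_coverage=False
        )
        assert len(chosen) == 1

    def test_coverage_spans_all_classes(self):
        curve = _fake_curve([0.72, 0.74, 0.76, 0.769, 0.78])
        chosen = select_optimal(curve, REFERENCE_RANKING, auc_band=(0.7, 0.8))
        from frailmark.synthetic_cohort import DEFAULT_FEATURES

        classes = {f.name: f.phenotype_class for f in DEFAULT_FEATURES}
        assert {classes[f] for f in chosen} == {
            "inactivity", "slowness_weakness", "exhaustion",
        }

    def test_no_feasible_coverage_falls_back_with_warning(self, caplog):
        # only the k=1 point lies in the band; it cannot cover both classes
        curve = _fake_curve([0.75, 0.85, 0.9])
        ranking = {"standing_pct": 1, "walking_cadence": 2, "sitting_pct": 3}
        with caplog.at_level("WARNING"):
            chosen = select_optimal(curve, ranking, auc_band=(0.7, 0.8))
        assert chosen == ["standing_pct"]
        assert any("coverage" in m for m in caplog.messages)

    def test_band_never_reached_raises(self):
        curve = _fake_curve([0.5, 0.55])
        with pytest.raises(ValidationError):
            select_optimal(curve, {"standing_pct": 1, "walking_pct": 2},
                           auc_band=(0.9, 0.95))

    def test_invalid_band_rejected(self):
        with pytest.raises(ValidationError):
            select_optimal(_fake_curve([0.75]), REFERENCE_RANKING, auc_band=(0.8, 0.7))
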