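import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import pair_count_auc, population_auc, youden_scan

from grspanel.roc import (
    RocError,
    auc,
    auc_ci_bootstrap,
    auc_ci_delong,
    best_point_youden,
    roc_curve,
)
from grspanel.simulate import SimulationConfig, simulate_frequency_matched

# Template-style group frequencies used for the coverage study
CASE_EAFS = [0.018, 0.89, 0.63, 0.49, 0.60, 0.83, 0.52, 0.30, 0.59, 0.40,
             0.59, 0.018]
CTRL_EAFS = [0.011, 0.85, 0.54, 0.55, 0.51, 0.80, 0.53, 0.24, 0.56, 0.37,
             0.49, 0.022]


def random_instance(rng, n_max=200, ties=True):
    n1 = int(rng.integers(2, n_max // 2))
    n0 = int(rng.integers(2, n_max // 2))
    if ties:
        pool = rng.integers(0, 10, n1 + n0).astype(float)
    else:
        pool = rng.normal(size=n1 + n0)
    labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
    return pool, labels


class TestCurve:
    def test_separable_scores_reach_perfect_corner(self):
        curve = roc_curve([2, 3, 0, 1], [1, 1, 0, 0], ci=None)
        perfect = (curve.sensitivity == 1.0) & (curve.specificity == 1.0)
        assert perfect.any()
        assert curve.auc == 1.0

    def test_all_tied_scores_collapse_to_chance(self):
        curve = roc_curve([5, 5, 5, 5], [1, 0, 1, 0], ci=None)
        assert curve.auc == pytest.approx(0.5)
        assert np.max(curve.youden) == pytest.approx(0.0)

    def test_sentinels_and_monotonicity(self):
        rng = np.random.default_rng(0)
        s, y = random_instance(rng)
        curve = roc_curve(s, y, ci=None)
        assert np.isposinf(curve.thresholds[0])
        assert np.isneginf(curve.thresholds[-1])
        assert (curve.sensitivity[0], curve.specificity[0]) == (0.0, 1.0)
        assert (curve.sensitivity[-1], curve.specificity[-1]) == (1.0, 0.0)
        assert (np.diff(curve.sensitivity) >= 0).all()
        assert (np.diff(curve.specificity) <= 0).all()

    def test_tied_instance_matches_hand_enumeration(self):
        # cases {1, 2, 3}, controls {0, 1, 2}: one cross-group tie at 1 and 2
        scores = [1, 2, 3, 0, 1, 2]
        labels = [1, 1, 1, 0, 0, 0]
        curve = roc_curve(scores, labels, ci=None)
        np.testing.assert_array_equal(curve.thresholds,
                                      [np.inf, 3, 2, 1, 0, -np.inf])
        np.testing.assert_allclose(curve.sensitivity,
                                   [0, 1 / 3, 2 / 3, 1, 1, 1])
        np.testing.assert_allclose(curve.specificity,
                                   [1, 1, 2 / 3, 1 / 3, 0, 0])

    def test_single_class_rejected(self):
        with pytest.raises(RocError):
            roc_curve([1, 2], [1, 1], ci=None)
        with pytest.raises(RocError):
            roc_curve([1, np.inf], [1, 0], ci=None)


class TestAuc:
    def test_trapezoid_equals_pair_counting(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            s, y = random_instance(rng, ties=bool(rng.integers(2)))
            assert auc(s, y) == pytest.approx(pair_count_auc(s, y), abs=1e-10)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        for _ in range(20):
            s, y = random_instance(rng)
            assert auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_score_negation_symmetry(self):
        rng = np.random.default_rng(7)
        s, y = random_instance(rng)
        assert auc(s, y) + auc(-s, y) == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_invariance_under_increasing_transforms(self, seed):
        rng = np.random.default_rng(seed)
        s, y = random_instance(rng, n_max=60)
        base = auc(s, y)
        assert auc(np.exp(s / 5.0), y) == base
        assert auc(3.0 * s + 11.0, y) == base

    def test_permutation_null_centres_on_half(self):
        rng = np.random.default_rng(21)
        s, y = random_instance(rng, n_max=80)
        vals = []
        for _ in range(2000):
            vals.append(auc(s, rng.permutation(y)))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.01)


class TestDelongCi:
    def test_frozen_proc_oracle_values(self):
        """Match R pROC's DeLong interval on a fixed instance (values frozen
        from an independent run of pROC ci.auc)."""
        rng = np.random.default_rng(42)
        cases = np.round(rng.normal(1.0, 1.0, 30), 3)
        controls = np.round(rng.normal(0.0, 1.0, 40), 3)
        s = np.r_[cases, controls]
        y = np.r_[np.ones(30, int), np.zeros(40, int)]
        assert auc(s, y) == pytest.approx(0.800000000000, abs=1e-12)
        lo, hi = auc_ci_delong(s, y)
        assert lo == pytest.approx(0.692201280672, abs=1e-10)
        assert hi == pytest.approx(0.907798719328, abs=1e-10)

    def test_interval_contains_point_estimate_and_truncates(self):
        s = np.array([3.0, 4.0, 1.0, 2.0, 0.0, -1.0])
        y = np.array([1, 1, 1, 0, 0, 0])
        lo, hi = auc_ci_delong(s, y)
        assert lo <= auc(s, y) <= hi
        sep = np.array([5.0, 6.0, 7.0, 0.0, 1.0, 2.0])
        with pytest.warns(UserWarning):  # zero placement variance
            lo, hi = auc_ci_delong(sep, y)
        assert hi == 1.0

    def test_degenerate_variance_collapses_with_warning(self):
        s = np.array([1.0, 1.0, 1.0, 1.0])
        y = np.array([1, 1, 0, 0])
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = auc_ci_delong(s, y)
        assert lo == hi == 0.5

    def test_bootstrap_interval_contains_point(self):
        rng = np.random.default_rng(3)
        s, y = random_instance(rng)
        lo, hi = auc_ci_bootstrap(s, y, n_boot=300,
                                  rng=np.random.default_rng(0))
        assert lo <= auc(s, y) <= hi

    def test_coverage_of_known_population_auc(self):
        """DeLong 95% interval covers the exact population AUC of the
        unit-weight score in ~95% of frequency-matched replicates."""
        vids = [f"v{i}" for i in range(len(CASE_EAFS))]
        truth = population_auc(CASE_EAFS, CTRL_EAFS)
        covered = 0
        reps = 500
        for seed in range(reps):
            cfg = SimulationConfig(
                114, 106, "frequency_matched",
                eaf_cases=dict(zip(vids, CASE_EAFS)),
                eaf_controls=dict(zip(vids, CTRL_EAFS)), seed=seed)
            c = simulate_frequency_matched(cfg)
            score = c.dosage.sum(axis=1)
            lo, hi = auc_ci_delong(score, c.phenotype)
            covered += lo <= truth <= hi
        assert covered / reps == pytest.approx(0.95, abs=0.03)


class TestYouden:
    def test_separable_best_point_is_perfect(self):
        curve = roc_curve([2, 3, 0, 1], [1, 1, 0, 0], ci=None)
        t, sens, spec = best_point_youden(curve)
        assert (sens, spec) == (1.0, 1.0)
        assert t == 2.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            s, y = random_instance(rng, n_max=40)
            curve = roc_curve(s, y, ci=None)
            t, sens, spec = best_point_youden(curve)
            t_o, sens_o, spec_o = youden_scan(s, y)
            assert t == t_o
            assert sens == pytest.approx(sens_o, abs=1e-12)
            assert spec == pytest.approx(spec_o, abs=1e-12)
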