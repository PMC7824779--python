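import math

import numpy as np
import pytest

from conftest import make_cohort
from _oracles import grid_logistic

from grspanel.association import run_panel_association
from grspanel.grs import (
    compute_grs,
    grs_association,
    run_grs_sensitivity,
    sensitivity_table,
)
from grspanel.panel import Scheme, WeightConfigError, WeightScheme, WeightSource
from grspanel.simulate import Cohort, SimulationConfig, simulate_logistic


def scheme_of(weights: dict, scheme=Scheme.STUDY) -> WeightScheme:
    return WeightScheme(scheme, weights,
                        {k: WeightSource.STUDY for k in weights})


def two_variant_cohort():
    d = np.array([[0, 2], [1, np.nan], [np.nan, np.nan], [2, 2]], dtype=float)
    y = np.array([1, 1, 0, 0], dtype=np.int8)
    return Cohort(["a", "b", "c", "d"], y, ["v1", "v2"], d)


class TestComputeGrs:
    def test_fully_genotyped_correction_is_identity(self):
        c = make_cohort([0, 1, 2], [2, 0, 1])
        s = compute_grs(c, scheme_of({"v1": 0.7}))
        np.testing.assert_allclose(s.corrected_score, s.raw_score)
        assert (s.m_genotyped == 1).all()

    def test_single_genotyped_of_twelve(self):
        d = np.full((1, 12), np.nan)
        d[0, 0] = 2.0
        c = Cohort(["s"], np.array([1], dtype=np.int8),
                   [f"v{i}" for i in range(12)], d)
        w = scheme_of({f"v{i}": 0.5 for i in range(12)})
        s = compute_grs(c, w)
        assert s.raw_score[0] == pytest.approx(1.0)
        assert s.corrected_score[0] == pytest.approx(12.0)
        assert s.m_genotyped[0] == 1

    def test_correction_algebra_exact(self):
        c = two_variant_cohort()
        with pytest.warns(UserWarning, match="zero genotyped"):
            s = compute_grs(c, scheme_of({"v1": 0.3, "v2": -0.2}), M_total=12)
        assert s.excluded_samples == ["c"]
        np.testing.assert_array_equal(
            s.corrected_score, s.raw_score * 12 / s.m_genotyped)

    def test_unit_scores_are_risk_allele_counts(self):
        c = make_cohort([0, 1, 2], [2, 2, 0])
        w = WeightScheme(Scheme.UNIT, {"v1": 1.0}, {"v1": WeightSource.UNIT})
        s = compute_grs(c, w, M_total=1)
        assert s.corrected_score.tolist() == [0, 1, 2, 2, 2, 0]
        assert all(float(v).is_integer() for v in s.corrected_score)

    def test_weighted_variant_missing_from_cohort_rejected(self):
        c = make_cohort([0, 1], [1, 2])
        with pytest.raises(WeightConfigError):
            compute_grs(c, scheme_of({"v1": 1.0, "ghost": 1.0}))

    def test_zero_weight_variant_changes_only_m(self):
        c = two_variant_cohort()
        with pytest.warns(UserWarning):
            base = compute_grs(c, scheme_of({"v1": 0.3}), M_total=2)
        with pytest.warns(UserWarning):
            extended = compute_grs(c, scheme_of({"v1": 0.3, "v2": 0.0}),
                                   M_total=2)
        # raw scores agree on the samples scored by both
        shared = [s for s in base.sample_ids if s in extended.sample_ids]
        for sid in shared:
            i, j = base.sample_ids.index(sid), extended.sample_ids.index(sid)
            assert base.raw_score[i] == pytest.approx(extended.raw_score[j])
        # sample "a" gains a genotyped variant, halving its correction factor
        ia, ja = base.sample_ids.index("a"), extended.sample_ids.index("a")
        assert base.m_genotyped[ia] == 1 and extended.m_genotyped[ja] == 2


class TestGrsAssociation:
    def test_identical_score_multisets_give_unit_or(self):
        c = make_cohort([0, 1, 2, 2], [2, 0, 2, 1])
        s = compute_grs(c, scheme_of({"v1": 1.0}))
        r = grs_association(s)
        assert r.or_ == pytest.approx(1.0, abs=1e-6)

    def test_toy_fit_matches_grid_search_oracle(self):
        c = make_cohort([2, 2, 1, 0], [0, 1, 0, 0])
        s = compute_grs(c, scheme_of({"v1": 0.8}))
        r = grs_association(s)
        _, beta = grid_logistic(s.corrected_score, s.phenotype)
        assert r.beta == pytest.approx(beta, abs=1e-3)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(9)
        d = rng.binomial(2, 0.4, (120, 2)).astype(float)
        y = rng.binomial(1, 0.5, 120).astype(np.int8)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        c = Cohort([f"s{i}" for i in range(120)], y, ["v1", "v2"], d)
        r1 = grs_association(compute_grs(c, scheme_of({"v1": 0.5, "v2": 0.2})))
        r2 = grs_association(compute_grs(c, scheme_of({"v1": 1.5, "v2": 0.6})))
        assert r2.beta == pytest.approx(r1.beta / 3.0, abs=1e-8)
        assert r2.beta / r2.se == pytest.approx(r1.beta / r1.se, abs=1e-8)
        assert r2.p == pytest.approx(r1.p, abs=1e-8)

    def test_standardized_or_is_per_sd(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.5, (200, 1)).astype(float)
        y = rng.binomial(1, 0.5, 200).astype(np.int8)
        c = Cohort([f"s{i}" for i in range(200)], y, ["v1"], d)
        s = compute_grs(c, scheme_of({"v1": 0.7}))
        plain = grs_association(s)
        std = grs_association(s, standardize=True)
        sd = s.corrected_score.std(ddof=1)
        assert std.beta == pytest.approx(plain.beta * sd, rel=1e-8)

    def test_consistent_slope_under_case_control_sampling(self):
        """Known liability slope 0.4 per risk allele is recovered on average."""
        betas = []
        for seed in range(60):
            cfg = SimulationConfig(
                114, 106, "logistic_liability",
                eaf_population={f"v{i}": 0.5 for i in range(4)},
                true_betas={f"v{i}": 0.4 for i in range(4)},
                intercept=-2.4, seed=seed)
            c = simulate_logistic(cfg)
            s = compute_grs(c, scheme_of({f"v{i}": 1.0 for i in range(4)},
                                         Scheme.UNIT))
            r = grs_association(s)
            if r.ok:
                betas.append(r.beta)
        mean = np.mean(betas)
        sem = np.std(betas, ddof=1) / math.sqrt(len(betas))
        assert abs(mean - 0.4) <= 4 * sem


class TestSensitivity:
    def test_three_scheme_rows(self, template_cohort, panel12):
        fits = run_grs_sensitivity(template_cohort, panel12)
        table = sensitivity_table(fits)
        assert list(table["scheme"]) == ["published_mixed", "study", "unit"]
        assert len(table) == 3

    def test_study_weights_equal_association_betas(self, template_cohort,
                                                   panel12):
        assoc = {r.variant_id: r.beta
                 for r in run_panel_association(template_cohort, panel12)
                 if r.ok}
        fits = run_grs_sensitivity(template_cohort, panel12, assoc)
        study = fits[Scheme.STUDY].weights.weights
        assert study == pytest.approx(assoc)

    def test_enriched_cases_give_or_above_one(self):
        rng = np.random.default_rng(1)
        d_cases = rng.binomial(2, 0.7, (80, 1)).astype(float)
        d_ctrl = rng.binomial(2, 0.3, (80, 1)).astype(float)
        c = Cohort([f"s{i}" for i in range(160)],
                   np.r_[np.ones(80, dtype=np.int8), np.zeros(80, dtype=np.int8)],
                   ["v1"], np.vstack([d_cases, d_ctrl]))
        w = WeightScheme(Scheme.UNIT, {"v1": 1.0}, {"v1": WeightSource.UNIT})
        r = grs_association(compute_grs(c, w))
        assert r.or_ > 1
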