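"""Quadratic imputation, eligibility filtering and min-max normalization."""

import numpy as np
import pytest

from natalweight import GeneratorConfig, generate_cohort
from natalweight.preprocess import (InsufficientDataError, SERIES_WEEKS,
                                    eligibility_filter, fit_normalizer,
                                    fit_quadratic, impute_weight_series,
                                    normalize, denormalize, normalize_scalar,
                                    denormalize_scalar, build_feature_table)
from natalweight.records import AntenatalVisit, Cohort, PregnancyRecord
from natalweight.simulate import true_weight_curve


def _visits(weeks, weights):
    return [AntenatalVisit(float(t), float(x)) for t, x in zip(weeks, weights)]


def _normal_equations_quadratic(weeks, weights):
    """Independent closed-form oracle: solve the 3x3 normal equations."""
    V = np.vander(np.asarray(weeks, float), 3)  # columns t^2, t, 1
    coef = np.linalg.solve(V.T @ V, V.T @ np.asarray(weights, float))
    return coef  # (a2, a1, a0)


class TestQuadraticFit:
    def test_noiseless_quadratic_recovered_exactly(self):
        weeks = [10, 15, 20, 25, 30, 35]
        weights = [0.05 * t ** 2 + 0.3 * t + 54 for t in weeks]
        fit = fit_quadratic(_visits(weeks, weights))
        assert fit.coefficients == pytest.approx((0.05, 0.3, 54.0), abs=1e-9)
        assert fit.sse <= 1e-12

    def test_three_collinear_points_interpolated(self):
        fit = fit_quadratic(_visits([10, 20, 30], [60, 65, 70]))
        assert fit.coefficients == pytest.approx((0.0, 0.5, 55.0), abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_normal_equations_oracle_on_noisy_data(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(4, 12)
        weeks = np.sort(rng.uniform(8, 40, m))
        weights = 55 + 0.3 * weeks + 0.01 * weeks ** 2 + rng.normal(0, 1.0, m)
        fit = fit_quadratic(_visits(weeks, weights))
        oracle = _normal_equations_quadratic(weeks, weights)
        assert fit.coefficients == pytest.approx(tuple(oracle), abs=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_sse_is_a_local_minimum(self, seed):
        rng = np.random.default_rng(100 + seed)
        weeks = np.sort(rng.uniform(8, 40, 8))
        weights = 55 + 0.3 * weeks + rng.normal(0, 2.0, 8)
        fit = fit_quadratic(_visits(weeks, weights))

        def sse(a2, a1, a0):
            return np.sum((a2 * weeks ** 2 + a1 * weeks + a0 - weights) ** 2)

        for d2, d1, d0 in [(1e-4, 0, 0), (0, 1e-3, 0), (0, 0, 1e-2),
                           (-1e-4, 1e-3, -1e-2)]:
            assert sse(fit.a2 + d2, fit.a1 + d1, fit.a0 + d0) >= fit.sse - 1e-12

    def test_fewer_than_three_distinct_weeks_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_quadratic(_visits([20, 20, 20, 25], [58, 58.1, 57.9, 60]))


class TestImputation:
    def _record(self, visits, w=54.0):
        return PregnancyRecord(id="x", h=160, w=w, a=29, uh=34, acp=100,
                               fl=7.2, acf=34.1, bpd=9.3, hc=33.2, afi=10.6,
                               visits=tuple(visits), parity=0,
                               delivery_week=39.0, birthweight=None)

    def test_identity_polynomial(self):
        weeks = [10, 20, 30]
        fit = fit_quadratic(_visits(weeks, weeks))  # P(t) = t
        series = impute_weight_series(self._record(_visits(weeks, weeks), w=0.0), fit)
        assert series == pytest.approx(SERIES_WEEKS, abs=1e-9)

    def test_direct_evaluation_at_week_20(self):
        weeks = [10, 15, 20, 25, 30, 35]
        weights = [0.05 * t ** 2 + 0.3 * t + 54 for t in weeks]
        fit = fit_quadratic(_visits(weeks, weights))
        series = impute_weight_series(self._record([], w=54.0), fit)
        assert series[0] == pytest.approx(26.0, abs=1e-9)

    def test_noiseless_generator_truth_recovered(self, noiseless_cohort_truth):
        cohort, truth = noiseless_cohort_truth
        for rec, row in zip(cohort, truth.itertuples()):
            fit = fit_quadratic(rec.visits)
            series = impute_weight_series(rec, fit)
            expect = [true_weight_curve(rec.w, row.g, row.c, t) - rec.w
                      for t in SERIES_WEEKS]
            assert series == pytest.approx(expect, abs=1e-6)

    def test_default_noise_week38_mean_relative_error_below_3pct(self):
        cohort, truth = generate_cohort(GeneratorConfig(n=1000, seed=31),
                                        return_truth=True)
        eligible, _ = eligibility_filter(cohort)
        truth = truth.set_index("id")
        rel = []
        for rec in eligible:
            fit = fit_quadratic(rec.visits)
            true38 = truth.loc[rec.id, "weight38"]
            rel.append(abs(fit(38.0) - true38) / true38)
        assert np.mean(rel) <= 0.03


class TestEligibility:
    def _rec(self, rid, n_visits):
        weeks = np.linspace(10, 38, n_visits)
        return PregnancyRecord(id=rid, h=160, w=54, a=29, uh=34, acp=100,
                               fl=7.2, acf=34.1, bpd=9.3, hc=33.2, afi=10.6,
                               visits=tuple(AntenatalVisit(float(t), 60.0 + t / 10)
                                            for t in weeks),
                               parity=0, delivery_week=39.0, birthweight=3400.0)

    def test_filter_rules(self):
        cohort = Cohort(records=[self._rec("full", 8), self._rec("sparse", 4),
                                 self._rec("gappy", 6), self._rec("seven", 7)])
        eligible, log = eligibility_filter(cohort, scheduled_visits=8)
        kept = {r.id for r in eligible}
        assert kept == {"full", "seven"}
        reasons = dict(log)
        assert "fewer than 5" in reasons["sparse"]
        assert "missing" in reasons["gappy"]  # 25% of schedule missed

    def test_filter_is_order_independent(self):
        records = [self._rec(f"r{i}", 8 if i % 2 else 4) for i in range(6)]
        a, _ = eligibility_filter(Cohort(records=records))
        b, _ = eligibility_filter(Cohort(records=records[::-1]))
        assert {r.id for r in a} == {r.id for r in b}


class TestNormalization:
    def test_min_max_learned_per_feature(self):
        spec = fit_normalizer(np.array([[1.0], [3.0], [5.0]]))
        assert spec.entry("f0") == (1.0, 5.0)

    def test_constant_feature_flagged_and_maps_to_zero(self):
        spec = fit_normalizer(np.array([[2.0, 1.0], [2.0, 3.0]]))
        assert spec.constant[0] and not spec.constant[1]
        assert normalize(np.array([[2.0, 2.0]]), spec)[0, 0] == 0.0

    def test_refit_is_idempotent(self, rng):
        X = rng.uniform(0, 10, (20, 4))
        a, b = fit_normalizer(X), fit_normalizer(X)
        assert np.array_equal(a.x_min, b.x_min) and np.array_equal(a.x_max, b.x_max)

    def test_training_extrema_map_to_unit_bounds(self):
        entry = (144.0, 184.0)
        assert normalize_scalar(144.0, entry) == -1.0
        assert normalize_scalar(184.0, entry) == 1.0
        assert normalize_scalar(164.0, entry) == 0.0

    def test_population_mean_height_example(self):
        # 2*(160.4-144)/(184-144) - 1 = -0.18
        assert normalize_scalar(160.4, (144.0, 184.0)) == pytest.approx(-0.18)

    def test_round_trip_identity(self, rng):
        X = rng.uniform(-5, 5, (50, 3))
        spec = fit_normalizer(X)
        assert np.allclose(denormalize(normalize(X, spec), spec), X, atol=1e-9)

    def test_out_of_range_values_clamped(self):
        spec = fit_normalizer(np.array([[0.0], [10.0]]))
        Y = normalize(np.array([[-5.0], [15.0]]), spec)
        assert Y[0, 0] == -1.0 and Y[1, 0] == 1.0

    def test_monotone_within_range(self, rng):
        entry = (0.0, 10.0)
        xs = np.sort(rng.uniform(0, 10, 30))
        ys = [normalize_scalar(x, entry) for x in xs]
        assert all(b >= a for a, b in zip(ys, ys[1:]))
        assert denormalize_scalar(normalize_scalar(7.3, entry), entry) == pytest.approx(7.3, abs=1e-9)

    def test_spec_json_round_trip(self, tmp_path, rng):
        from natalweight.preprocess import NormalizationSpec

        X = rng.uniform(0, 1, (10, 16))
        spec = fit_normalizer(X)
        spec.to_json(tmp_path / "s.json")
        back = NormalizationSpec.from_json(tmp_path / "s.json")
        assert back.names == spec.names
        assert np.array_equal(back.x_min, spec.x_min)

    def test_feature_table_shape(self, small_cohort):
        eligible, _ = eligibility_filter(small_cohort)
        X, y, meta = build_feature_table(eligible)
        assert X.shape == (len(eligible), 16)
        assert len(y) == len(meta) == len(eligible)
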