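"""Geometry, aggregation and regression checks for the morphometrics layer."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from sensetrade import (
    aggregate_species,
    allometry_fit,
    attraction_index,
    build_species_table,
    disc_ratio,
    ef_ratio,
    eye_surface_area,
    funiculus_surface_area,
    multiple_regression,
    sensilla_density,
    trait_correlation,
    volume_ratios,
)
from sensetrade.exceptions import (
    GeometryError,
    InvalidMeasurementError,
    RankDeficiencyError,
    UndefinedStatisticError,
)
from sensetrade.morphometrics import DiscMeasurement, NeuropilVolumes, SensillumCounts, \
    SpecimenMeasurement

positive = hst.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


def _specimen(species="sp", rep="r1", **kw):
    base = dict(body_length=2500.0, head_width=900.0, eye_width=350.0,
                eye_height=420.0, funiculus_length=150.0, funiculus_width=100.0)
    base.update(kw)
    return SpecimenMeasurement(species_id=species, replicate_id=rep, **base)


class TestGeometry:
    @pytest.mark.parametrize("w,h,expected", [
        (2.0, 4.0, 8.0 * math.pi),
        (1.0, 2.0, 2.0 * math.pi),
        (7.3, 14.6, 2.0 * math.pi * 7.3 ** 2),  # height = 2*width -> r = width
    ])
    def test_eye_area_closed_form(self, w, h, expected):
        assert eye_surface_area(w, h) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("l,w,expected", [
        (2.0, 2.0, 3.0 * math.pi),
        (4.0, 2.0, 8.0 * math.pi),
    ])
    def test_funiculus_area_closed_form(self, l, w, expected):
        assert funiculus_surface_area(l, w) == pytest.approx(expected, rel=1e-12)

    def test_funiculus_quadratic_scaling(self):
        assert funiculus_surface_area(20, 20) == pytest.approx(
            100 * funiculus_surface_area(2, 2), rel=1e-12)

    def test_composed_ef_ratio(self):
        # eye (1,2) -> 2*pi; funiculus (2,2) -> 3*pi
        eye = eye_surface_area(1, 2)
        fun = funiculus_surface_area(2, 2)
        assert ef_ratio(eye, fun) == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_alternative_eye_radius_rule(self):
        # semi-axes reading: r = (w/2 + h/2)/2
        assert eye_surface_area(2, 4, rule="semi-axes") == pytest.approx(
            2 * math.pi * 1.5 ** 2, rel=1e-12)

    @pytest.mark.parametrize("w,h", [(0, 1), (1, 0), (-1, 1)])
    def test_eye_rejects_nonpositive(self, w, h):
        with pytest.raises(InvalidMeasurementError):
            eye_surface_area(w, h)

    def test_funiculus_pathological_width(self):
        # full-ovoid surface minus base is pi/4*((l+w)^2 - w^2), always positive;
        # the hemisphere variant can go non-positive when width >> length
        with pytest.raises(GeometryError):
            funiculus_surface_area(0.1, 10.0, hemisphere=True)
        assert funiculus_surface_area(0.1, 10.0) > 0

    @settings(derandomize=True, max_examples=50)
    @given(w=positive, h=positive, c=hst.floats(min_value=0.01, max_value=100))
    def test_area_scales_quadratically(self, w, h, c):
        a1 = eye_surface_area(w, h)
        a2 = eye_surface_area(c * w, c * h)
        assert a2 == pytest.approx(c * c * a1, rel=1e-9)


class TestRatios:
    @pytest.mark.parametrize("e,f,expected", [(50, 25, 2.0), (7.5, 7.5, 1.0)])
    def test_ef_ratio(self, e, f, expected):
        assert ef_ratio(e, f) == expected

    @settings(derandomize=True, max_examples=50)
    @given(e=positive, f=positive, c=hst.floats(min_value=0.01, max_value=100))
    def test_scale_invariance(self, e, f, c):
        assert ef_ratio(c * e, c * f) == pytest.approx(ef_ratio(e, f), rel=1e-9)
        d1 = disc_ratio(DiscMeasurement("s", "r", e, f))
        d2 = disc_ratio(DiscMeasurement("s", "r", c * e, c * f))
        assert d2 == pytest.approx(d1, rel=1e-9)

    def test_disc_ratio_reciprocal(self):
        a = disc_ratio(DiscMeasurement("s", "r", 10, 5))
        b = disc_ratio(DiscMeasurement("s", "r", 5, 10))
        assert a == 2.0 and b == pytest.approx(1 / a, rel=1e-12)

    def test_volume_ratios(self):
        r = volume_ratios(NeuropilVolumes("s", 4, 2, 8))
        assert r == {"ol_al": 2.0, "ol_central": 0.5, "al_central": 0.25}

    def test_volume_ratio_consistency(self, rng):
        for _ in range(20):
            ol, al, cb = rng.uniform(0.1, 10, size=3)
            r = volume_ratios(NeuropilVolumes("s", ol, al, cb))
            assert r["ol_al"] == pytest.approx(r["ol_central"] / r["al_central"], rel=1e-12)

    @pytest.mark.parametrize("count,surface,expected",
                             [(100, 200, 1.0), (0, 123.4, 0.0), (36, 1800, 0.04)])
    def test_sensilla_density(self, count, surface, expected):
        assert sensilla_density(count, surface) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("t,c,expected", [(15, 15, 0.0), (30, 0, 1.0), (30, 10, 0.5)])
    def test_attraction_index(self, t, c, expected):
        assert attraction_index(t, c) == expected

    def test_attraction_index_no_flies(self):
        with pytest.raises(UndefinedStatisticError):
            attraction_index(0, 0)

    @settings(derandomize=True, max_examples=30)
    @given(t=hst.integers(1, 100), c=hst.integers(0, 100), k=hst.integers(2, 9))
    def test_attraction_scale_invariance(self, t, c, k):
        assert attraction_index(k * t, k * c) == pytest.approx(
            attraction_index(t, c), rel=1e-12)


class TestAggregation:
    def test_single_replicate_identity(self):
        s = _specimen()
        row = aggregate_species([s])
        assert row["eye_area"] == pytest.approx(eye_surface_area(350, 420))
        assert row["n_replicates"] == 1

    def test_mean_of_raw_measurements(self):
        a = _specimen(rep="r1", eye_width=100, eye_height=200)
        b = _specimen(rep="r2", eye_width=300, eye_height=200)
        row = aggregate_species([a, b])
        # widths averaged (200) before the area formula, not mean of areas
        assert row["eye_area"] == pytest.approx(eye_surface_area(200, 200))

    def test_order_invariance(self):
        reps = [_specimen(rep=f"r{i}", eye_width=100 + 37 * i) for i in range(5)]
        fwd = aggregate_species(reps)
        rev = aggregate_species(list(reversed(reps)))
        assert fwd == rev

    def test_empty_and_mixed_species_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            aggregate_species([])
        with pytest.raises(InvalidMeasurementError):
            aggregate_species([_specimen(species="A"), _specimen(species="B")])

    def test_duplicate_replicates_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            aggregate_species([_specimen(rep="r1"), _specimen(rep="r1")])

    def test_anterior_density_uses_half_surface(self):
        s = _specimen()
        c = SensillumCounts("sp", "r1", "anterior", trichoid=30, basiconic=20, coeloconic=10)
        row = aggregate_species([s], [c])
        fun = funiculus_surface_area(150, 100)
        assert row["sensilla_density"] == pytest.approx(60 / (0.5 * fun))
        assert row["trichoid_total"] == 30

    def test_table_invariant_ef_from_areas(self):
        rows = [_specimen(species=f"s{i}", eye_width=200 + 10 * i) for i in range(4)]
        table = build_species_table(rows)
        assert np.allclose(table.ef_ratio, table.eye_area / table.funiculus_area,
                           rtol=1e-9)


class TestRegression:
    def test_allometry_exact_power_laws(self, rng):
        size = rng.uniform(1, 10, 30)
        quad = allometry_fit(size, 3.7 * size ** 2, expected_slope=2.0)
        assert quad.slope == pytest.approx(2.0, abs=1e-10)
        assert quad.p_isometry > 0.99
        lin = allometry_fit(size, 0.4 * size, expected_slope=1.0)
        assert lin.slope == pytest.approx(1.0, abs=1e-10)

    def test_allometry_matches_normal_equations(self, rng):
        size = rng.uniform(1, 50, 40)
        trait = np.exp(1.0 + 1.7 * np.log(size) + rng.normal(0, 0.3, 40))
        fit = allometry_fit(size, trait, expected_slope=2.0)
        X = np.column_stack([np.ones(40), np.log(size)])
        beta = np.linalg.solve(X.T @ X, X.T @ np.log(trait))
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_allometry_ci_coverage(self):
        # known slope recovered inside the 95% CI in >= 90% of simulations
        hits = 0
        for i in range(200):
            r = np.random.default_rng(900 + i)
            size = r.uniform(1, 20, 25)
            trait = np.exp(0.5 + 2.0 * np.log(size) + r.normal(0, 0.4, 25))
            fit = allometry_fit(size, trait, expected_slope=2.0)
            hits += fit.ci_low <= 2.0 <= fit.ci_high
        assert hits >= 180

    def test_allometry_input_validation(self):
        with pytest.raises(InvalidMeasurementError):
            allometry_fit(np.array([1.0, 2.0]), np.array([1.0, 4.0]), 2.0)
        with pytest.raises(InvalidMeasurementError):
            allometry_fit(np.array([1.0, 2.0, -3.0]), np.array([1.0, 4.0, 9.0]), 2.0)

    def test_multiple_regression_matches_pseudoinverse(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = rng.normal(size=30)
        res = multiple_regression(y, X)
        Xc = np.column_stack([np.ones(30), X.to_numpy()])
        beta = np.linalg.pinv(Xc) @ y
        assert np.allclose(res.params.to_numpy(), beta, atol=1e-10)

    def test_multiple_regression_single_predictor_reduces(self, rng):
        x = rng.normal(size=25)
        y = 2 + 3 * x + rng.normal(size=25)
        multi = multiple_regression(y, pd.DataFrame({"x": x}))
        fit = allometry_fit(np.exp(x), np.exp(y), expected_slope=1.0)
        assert multi.params["x"] == pytest.approx(fit.slope, abs=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=20)
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(RankDeficiencyError, match="x2?"):
            multiple_regression(rng.normal(size=20), X)

    def test_correlation_exact_lines(self):
        x = np.arange(1.0, 9.0)
        r_up, _ = trait_correlation(x, 2 * x + 1)
        r_dn, _ = trait_correlation(x, -x)
        assert r_up == pytest.approx(1.0, abs=1e-12)
        assert r_dn == pytest.approx(-1.0, abs=1e-12)

    def test_correlation_matches_covariance_formula(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        r, p = trait_correlation(x, y)
        expect = np.cov(x, y)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(expect, abs=1e-12)

    def test_correlation_zero_variance(self):
        with pytest.raises(UndefinedStatisticError):
            trait_correlation(np.ones(5), np.arange(5.0))
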