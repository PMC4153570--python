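"""Axis transforms and the three IC50 estimators."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from platec50 import (DoseResponseTable, HillParams, InhibitionPoint,
                      TransformDomainError, TransformSpec, hill_absolute_ic50,
                      hill_fit, inverse_transform, linear_ic50, nonlinear_ic50,
                      transform, two_point_ic50)

ALL_X = ("log10", "log2", "log5", "linear")
ALL_Y = ("linear", "probit", "logit", "log10")


def table_from_means(dose_ips, reps=1):
    """Table with `reps` identical points per (dose, mean IP)."""
    pts = [InhibitionPoint(dose=d, ip=ip)
           for d, ip in dose_ips for _ in range(reps)]
    return DoseResponseTable.from_points("t", pts)


def eq2_oracle(c_lower, c_higher, ip_lower, ip_higher):
    """Independent direct evaluation of the log-linear interpolation formula."""
    return 10 ** (math.log10(c_lower)
                  + (50 - ip_lower) / (ip_higher - ip_lower)
                  * (math.log10(c_higher) - math.log10(c_lower)))


class TestTransforms:
    def test_symmetry_at_half(self):
        assert transform(50.0, "probit") == pytest.approx(0.0, abs=1e-12)
        assert transform(50.0, "logit") == pytest.approx(0.0, abs=1e-12)

    def test_log10_inverse_pair(self):
        assert transform(100.0, "log10") == pytest.approx(2.0)
        assert inverse_transform(2.0, "log10") == pytest.approx(100.0)

    def test_probit_is_normal_quantile(self):
        assert transform(97.5, "probit") == pytest.approx(
            stats.norm.ppf(0.975), abs=1e-9)

    @pytest.mark.parametrize("which", ALL_X + ("probit", "logit"))
    @given(st.floats(1.0, 99.0))
    def test_round_trip_identity(self, which, value):
        assert inverse_transform(transform(value, which), which) == \
            pytest.approx(value, rel=1e-10)

    @pytest.mark.parametrize("which,bad", [
        ("log10", 0.0), ("log2", -1.0), ("probit", 0.0), ("probit", 100.0),
        ("logit", -5.0), ("log10", -2.0)])
    def test_domain_violations_raise(self, which, bad):
        with pytest.raises(TransformDomainError):
            transform(bad, which)


class TestTwoPoint:
    def test_worked_example(self):
        # 10 ug/ml -> 25%, 100 ug/ml -> 65%: IC50 = 10^1.625
        table = table_from_means([(10.0, 25.0), (100.0, 65.0)])
        est = two_point_ic50(table)
        assert not est.refused
        assert est.value == pytest.approx(10 ** 1.625, rel=1e-12)
        assert est.ic50_type == "absolute"
        assert est.ci_95 is None and est.gof is None

    @given(st.floats(0.01, 1e3), st.floats(1.5, 100.0),
           st.floats(1.0, 45.0), st.floats(55.0, 99.0))
    def test_matches_direct_formula(self, c_lo, ratio, ip_lo, ip_hi):
        c_hi = c_lo * ratio
        table = table_from_means([(c_lo, ip_lo), (c_hi, ip_hi)])
        est = two_point_ic50(table)
        assert est.value == pytest.approx(
            eq2_oracle(c_lo, c_hi, ip_lo, ip_hi), rel=1e-12)

    def test_no_bracket_refusal(self):
        table = table_from_means(
            [(1.0, 10.0), (10.0, 20.0), (100.0, 30.0), (1000.0, 40.0)])
        est = two_point_ic50(table)
        assert est.refused and "no bracket" in est.refusal_reason

    @pytest.mark.parametrize("boundary", [0.0, 100.0])
    def test_exact_0_or_100_refusal(self, boundary):
        table = table_from_means([(1.0, boundary if boundary == 0 else 10.0),
                                  (10.0, boundary if boundary == 100 else 90.0)])
        est = two_point_ic50(table)
        assert est.refused and f"{boundary:g}%" in est.refusal_reason

    def test_band_refusal(self):
        table = table_from_means([(1.0, 49.0), (10.0, 70.0)])
        est = two_point_ic50(table)
        assert est.refused and "band" in est.refusal_reason

    def test_band_configurable(self):
        table = table_from_means([(1.0, 49.0), (10.0, 70.0)])
        est = two_point_ic50(table, band=(49.5, 50.5))
        assert not est.refused

    def test_first_bracket_wins_when_non_monotone(self):
        # two brackets: (1,10) and (100,1000); the low-dose pair is used
        table = table_from_means(
            [(1.0, 20.0), (10.0, 60.0), (100.0, 40.0), (1000.0, 80.0)])
        est = two_point_ic50(table)
        assert est.value == pytest.approx(eq2_oracle(1.0, 10.0, 20.0, 60.0))

    def test_transformed_axes(self):
        # x linear, y logit: interpolation happens in transformed space
        table = table_from_means([(10.0, 25.0), (100.0, 65.0)])
        est = two_point_ic50(table, TransformSpec(x="linear", y="logit"))
        t25, t65 = transform(25.0, "logit"), transform(65.0, "logit")
        expected = 10 + (0.0 - t25) / (t65 - t25) * 90
        assert est.value == pytest.approx(expected, rel=1e-12)


class TestLinear:
    def test_exact_line_recovery(self):
        # y = 10 + 20*log10(C): crosses 50% at C = 100
        dose_ips = [(10.0 ** e, 10 + 20 * e) for e in range(4)]
        est = linear_ic50(table_from_means(dose_ips, reps=3))
        assert est.value == pytest.approx(100.0, rel=1e-12)
        assert est.gof == pytest.approx(1.0, abs=1e-12)

    def test_0_100_filter(self):
        dose_ips = [(1.0, 0.0), (10.0, 30.0), (100.0, 50.0), (1000.0, 70.0)]
        est = linear_ic50(table_from_means(dose_ips, reps=3))
        assert est.extra["n_points"] == 9  # the 0% triplicate is excluded

    def test_flat_response_refused(self):
        est = linear_ic50(table_from_means(
            [(1.0, 40.0), (10.0, 40.0), (100.0, 40.0), (1000.0, 40.0)], reps=3))
        assert est.refused

    def test_insufficient_points_refused(self):
        est = linear_ic50(table_from_means([(1.0, 30.0), (10.0, 70.0)]))
        assert est.refused and "insufficient" in est.refusal_reason

    def test_relative_uses_observed_plateau(self):
        # line y = 10 + 20*log10(C); largest mean IP = 70 so relative
        # IC50 solves the line at 35%: log10(C) = 1.25
        dose_ips = [(10.0 ** e, 10 + 20 * e) for e in range(4)]
        est = linear_ic50(table_from_means(dose_ips, reps=3),
                          ic50_type="relative")
        assert est.i_max == pytest.approx(70.0)
        assert est.value == pytest.approx(10 ** 1.25, rel=1e-9)

    @pytest.mark.parametrize("x", ALL_X)
    @pytest.mark.parametrize("y", ALL_Y)
    def test_generating_crossing_recovered_for_all_transforms(self, x, y):
        """Data exactly linear in (Tx, Ty) space returns the generating
        crossing of transformed 50% to 1e-9 with r^2 = 1."""
        doses = [1.0, 10.0, 100.0, 1000.0] if x != "linear" else \
            [10.0, 20.0, 30.0, 40.0]
        tx = np.array([transform(d, x) for d in doses])
        ty_lo, ty_hi = transform(20.0, y), transform(80.0, y)
        slope = (ty_hi - ty_lo) / (tx[-1] - tx[0])
        intercept = ty_lo - slope * tx[0]
        dose_ips = [(d, inverse_transform(intercept + slope * t, y))
                    for d, t in zip(doses, tx)]
        est = linear_ic50(table_from_means(dose_ips, reps=3),
                          TransformSpec(x=x, y=y))
        expected = inverse_transform((transform(50.0, y) - intercept) / slope, x)
        assert not est.refused
        assert est.value == pytest.approx(expected, rel=1e-9)
        assert est.gof == pytest.approx(1.0, abs=1e-9)


class TestHillFit:
    def test_noiseless_recovery(self):
        true = HillParams(i_max=80.0, h=1.0, k=10.0)
        doses = [1.0, 10.0, 100.0, 1000.0]
        pts = [(d, true.predict(d)) for d in doses for _ in range(3)]
        params, r2 = hill_fit(pts)
        assert params.i_max == pytest.approx(80.0, rel=1e-4)
        assert params.h == pytest.approx(1.0, rel=1e-4)
        assert params.k == pytest.approx(10.0, rel=1e-4)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_predict_at_k_is_half_plateau(self):
        p = HillParams(i_max=73.0, h=1.7, k=4.2)
        assert p.predict(p.k) == pytest.approx(p.i_max / 2)

    def test_monotone_in_dose(self):
        p = HillParams(i_max=90.0, h=0.7, k=5.0)
        doses = np.geomspace(0.01, 1000, 50)
        assert np.all(np.diff(p.predict(doses)) > 0)

    def test_constant_response_degenerate_r2(self):
        # flat data: (i_max, h) jointly unidentifiable (any curve flat at 60
        # over the dose range has zero SS), so only the degenerate R^2 flag
        # and the fitted level are contractual
        pts = [(d, 60.0) for d in (1.0, 10.0, 100.0, 1000.0) for _ in range(3)]
        params, r2 = hill_fit(pts)
        assert r2 is None
        for d in (1.0, 10.0, 100.0, 1000.0):
            assert params.predict(d) == pytest.approx(60.0, abs=0.1)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            hill_fit([(1.0, 10.0), (2.0, 20.0), (3.0, 30.0)])
        with pytest.raises(ValueError):
            hill_fit([(1.0, 10.0)] * 5)
        with pytest.raises(ValueError):
            hill_fit([(-1.0, 10.0), (1.0, 20.0), (2.0, 30.0), (3.0, 40.0)])


class TestNonlinearIc50:
    def test_closed_form_relative_and_absolute(self):
        true = HillParams(i_max=80.0, h=1.0, k=10.0)
        pts = [InhibitionPoint(dose=d, ip=true.predict(d))
               for d in (1.0, 10.0, 100.0, 1000.0) for _ in range(3)]
        table = DoseResponseTable.from_points("t", pts)
        rel = nonlinear_ic50(table, "relative")
        ab = nonlinear_ic50(table, "absolute")
        assert rel.value == pytest.approx(10.0, rel=1e-4)
        assert ab.value == pytest.approx(10.0 * 50.0 / 30.0, rel=1e-4)
        assert ab.i_max == pytest.approx(80.0, rel=1e-4)

    def test_full_efficacy_limit_types_coincide(self):
        p = HillParams(i_max=100.0, h=2.0, k=7.0)
        assert hill_absolute_ic50(p) == pytest.approx(p.k)

    def test_absolute_refused_below_half(self):
        true = HillParams(i_max=45.0, h=1.0, k=10.0)
        pts = [InhibitionPoint(dose=d, ip=true.predict(d))
               for d in (1.0, 10.0, 100.0, 1000.0) for _ in range(3)]
        est = nonlinear_ic50(DoseResponseTable.from_points("t", pts), "absolute")
        assert est.refused and "never reaches 50%" in est.refusal_reason
        assert hill_absolute_ic50(true) is None


class TestScaleEquivariance:
    @given(st.floats(0.05, 20.0))
    def test_all_methods_scale_with_doses(self, gamma):
        """Multiplying all doses by gamma multiplies every IC50 by gamma."""
        true = HillParams(i_max=85.0, h=1.2, k=8.0)
        doses = (0.5, 5.0, 50.0, 500.0)
        base_pts = [(d, true.predict(d)) for d in doses for _ in range(3)]

        def estimates(pts):
            table = DoseResponseTable.from_points(
                "t", [InhibitionPoint(dose=d, ip=ip) for d, ip in pts])
            return (two_point_ic50(table).value,
                    linear_ic50(table).value,
                    nonlinear_ic50(table, "relative").value)

        for v1, vg in zip(estimates(base_pts),
                          estimates([(gamma * d, ip) for d, ip in base_pts])):
            assert vg == pytest.approx(gamma * v1, rel=1e-3)
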