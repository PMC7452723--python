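"""Closed-form isotherm and kinetics equations against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equibind import (
    BindingParameters,
    KineticPrediction,
    ceil_to_sigfigs,
    dissociation_remaining,
    equilibration_rate,
    equilibration_time,
    equilibration_time_table,
    format_equilibration_time,
    fraction_bound_at_time,
    fraction_bound_free,
    fraction_bound_hyperbolic,
    fraction_bound_quadratic,
    half_saturation_point,
    round_to_sigfigs,
    solve_free_protein,
)

NM = 1e-9
PM = 1e-12

conc = st.floats(min_value=1e-14, max_value=1e-5)


def bisection_bound_fraction(p_total, r_total, kd, tol=1e-14):
    """Independent oracle: bound-complex concentration by bisection of the
    single-species mass balance (P_tot - x)(R_tot - x) = kd * x."""
    lo, hi = 0.0, min(p_total, r_total)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if (p_total - mid) * (r_total - mid) - kd * mid > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi) / r_total


class TestIsotherms:
    @pytest.mark.parametrize("p_free, kd, expected", [
        (1 * NM, 1 * NM, 0.5),        # half-saturation at K_D by definition
        (0.0, 3 * NM, 0.0),
        (9 * NM, 1 * NM, 0.9),
    ])
    def test_free_isotherm_values(self, p_free, kd, expected):
        assert fraction_bound_free(p_free, kd) == pytest.approx(expected)

    @pytest.mark.parametrize("p_total, kd, expected", [
        (1 * NM, 1 * NM, 0.5),
        (0.1 * NM, 1 * NM, 0.1 / 1.1),
    ])
    def test_hyperbolic_values(self, p_total, kd, expected):
        assert fraction_bound_hyperbolic(p_total, kd) == pytest.approx(expected)

    def test_hyperbolic_saturates(self):
        assert fraction_bound_hyperbolic(1e6 * NM, 1 * NM) > 0.999

    def test_quadratic_half_saturation_example(self):
        # at p_total = kd + r_total/2 the free concentration equals kd
        assert fraction_bound_quadratic(1.01 * NM, 2 * NM, 0.01 * NM) == \
            pytest.approx(0.5, abs=1e-12)

    def test_quadratic_titration_value(self):
        got = fraction_bound_quadratic(2 * NM, 2 * NM, 0.01 * NM)
        assert got == pytest.approx(0.9318, abs=2e-4)
        assert got == pytest.approx(
            bisection_bound_fraction(2 * NM, 2 * NM, 0.01 * NM), rel=1e-8)

    def test_quadratic_rejects_zero_r(self):
        with pytest.raises(ValueError):
            fraction_bound_quadratic(1 * NM, 0.0, 1 * NM)

    def test_nonpositive_kd_rejected(self):
        for f in (fraction_bound_free, fraction_bound_hyperbolic):
            with pytest.raises(ValueError):
                f(1 * NM, 0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(p=conc, r=conc, kd=conc)
    def test_quadratic_matches_bisection_oracle(self, p, r, kd):
        got = float(fraction_bound_quadratic(p, r, kd))
        want = bisection_bound_fraction(p, r, kd)
        assert got == pytest.approx(want, rel=1e-8, abs=1e-12)
        assert 0 <= got < 1

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=conc, kd=conc)
    def test_dilute_limit_equivalence(self, p, kd):
        r = 1e-4 * kd  # well below kd: depletion negligible
        quad = fraction_bound_quadratic(p, r, kd)
        hyp = fraction_bound_hyperbolic(p, kd)
        assert abs(quad - hyp) < 1e-3

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(r=conc, kd=conc)
    def test_half_saturation_law(self, r, kd):
        k_half = half_saturation_point(r, kd)
        assert fraction_bound_quadratic(k_half, r, kd) == \
            pytest.approx(0.5, abs=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=conc, r=conc, kd=conc)
    def test_monotonicity(self, p, r, kd):
        up, down = p * 1.5, kd * 1.5
        assert fraction_bound_quadratic(up, r, kd) > \
            fraction_bound_quadratic(p, r, kd)
        assert fraction_bound_quadratic(p, r, down) < \
            fraction_bound_quadratic(p, r, kd)
        assert fraction_bound_hyperbolic(up, kd) > \
            fraction_bound_hyperbolic(p, kd)

    def test_half_saturation_examples(self):
        assert half_saturation_point(2 * NM, 0.01 * NM) == \
            pytest.approx(1.01 * NM)
        assert half_saturation_point(0.0, 5 * NM) == 5 * NM
        # K_1/2 = 2 nM really gives half binding
        assert fraction_bound_quadratic(2 * NM, 2 * NM, 1 * NM) == \
            pytest.approx(0.5, abs=1e-12)


class TestFreeProteinSolver:
    def test_reduces_to_total_without_partners(self):
        assert solve_free_protein(3 * NM, 0.0, 1 * NM) == \
            pytest.approx(3 * NM, rel=1e-12)

    def test_consistent_with_quadratic(self):
        p, r, kd = 2 * NM, 2 * NM, 0.01 * NM
        pf = solve_free_protein(p, r, kd)
        assert pf / (pf + kd) == \
            pytest.approx(float(fraction_bound_quadratic(p, r, kd)), rel=1e-9)

    def test_chase_effectiveness_fractions(self):
        # excess unlabeled competitor of equal affinity suppresses labeled
        # binding to 0.01 (1000 nM) and 0.1 (100 nM)
        kd = 0.12 * NM
        for c, expected in [(1000 * NM, 0.01), (100 * NM, 0.1)]:
            pf = solve_free_protein(10 * NM, 0.0, kd, c_total=c,
                                    kd_competitor=kd)
            assert pf / (pf + kd) == pytest.approx(expected, abs=5e-4)

    def test_competitor_requires_kd(self):
        with pytest.raises(ValueError):
            solve_free_protein(1 * NM, 0.0, 1 * NM, c_total=1 * NM)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=conc, r=conc, kd=conc, c=conc, kdc=conc)
    def test_mass_balance_closes(self, p, r, kd, c, kdc):
        pf = solve_free_protein(p, r, kd, c_total=c, kd_competitor=kdc)
        total = pf * (1 + r / (pf + kd) + c / (pf + kdc))
        assert total == pytest.approx(p, rel=1e-9)
        assert 0 <= pf <= p


class TestKinetics:
    def test_equilibration_rate(self):
        assert equilibration_rate(1e8, 1 * NM, 0.01) == pytest.approx(0.11)
        # [P] -> 0 limit is koff
        assert equilibration_rate(1e8, 0.0, 1e-4) == pytest.approx(1e-4)
        assert equilibration_rate(2.85e7, 0.0, 2.92e-5) == \
            pytest.approx(2.92e-5)
        with pytest.raises(ValueError):
            equilibration_rate(0.0, 0.0, 0.0)

    @pytest.mark.parametrize("kd, kon, t_raw_s, display", [
        (1 * PM, 1e8, 34650, (10, "hr")),     # tight binder: 10 hr
        (1e-6, 1e8, 0.03465, (0.04, "s")),    # weak binder: 40 ms
        (1 * NM, 1e6, 3465, (1, "hr")),
    ])
    def test_equilibration_time(self, kd, kon, t_raw_s, display):
        pred = equilibration_time(kd, kon)
        assert pred.t_equil == pytest.approx(t_raw_s, rel=1e-3)
        val, unit = format_equilibration_time(pred.t_equil)
        assert (val, unit) == (pytest.approx(display[0]), display[1])

    def test_kinetic_prediction_invariants(self):
        with pytest.raises(ValueError):
            KineticPrediction(k_equil=1.0, t_half=1.0, t_equil=5.0)

    def test_three_halflives_87_5_percent(self):
        t_half = math.log(2)
        assert fraction_bound_at_time(3 * t_half, 1.0, 1.0) == \
            pytest.approx(0.875)

    def test_five_halflives_completion(self):
        # exactly 1 - 2^-5 = 96.875%
        t_half = math.log(2)
        assert fraction_bound_at_time(5 * t_half, 1.0, 1.0) == \
            pytest.approx(1 - 2 ** -5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(t=st.floats(min_value=0, max_value=1e6),
           k=st.floats(min_value=1e-6, max_value=10),
           amp=st.floats(min_value=0, max_value=1))
    def test_time_course_bounded_by_equilibrium(self, t, k, amp):
        f = fraction_bound_at_time(t, k, amp)
        assert 0 <= f <= amp + 1e-15

    def test_dissociation_remaining(self):
        assert dissociation_remaining(1.0, 30.0) == \
            pytest.approx(9.36e-14, rel=1e-2)
        assert dissociation_remaining(0.01, 30.0) == \
            pytest.approx(0.7408, abs=1e-3)
        assert dissociation_remaining(5.0, 0.0) == 1.0


class TestBindingParameters:
    def test_thermodynamic_consistency_enforced(self):
        with pytest.raises(ValueError):
            BindingParameters(kd=1 * NM, kon=1e8, koff=1.0)  # koff/kon=10nM
        ok = BindingParameters(kd=1 * NM, kon=1e8, koff=0.1)
        assert ok.koff / ok.kon == pytest.approx(ok.kd)

    def test_from_rates(self):
        p = BindingParameters.from_rates(kon=2.85e7, koff=2.92e-5)
        assert p.kd == pytest.approx(1.0246 * PM, rel=1e-3)

    @pytest.mark.parametrize("kwargs", [
        {"kd": 0.0}, {"kd": -1e-9}, {"kd": 1e-9, "kon": -1.0},
        {"kd": 1e-9, "active_fraction": 0.0},
        {"kd": 1e-9, "active_fraction": 1.2},
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            BindingParameters(**kwargs)


class TestPresentation:
    @pytest.mark.parametrize("x, expected", [
        (0.03465, 0.04), (3.465, 4.0), (34.65, 40.0), (9.625, 10.0),
        (962.5, 1000.0), (962500.0, 1e6), (1.0, 1.0), (0.04, 0.04),
    ])
    def test_ceiling_one_sigfig(self, x, expected):
        assert ceil_to_sigfigs(x, 1) == pytest.approx(expected)

    @pytest.mark.parametrize("x, sf, expected", [
        (32.96, 1, 30.0), (134.6, 2, 130.0), (1.0246, 3, 1.02),
    ])
    def test_round_sigfigs(self, x, sf, expected):
        assert round_to_sigfigs(x, sf) == pytest.approx(expected)

    def test_design_table_grid(self):
        df = equilibration_time_table([1e-6, 1e-9, 1e-12], [1e8, 1e6, 1e3])
        assert len(df) == 9
        by = {(row.kd_M, row.kon_per_M_s): (row.display_value,
                                            row.display_unit)
              for row in df.itertuples()}
        assert by[(1e-6, 1e8)] == (pytest.approx(0.04), "s")
        assert by[(1e-12, 1e3)] == (pytest.approx(1e6), "hr")
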