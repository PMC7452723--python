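"""Parameter estimation: round trips, apparent-K_D behavior, identifiability."""

import numpy as np
import pytest

from equibind import (
    BindingParameters,
    CompetitionBinding,
    CompetitionSeries,
    HyperbolicIsotherm,
    QuadraticIsotherm,
    SimulationDesign,
    TitrationSeries,
    bootstrap_ci,
    dilution_grid,
    fit_active_fraction_breakpoint,
    fit_active_fraction_quadratic,
    fit_competition,
    fit_exponential,
    fit_hyperbolic,
    fit_kon_koff,
    fit_quadratic,
    fraction_bound_quadratic,
    half_saturation_point,
    simulate_kinetic_trace,
    simulate_titration_series,
)
from equibind.data import KineticTrace

NM = 1e-9
PM = 1e-12


def quadratic_series(kd, r, span=100.0, **kwargs):
    grid = dilution_grid(half_saturation_point(r, kd), span=span)
    return TitrationSeries(grid, fraction_bound_quadratic(grid, r, kd),
                           r_total_low=r, **kwargs)


class TestHyperbolicFit:
    def test_noiseless_roundtrip(self):
        params = BindingParameters(kd=0.1 * NM)
        d = SimulationDesign(params=params, r_total=0.0001 * NM,
                             noise_sd=0.0, n_replicates=1, seed=0)
        res = fit_hyperbolic(simulate_titration_series(d)[0])
        assert res.estimates["kd"] == pytest.approx(0.1 * NM, rel=1e-6)
        assert res.estimates["amplitude"] == pytest.approx(1.0, rel=1e-6)
        assert res.estimates["offset"] == pytest.approx(0.0, abs=1e-9)
        assert res.well_defined

    def test_titration_regime_overestimates_100_fold(self):
        # K_D = 0.01 nM measured at R_total = 2 nM: the apparent K_D lands
        # near r/2, two orders of magnitude above the truth
        res = fit_hyperbolic(quadratic_series(0.01 * NM, 2 * NM))
        assert res.estimates["kd"] / (0.01 * NM) > 50
        assert res.estimates["kd"] == pytest.approx(1.01 * NM, rel=0.25)

    def test_apparent_kd_tracks_half_saturation_law(self):
        # the curve midpoint is exactly kd + r/2; the least-squares
        # hyperbolic kd tracks it to within ~25% across regimes
        kd = 0.1 * NM
        for ratio in (0.1, 1.0, 10.0, 100.0, 1000.0):
            r = ratio * kd
            res = fit_hyperbolic(quadratic_series(kd, r))
            assert res.estimates["kd"] == \
                pytest.approx(half_saturation_point(r, kd), rel=0.25)

    def test_noisy_binding_regime_recovery(self):
        params = BindingParameters(kd=0.1 * NM)
        d = SimulationDesign(params=params, r_total=0.001 * NM,
                             noise_sd=0.05, n_replicates=10, seed=3)
        kds = [fit_hyperbolic(s).estimates["kd"]
               for s in simulate_titration_series(d)]
        assert np.median(kds) == pytest.approx(0.1 * NM, rel=0.10)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_hyperbolic(TitrationSeries([1e-9, 2e-9, 4e-9],
                                           [0.5, 0.6, 0.7]))

    def test_sklearn_estimator_protocol(self):
        from sklearn.base import clone

        est = HyperbolicIsotherm(free_offset=False)
        assert clone(est).get_params()["free_offset"] is False
        x = dilution_grid(1 * NM)
        y = x / (x + 1 * NM)
        est.fit(x.reshape(-1, 1), y)
        assert est.kd_ == pytest.approx(1 * NM, rel=1e-6)
        assert np.allclose(est.predict(x.reshape(-1, 1)), y, atol=1e-9)


class TestQuadraticFit:
    def test_noiseless_roundtrip_intermediate_regime(self):
        # tight binder measured at 16-fold excess: quadratic recovers truth
        res = fit_quadratic(quadratic_series(1.9 * PM, 30 * PM))
        assert res.estimates["kd"] == pytest.approx(1.9 * PM, rel=1e-6)
        assert res.well_defined
        assert res.extras["excess_ratio"] == pytest.approx(30 / 1.9, rel=1e-4)

    def test_trace_limit_agrees_with_hyperbolic(self):
        kd = 0.1 * NM
        grid = dilution_grid(kd)
        y = fraction_bound_quadratic(grid, 1e-5 * kd, kd)
        s = TitrationSeries(grid, y, r_total_low=1e-5 * kd)
        rq = fit_quadratic(s)
        rh = fit_hyperbolic(s)
        assert rq.estimates["kd"] == pytest.approx(rh.estimates["kd"],
                                                   rel=1e-4)

    def test_titration_regime_flagged_poorly_defined(self):
        params = BindingParameters(kd=0.1 * NM)
        d = SimulationDesign(params=params, r_total=1000 * 0.1 * NM,
                             noise_sd=0.01, n_replicates=6, seed=9)
        flagged = [not fit_quadratic(s).well_defined
                   for s in simulate_titration_series(d)]
        assert np.mean(flagged) > 0.5

    def test_titration_warning_attached(self):
        res = fit_quadratic(quadratic_series(0.01 * NM, 2 * NM))
        assert any("titration regime" in w for w in res.warnings)

    def test_rtotal_bounds_reported_as_systematic_spread(self):
        kd, r = 1.9 * PM, 12 * PM
        grid = dilution_grid(half_saturation_point(r, kd))
        s = TitrationSeries(grid, fraction_bound_quadratic(grid, r, kd),
                            r_total_low=r, r_total_high=3 * r)
        res = fit_quadratic(s)
        assert "kd_at_r_high" in res.extras
        assert res.extras["kd_systematic_spread"] > 0

    def test_requires_r_total(self):
        grid = dilution_grid(1 * NM)
        s = TitrationSeries(grid, grid / (grid + 1 * NM))
        with pytest.raises(ValueError):
            fit_quadratic(s)


class TestExponentialFit:
    def test_association_roundtrip(self):
        params = BindingParameters.from_rates(kon=1e8, koff=0.01)
        tr = simulate_kinetic_trace(params, 1 * NM,
                                    np.linspace(0, 60, 12), "association")
        res = fit_exponential(tr)
        assert res.estimates["k_obs"] == pytest.approx(0.11, rel=1e-6)

    def test_slow_dissociation_recovery(self, cold_params):
        t = np.linspace(0, 48 * 3600, 16)
        tr = simulate_kinetic_trace(cold_params, 1 * NM, t, "dissociation",
                                    initial_fraction=0.9)
        res = fit_exponential(tr)
        assert res.estimates["k_obs"] == pytest.approx(2.92e-5, rel=0.01)
        assert res.extras["koff"] == res.estimates["k_obs"]

    def test_constant_trace_flagged(self):
        tr = KineticTrace(t=np.arange(6.0), fraction_bound=np.full(6, 0.4),
                          p_total=1 * NM)
        res = fit_exponential(tr)
        assert not res.converged
        assert not res.well_defined


class TestRateLine:
    def test_table_consistency_cold(self):
        p = np.array([0.5, 1, 2, 4, 8]) * NM
        pts = np.column_stack([p, 2.85e7 * p + 2.92e-5])
        res = fit_kon_koff(pts)
        assert res.estimates["kon"] == pytest.approx(2.85e7, rel=1e-8)
        assert res.estimates["koff"] == pytest.approx(2.92e-5, rel=1e-8)
        assert res.estimates["kd"] == pytest.approx(1.0246 * PM, rel=1e-3)

    def test_table_consistency_warm(self):
        p = np.array([0.5, 1, 2, 4]) * NM
        pts = np.column_stack([p, 1.04e8 * p + 0.014])
        res = fit_kon_koff(pts)
        assert res.estimates["kd"] == pytest.approx(134.6 * PM, rel=1e-3)

    def test_active_fraction_correction(self):
        p = np.array([1, 2, 4, 8]) * NM
        pts = np.column_stack([p, 1e7 * p + 1e-4])
        res = fit_kon_koff(pts, active_fraction=0.5)
        assert res.estimates["kon"] == pytest.approx(2e7, rel=1e-8)

    def test_degenerate_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_kon_koff([(1 * NM, 0.1), (1 * NM, 0.2)])

    def test_negative_intercept_flagged(self):
        p = np.array([1, 2, 4, 8]) * NM
        k = 1e7 * p - 5e-3 + np.array([1e-4, -1e-4, 1e-4, -1e-4])
        res = fit_kon_koff(np.column_stack([p, k]))
        assert any("upper limit" in w for w in res.warnings)


class TestActiveFraction:
    @staticmethod
    def titration_data(f_active, ligand=10 * NM, kd=0.01 * NM, n=16):
        p = np.linspace(0.1, 4.0, n) * ligand
        y = fraction_bound_quadratic(f_active * p, ligand, kd)
        return TitrationSeries(p, y, r_total_low=ligand)

    @pytest.mark.parametrize("f_true, expected_ratio", [
        (0.5, 2.0),    # half-active protein breaks at 2:1
        (1.0, 1.0),
        (1 / 1.3, 1.3),  # 75%-active preparation breaks at 1.3:1
    ])
    def test_breakpoint_recovers_active_fraction(self, f_true,
                                                 expected_ratio):
        s = self.titration_data(f_true)
        res = fit_active_fraction_breakpoint(s, 10 * NM,
                                             measured_kd=0.01 * NM)
        assert res.breakpoint_ratio == pytest.approx(expected_ratio,
                                                     rel=0.05)
        assert res.active_fraction == pytest.approx(f_true, rel=0.05)

    def test_quadratic_coefficient_route(self):
        s = self.titration_data(0.75)
        res = fit_active_fraction_quadratic(s, 10 * NM)
        assert res.active_fraction == pytest.approx(0.75, rel=1e-4)
        assert res.method == "quadratic-coefficient"

    def test_methods_agree_on_noisy_data(self, rng):
        s = self.titration_data(0.5)
        noisy = TitrationSeries(s.p_total,
                                s.fraction_bound
                                + rng.normal(0, 0.02, len(s)),
                                r_total_low=s.r_total_low)
        bp = fit_active_fraction_breakpoint(noisy, 10 * NM)
        qd = fit_active_fraction_quadratic(noisy, 10 * NM)
        assert bp.active_fraction == pytest.approx(qd.active_fraction,
                                                   rel=0.10)

    def test_overactive_estimate_flagged(self):
        # data consistent with more binding than the nominal protein allows
        p = np.linspace(0.1, 4.0, 16) * 10 * NM
        y = fraction_bound_quadratic(1.4 * p, 10 * NM, 0.01 * NM)
        s = TitrationSeries(p, y, r_total_low=10 * NM)
        res = fit_active_fraction_quadratic(s, 10 * NM)
        assert "active_fraction>1" in res.flags

    def test_parallel_segments_rejected(self):
        p = np.linspace(0.1, 4.0, 12) * 10 * NM
        y = 0.02 * p / (10 * NM)  # a single straight line: no breakpoint
        s = TitrationSeries(p, y, r_total_low=10 * NM)
        with pytest.raises(ValueError, match="breakpoint"):
            fit_active_fraction_breakpoint(s, 10 * NM)


class TestCompetitionFit:
    @staticmethod
    def series(kd_comp, kd_lab=0.12 * NM, p_total=0.4 * NM, noise=0.0,
               seed=0):
        c = np.concatenate([[0.0], np.geomspace(0.01 * NM, 3000 * NM, 12)])
        model = CompetitionBinding(p_total=p_total, kd_labeled=kd_lab)
        model.kd_competitor_, model.amplitude_, model.offset_ = \
            kd_comp, 1.0, 0.0
        y = model.predict(c)
        if noise:
            y = y + np.random.default_rng(seed).normal(0, noise, len(c))
        return CompetitionSeries(c, y, p_total=p_total, kd_labeled=kd_lab)

    def test_roundtrip(self):
        res = fit_competition(self.series(10 * NM))
        assert res.estimates["kd_competitor"] == pytest.approx(10 * NM,
                                                               rel=1e-6)
        assert res.well_defined

    def test_noisy_recovery_within_ci(self):
        res = fit_competition(self.series(10 * NM, noise=0.03, seed=2))
        lo, hi = res.ci95["kd_competitor"]
        assert lo <= 10 * NM <= hi

    def test_transition_not_bracketed_flagged(self):
        s = self.series(10 * NM)
        weak = CompetitionSeries(s.c_total[:6], s.fraction_bound[:6] * 0
                                 + s.fraction_bound[0], p_total=s.p_total,
                                 kd_labeled=s.kd_labeled)
        res = fit_competition(weak)
        assert not res.well_defined

    def test_all_zero_competitor_rejected(self):
        with pytest.raises(ValueError):
            fit_competition(CompetitionSeries(
                np.zeros(5), np.full(5, 0.9), p_total=0.4 * NM,
                kd_labeled=0.12 * NM))


class TestConfidenceIntervals:
    def test_binding_regime_ci_coverage(self):
        """Asymptotic 95% CIs cover the true K_D in >= 90% of simulated
        binding-regime series."""
        params = BindingParameters(kd=0.1 * NM)
        d = SimulationDesign(params=params, r_total=0.001 * NM,
                             noise_sd=0.05, n_replicates=200, seed=11)
        hits = 0
        for s in simulate_titration_series(d):
            res = fit_hyperbolic(s)
            lo, hi = res.ci95["kd"]
            hits += lo <= params.kd <= hi
        assert hits / 200 >= 0.90

    def test_bootstrap_ci_brackets_estimate(self, rng):
        grid = dilution_grid(1 * NM)
        y = grid / (grid + 1 * NM) + rng.normal(0, 0.03, len(grid))
        lo, hi = bootstrap_ci(HyperbolicIsotherm(), grid, y, "kd",
                              n_boot=100, seed=4)
        est = HyperbolicIsotherm().fit(grid, y).kd_
        assert lo < est < hi
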