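"""Estimation of binding parameters from titration, kinetic and competition data.

Every fitting operation is an sklearn-style estimator (``fit`` /
``predict`` / ``get_params``) so curves compose with sklearn model
selection; thin module-level functions (``fit_hyperbolic`` etc.) wrap the
estimators for the domain containers in :mod:`equibind.data`.

Conventions shared by all fits
------------------------------
* K_D (and any rate constant) is constrained positive; initial estimates
  default to an interpolated half-saturation point of the data.
* The default isotherm model carries free amplitude A and y-offset O
  (``A * f(p) + O``) to absorb normalization error; ``free_amplitude`` /
  ``free_offset`` pin them to the theory-clean 1/0.
* 95% confidence intervals are asymptotic: estimate ± t(0.975, dof) * SE
  with SE from the Jacobian covariance at the optimum.
* Identifiability: a fit is flagged ``poorly-defined`` when the 95% CI of
  the key parameter spans more than a 100-fold ratio (including any CI
  touching zero) or the estimate sits within 1% of an imposed bound —
  operationalizing "a meaningful K_D cannot be extracted".
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .data import (
    MIN_FIT_POINTS,
    CompetitionSeries,
    KineticTrace,
    TitrationSeries,
)
from .models import (
    fraction_bound_hyperbolic,
    fraction_bound_quadratic,
    half_saturation_point,
    solve_free_protein,
)

__all__ = [
    "FitResult",
    "ActiveFractionResult",
    "HyperbolicIsotherm",
    "QuadraticIsotherm",
    "ExponentialKinetics",
    "ObservedRateLine",
    "BreakpointTitration",
    "ActiveSiteQuadratic",
    "CompetitionBinding",
    "fit_hyperbolic",
    "fit_quadratic",
    "fit_exponential",
    "fit_kon_koff",
    "fit_active_fraction_breakpoint",
    "fit_active_fraction_quadratic",
    "fit_competition",
    "bootstrap_ci",
]

#: CI fold-span beyond which the key parameter is declared poorly defined
IDENTIFIABILITY_FOLD = 100.0

WELL_DEFINED = "well-defined"
POORLY_DEFINED = "poorly-defined"


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates, uncertainties and quality flags from one fit."""

    model_id: str
    estimates: dict
    se: dict
    ci95: dict
    residuals: np.ndarray
    converged: bool
    identifiability: str
    identifiability_metric: float
    n_points: int
    dof: int
    key_param: str = "kd"
    warnings: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    @property
    def well_defined(self) -> bool:
        return self.converged and self.identifiability == WELL_DEFINED

    def to_dict(self) -> dict:
        d = {
            "model_id": self.model_id,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "ci95": {k: [float(v[0]), float(v[1])]
                     for k, v in self.ci95.items()},
            "converged": bool(self.converged),
            "identifiability": self.identifiability,
            "identifiability_metric": float(self.identifiability_metric),
            "n_points": int(self.n_points),
            "dof": int(self.dof),
            "key_param": self.key_param,
        }
        if self.warnings:
            d["warnings"] = list(self.warnings)
        if self.extras:
            d["extras"] = {k: (float(v) if np.isscalar(v) else v)
                           for k, v in self.extras.items()}
        return d


@dataclass
class ActiveFractionResult:
    """Active protein fraction from a stoichiometric titration."""

    breakpoint_ratio: float
    active_fraction: float
    method: str
    flags: list = field(default_factory=list)
    fit: FitResult | None = None

    def __post_init__(self) -> None:
        if self.breakpoint_ratio <= 0:
            raise ValueError("breakpoint_ratio must be > 0")
        if self.active_fraction > 1.05 and "active_fraction>1" not in self.flags:
            self.flags.append("active_fraction>1")


# --------------------------------------------------------------------------
# shared nonlinear least-squares machinery
# --------------------------------------------------------------------------

def _interp_k_half(x: np.ndarray, y: np.ndarray) -> float:
    """Crude half-saturation abscissa for initializing K_D searches."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    lo, hi = np.min(ys), np.max(ys)
    if hi - lo <= 0:
        return float(np.exp(np.mean(np.log(xs))))
    mid = (lo + hi) / 2.0
    above = ys >= mid
    if above.any() and not above.all():
        i = int(np.argmax(above))
        if i > 0:
            x0, x1 = xs[i - 1], xs[i]
            y0, y1 = ys[i - 1], ys[i]
            if y1 != y0:
                return float(x0 + (mid - y0) * (x1 - x0) / (y1 - y0))
        return float(xs[i])
    return float(np.exp(np.mean(np.log(xs))))


def _ci_fold(lo: float, hi: float) -> float:
    if not np.isfinite(lo) or not np.isfinite(hi) or lo <= 0:
        return math.inf
    return hi / lo


def _identifiability(estimate: float, lo: float, hi: float,
                     bounds: tuple[float, float] | None = None
                     ) -> tuple[str, float]:
    fold = _ci_fold(lo, hi)
    status = WELL_DEFINED if fold <= IDENTIFIABILITY_FOLD else POORLY_DEFINED
    if bounds is not None:
        for b in bounds:
            if np.isfinite(b) and b != 0 and abs(estimate - b) <= 0.01 * abs(b):
                status = POORLY_DEFINED
    return status, fold


def _nls_fit(func, x, y, names, p0, lower, upper, model_id, key_param,
             ) -> FitResult:
    """curve_fit wrapper returning a flagged FitResult (never raises on
    non-convergence)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    dof = max(n - len(p0), 0)
    nan = {k: math.nan for k in names}
    nan_ci = {k: (math.nan, math.nan) for k in names}

    # Fit in normalized parameter space: molar K_D values and order-one
    # amplitudes differ by ~10 decades, which stalls finite-difference
    # trust-region steps; dividing each parameter by its initial magnitude
    # restores machine-precision convergence.
    p0 = np.asarray(p0, dtype=float)
    scale = np.where(p0 != 0, np.abs(p0), 1.0)
    lo_s = np.asarray(lower, dtype=float) / scale
    hi_s = np.asarray(upper, dtype=float) / scale

    def func_scaled(xx, *theta):
        return func(xx, *(np.asarray(theta) * scale))

    converged = True
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", category=optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                func_scaled, x, y, p0=p0 / scale, bounds=(lo_s, hi_s),
                method="trf", maxfev=20000,
                ftol=1e-12, xtol=1e-12, gtol=1e-12)
            popt = popt * scale
            pcov = pcov * np.outer(scale, scale)
    except (RuntimeError, ValueError, ArithmeticError):
        return FitResult(model_id=model_id, estimates=nan, se=nan,
                         ci95=nan_ci, residuals=np.full(n, math.nan),
                         converged=False, identifiability=POORLY_DEFINED,
                         identifiability_metric=math.inf, n_points=n,
                         dof=dof, key_param=key_param,
                         warnings=["fit did not converge"])

    resid = y - func(x, *popt)
    se_vec = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else math.inf
    estimates = dict(zip(names, (float(v) for v in popt)))
    se = dict(zip(names, (float(v) for v in se_vec)))
    ci95 = {k: (estimates[k] - tcrit * se[k], estimates[k] + tcrit * se[k])
            for k in names}
    # the key parameter is strictly positive: report its CI on the log
    # scale (delta method), kd * exp(±t * SE/kd), which cannot cross zero
    kv, ks = estimates[key_param], se[key_param]
    if kv > 0 and np.isfinite(ks):
        rel = min(tcrit * ks / kv, 700.0)  # cap to avoid overflow
        ci95[key_param] = (kv * math.exp(-rel), kv * math.exp(rel))
    warns = []
    if not np.all(np.isfinite(se_vec)):
        warns.append("covariance is singular; uncertainties unreliable")
    i_key = names.index(key_param)
    status, fold = _identifiability(
        estimates[key_param], *ci95[key_param],
        bounds=(lower[i_key], upper[i_key]))
    return FitResult(model_id=model_id, estimates=estimates, se=se,
                     ci95=ci95, residuals=resid, converged=converged,
                     identifiability=status, identifiability_metric=fold,
                     n_points=n, dof=dof, key_param=key_param,
                     warnings=warns)


def _column(X) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 2:
        if arr.shape[1] != 1:
            raise ValueError("X must be a single column")
        arr = arr[:, 0]
    if arr.ndim != 1:
        raise ValueError("X must be 1-d or a single column")
    return arr


def _require_points(n: int, minimum: int = MIN_FIT_POINTS) -> None:
    if n < minimum:
        raise ValueError(f"need at least {minimum} points to fit, got {n}")


# --------------------------------------------------------------------------
# isotherm estimators
# --------------------------------------------------------------------------

class HyperbolicIsotherm(RegressorMixin, BaseEstimator):
    """Binding-regime isotherm fit: ``y = A * p/(p + kd) + O``.

    Valid when the limiting species is trace relative to K_D; applied
    outside that regime it recovers not K_D but the half-saturation point
    kd + r_total/2 (see :class:`QuadraticIsotherm`).

    Attributes after ``fit`` — ``kd_``, ``amplitude_``, ``offset_``,
    ``result_`` (full :class:`FitResult`).
    """

    model_id = "hyperbolic"

    def __init__(self, free_amplitude: bool = True, free_offset: bool = True,
                 kd_init: float | None = None):
        self.free_amplitude = free_amplitude
        self.free_offset = free_offset
        self.kd_init = kd_init

    def _curve(self, p, kd, amplitude, offset):
        return amplitude * fraction_bound_hyperbolic(p, kd) + offset

    def fit(self, X, y):
        x = _column(X)
        y = np.asarray(y, dtype=float)
        _require_points(len(x))
        kd0 = self.kd_init if self.kd_init is not None else _interp_k_half(x, y)
        names = ["kd"]
        p0 = [max(kd0, 1e-30)]
        lower, upper = [0.0], [np.inf]
        if self.free_amplitude:
            names.append("amplitude")
            p0.append(max(float(np.max(y)), 0.1))
            lower.append(0.0)
            upper.append(np.inf)
        if self.free_offset:
            names.append("offset")
            p0.append(0.0)
            lower.append(-np.inf)
            upper.append(np.inf)

        def func(p, *theta):
            d = dict(zip(names, theta))
            return self._curve(p, d["kd"], d.get("amplitude", 1.0),
                               d.get("offset", 0.0))

        res = _nls_fit(func, x, y, names, p0, lower, upper,
                       self.model_id, "kd")
        res.estimates.setdefault("amplitude", 1.0)
        res.estimates.setdefault("offset", 0.0)
        self.result_ = res
        self.kd_ = res.estimates["kd"]
        self.amplitude_ = res.estimates["amplitude"]
        self.offset_ = res.estimates["offset"]
        return self

    def predict(self, X):
        x = _column(X)
        return self._curve(x, self.kd_, self.amplitude_, self.offset_)


class QuadraticIsotherm(HyperbolicIsotherm):
    """Depletion-corrected (quadratic) isotherm fit at known ``r_total``.

    ``y = A * q(p; r_total, kd) + O`` with q the exact 1:1 mass-balance
    fraction bound. r_total is fixed to the known limiting-species
    concentration, not fitted. ``titration_ceiling`` sets the excess ratio
    r_total/kd above which the result carries a titration-regime warning.
    """

    model_id = "quadratic"

    def __init__(self, r_total: float | None = None,
                 free_amplitude: bool = True, free_offset: bool = True,
                 kd_init: float | None = None,
                 titration_ceiling: float = 10.0):
        super().__init__(free_amplitude=free_amplitude,
                         free_offset=free_offset, kd_init=kd_init)
        self.r_total = r_total
        self.titration_ceiling = titration_ceiling

    def _curve(self, p, kd, amplitude, offset):
        return amplitude * fraction_bound_quadratic(
            p, self.r_total, kd) + offset

    def fit(self, X, y):
        if self.r_total is None or self.r_total <= 0:
            raise ValueError("r_total must be set (> 0) for a quadratic fit")
        if self.kd_init is None:
            x = _column(X)
            ya = np.asarray(y, float)
            k_half = _interp_k_half(x, ya)
            # invert K_1/2 = kd + r/2, floored well below the grid
            self._kd0 = max(k_half - self.r_total / 2.0, k_half * 1e-4)
        else:
            self._kd0 = self.kd_init
        saved = self.kd_init
        try:
            self.kd_init = self._kd0
            super().fit(X, y)
        finally:
            self.kd_init = saved
        res = self.result_
        if res.converged and res.estimates["kd"] > 0:
            ratio = self.r_total / res.estimates["kd"]
            res.extras["excess_ratio"] = ratio
            if ratio > self.titration_ceiling:
                res.warnings.append(
                    f"titration regime: r_total/kd = {ratio:.3g} exceeds "
                    f"ceiling {self.titration_ceiling:g}")
        return self


# --------------------------------------------------------------------------
# kinetics estimators
# --------------------------------------------------------------------------

class ExponentialKinetics(RegressorMixin, BaseEstimator):
    """Single-exponential time-course fit.

    association: ``y = A * (1 - exp(-k_obs t)) + O``;
    dissociation: ``y = A * exp(-k_obs t) + O``. For a chase (dissociation)
    experiment k_obs is koff directly. A constant or signal-free trace is
    returned flagged non-converged rather than yielding a silent number.
    """

    model_id = "exponential"

    def __init__(self, mode: str = "association", free_offset: bool = False):
        self.mode = mode
        self.free_offset = free_offset

    def _curve(self, t, k_obs, amplitude, offset):
        if self.mode == "association":
            return amplitude * (-np.expm1(-k_obs * t)) + offset
        return amplitude * np.exp(-k_obs * t) + offset

    def fit(self, X, y):
        if self.mode not in ("association", "dissociation"):
            raise ValueError("mode must be 'association' or 'dissociation'")
        t = _column(X)
        y = np.asarray(y, dtype=float)
        _require_points(len(t))
        span = float(np.ptp(y))
        names = ["k_obs", "amplitude"]
        if span < 1e-12:
            self.result_ = FitResult(
                model_id=self.model_id,
                estimates={k: math.nan for k in names},
                se={k: math.nan for k in names},
                ci95={k: (math.nan, math.nan) for k in names},
                residuals=np.full(len(t), math.nan), converged=False,
                identifiability=POORLY_DEFINED,
                identifiability_metric=math.inf,
                n_points=len(t), dof=len(t) - 2, key_param="k_obs",
                warnings=["no signal change in trace"])
            self.k_obs_ = math.nan
            self.amplitude_ = math.nan
            self.offset_ = 0.0
            return self

        amp0 = span
        # half-change time for the rate initial estimate
        tpos = t[t > 0]
        tscale = float(np.median(tpos)) if len(tpos) else 1.0
        k0 = math.log(2.0) / tscale
        p0 = [k0, amp0]
        lower, upper = [0.0, 0.0], [np.inf, np.inf]
        if self.free_offset:
            names = names + ["offset"]
            p0.append(float(np.min(y)) if self.mode == "dissociation" else 0.0)
            lower.append(-np.inf)
            upper.append(np.inf)

        def func(tt, *theta):
            d = dict(zip(names, theta))
            return self._curve(tt, d["k_obs"], d["amplitude"],
                               d.get("offset", 0.0))

        res = _nls_fit(func, t, y, names, p0, lower, upper,
                       self.model_id, "k_obs")
        res.estimates.setdefault("offset", 0.0)
        if self.mode == "dissociation" and res.converged:
            res.extras["koff"] = res.estimates["k_obs"]
        # SNR sanity: amplitude must clear its own uncertainty
        if res.converged and res.dof > 0:
            se_a = res.se.get("amplitude", math.nan)
            if np.isfinite(se_a) and res.estimates["amplitude"] < 2 * se_a:
                res.warnings.append("amplitude not significant (SNR check)")
                res.identifiability = POORLY_DEFINED
        self.result_ = res
        self.k_obs_ = res.estimates["k_obs"]
        self.amplitude_ = res.estimates["amplitude"]
        self.offset_ = res.estimates["offset"]
        return self

    def predict(self, X):
        t = _column(X)
        return self._curve(t, self.k_obs_, self.amplitude_, self.offset_)


class ObservedRateLine(RegressorMixin, BaseEstimator):
    """Linear fit of observed equilibration rates vs concentration.

    ``k_obs = kon * [P] + koff``: the slope is the association rate
    constant, the intercept the dissociation rate constant, and
    K_D = koff/kon follows with first-order error propagation. Ordinary
    least squares by default (slope and standard error of the linear fit);
    optional inverse-variance weights. ``active_fraction`` corrects the
    slope for partially active protein (kon = slope / f_active).
    """

    model_id = "linear"

    def __init__(self, weights=None, active_fraction: float = 1.0):
        self.weights = weights
        self.active_fraction = active_fraction

    def fit(self, X, y):
        p = _column(X)
        k_obs = np.asarray(y, dtype=float)
        if len(np.unique(p)) < 2:
            raise ValueError("need at least 2 distinct concentrations")
        warns = []
        if len(np.unique(p)) < 3:
            warns.append("fewer than 3 distinct concentrations; "
                         "slope/intercept poorly constrained")
        n = len(p)
        if self.weights is None:
            w = np.ones(n)
        else:
            w = np.asarray(self.weights, dtype=float)
        sw = np.sqrt(w)
        A = np.column_stack([p * sw, sw])
        coef, _, _, _ = np.linalg.lstsq(A, k_obs * sw, rcond=None)
        slope, intercept = float(coef[0]), float(coef[1])
        resid = k_obs - (slope * p + intercept)
        dof = n - 2
        if dof > 0:
            s2 = float(np.sum(w * resid ** 2) / dof)
            cov = s2 * np.linalg.inv(A.T @ A)
            se_slope = math.sqrt(max(cov[0, 0], 0.0))
            se_int = math.sqrt(max(cov[1, 1], 0.0))
        else:
            se_slope = se_int = math.nan
        f = self.active_fraction
        kon = slope / f
        se_kon = se_slope / f
        koff = intercept
        if koff < 0:
            warns.append("negative fitted intercept: koff reported as an "
                         "upper limit only")
        kd = koff / kon if kon > 0 else math.nan
        if kon > 0 and koff > 0:
            se_kd = abs(kd) * math.sqrt((se_kon / kon) ** 2
                                        + (se_int / koff) ** 2)
        else:
            se_kd = math.nan
        tcrit = stats.t.ppf(0.975, dof) if dof > 0 else math.inf
        estimates = {"kon": kon, "koff": koff, "kd": kd}
        se = {"kon": se_kon, "koff": se_int, "kd": se_kd}
        ci95 = {k: (estimates[k] - tcrit * se[k], estimates[k] + tcrit * se[k])
                for k in estimates}
        if kd > 0 and np.isfinite(se_kd):  # log-scale CI for positive kd
            rel = min(tcrit * se_kd / kd, 700.0)
            ci95["kd"] = (kd * math.exp(-rel), kd * math.exp(rel))
        status, fold = _identifiability(kd, *ci95["kd"])
        self.result_ = FitResult(
            model_id=self.model_id, estimates=estimates, se=se, ci95=ci95,
            residuals=resid, converged=np.isfinite(kon),
            identifiability=status, identifiability_metric=fold,
            n_points=n, dof=dof, key_param="kd", warnings=warns,
            extras={"active_fraction": f})
        self.kon_ = kon
        self.koff_ = koff
        self.kd_ = kd
        return self

    def predict(self, X):
        p = _column(X)
        return self.kon_ * self.active_fraction * p + self.koff_


# --------------------------------------------------------------------------
# active-fraction estimators
# --------------------------------------------------------------------------

class BreakpointTitration(BaseEstimator):
    """Active-fraction determination by two-line breakpoint titration.

    With ligand held far above K_D, fraction bound rises linearly with the
    protein:ligand ratio until the active protein saturates the ligand and
    the curve flattens. The intersection of straight-line fits to the low
    and high segments (exhaustive search over contiguous splits, >= 3
    points each) is the breakpoint ratio; its reciprocal is the active
    fraction. A breakpoint ratio of 2.0 means half the protein is active.
    """

    model_id = "breakpoint"

    def __init__(self, ligand_total: float | None = None,
                 min_points: int = 3, measured_kd: float | None = None,
                 parallel_angle_deg: float = 2.0):
        self.ligand_total = ligand_total
        self.min_points = min_points
        self.measured_kd = measured_kd
        self.parallel_angle_deg = parallel_angle_deg

    def fit(self, X, y):
        if self.ligand_total is None or self.ligand_total <= 0:
            raise ValueError("ligand_total must be set (> 0)")
        p = _column(X)
        y = np.asarray(y, dtype=float)
        if len(p) < 2 * self.min_points:
            raise ValueError(
                f"need at least {2 * self.min_points} points "
                f"({self.min_points} per segment)")
        warns = []
        if (self.measured_kd is not None
                and self.ligand_total < 10 * self.measured_kd):
            warns.append("ligand_total is not >= 10x the measured kd; "
                         "breakpoint may be rounded by binding curvature")
        ratio = p / self.ligand_total
        order = np.argsort(ratio)
        xr, yr = ratio[order], y[order]
        n = len(xr)

        best = None
        for i in range(self.min_points, n - self.min_points + 1):
            c1 = np.polyfit(xr[:i], yr[:i], 1)
            c2 = np.polyfit(xr[i:], yr[i:], 1)
            sse = (np.sum((yr[:i] - np.polyval(c1, xr[:i])) ** 2)
                   + np.sum((yr[i:] - np.polyval(c2, xr[i:])) ** 2))
            cand = (sse, abs(xr[i - 1] - 1.0), i, c1, c2)
            if best is None or cand[:2] < best[:2]:
                best = cand
        _, _, i, c1, c2 = best
        m1, b1 = c1
        m2, b2 = c2
        angle = abs(math.degrees(math.atan(m1) - math.atan(m2)))
        self.flags_ = list(warns)
        if angle < self.parallel_angle_deg:
            self.flags_.append("segments near-parallel: no breakpoint")
            self.breakpoint_ratio_ = math.nan
            self.active_fraction_ = math.nan
            self.segments_ = ((m1, b1), (m2, b2))
            return self
        x_star = (b2 - b1) / (m1 - m2)
        self.breakpoint_ratio_ = float(x_star)
        self.active_fraction_ = float(1.0 / x_star)
        if self.active_fraction_ > 1.05:
            self.flags_.append("active_fraction>1")
        self.segments_ = ((float(m1), float(b1)), (float(m2), float(b2)))
        self.split_index_ = int(i)
        return self


class ActiveSiteQuadratic(QuadraticIsotherm):
    """Joint fit of active fraction and K_D to stoichiometric-titration data.

    Replaces p_total by ``f_active * p_total`` in the quadratic isotherm
    with r_total fixed at the (intentionally saturating) ligand
    concentration, estimating f_active and kd together — the curve-fitting
    alternative to the two-line breakpoint construction.
    """

    model_id = "active-quadratic"

    def __init__(self, r_total: float | None = None,
                 free_amplitude: bool = True, free_offset: bool = False,
                 kd_init: float | None = None,
                 titration_ceiling: float = math.inf):
        super().__init__(r_total=r_total, free_amplitude=free_amplitude,
                         free_offset=free_offset, kd_init=kd_init,
                         titration_ceiling=titration_ceiling)

    def fit(self, X, y):
        if self.r_total is None or self.r_total <= 0:
            raise ValueError("r_total (total ligand) must be set (> 0)")
        x = _column(X)
        ya = np.asarray(y, dtype=float)
        _require_points(len(x))
        kd0 = (self.kd_init if self.kd_init is not None
               else self.r_total / 100.0)
        names = ["active_fraction", "kd"]
        p0 = [1.0, kd0]
        lower = [1e-6, 0.0]
        upper = [1.5, np.inf]
        if self.free_amplitude:
            names.append("amplitude")
            p0.append(max(float(np.max(ya)), 0.1))
            lower.append(0.0)
            upper.append(np.inf)
        if self.free_offset:
            names.append("offset")
            p0.append(0.0)
            lower.append(-np.inf)
            upper.append(np.inf)

        def func(p, *theta):
            d = dict(zip(names, theta))
            return (d.get("amplitude", 1.0)
                    * fraction_bound_quadratic(d["active_fraction"] * p,
                                               self.r_total, d["kd"])
                    + d.get("offset", 0.0))

        res = _nls_fit(func, x, ya, names, p0, lower, upper,
                       self.model_id, "active_fraction")
        res.estimates.setdefault("amplitude", 1.0)
        res.estimates.setdefault("offset", 0.0)
        if res.converged and res.estimates["active_fraction"] > 1.05:
            res.warnings.append("active_fraction estimate > 1.05")
        self.result_ = res
        self.active_fraction_ = res.estimates["active_fraction"]
        self.kd_ = res.estimates["kd"]
        self.amplitude_ = res.estimates["amplitude"]
        self.offset_ = res.estimates["offset"]
        return self

    def predict(self, X):
        x = _column(X)
        return (self.amplitude_
                * fraction_bound_quadratic(self.active_fraction_ * x,
                                           self.r_total, self.kd_)
                + self.offset_)


# --------------------------------------------------------------------------
# competition estimator
# --------------------------------------------------------------------------

class CompetitionBinding(RegressorMixin, BaseEstimator):
    """Competitor K_D from displacement of a labeled trace species.

    The labeled fraction bound at each competitor concentration is
    predicted from the exact coupled 1:1 mass balance (no IC50
    approximation): free protein solves
    ``p_total = P_free (1 + r_lab/(P_free + kd_labeled)
    + c/(P_free + kd_competitor))`` and labeled binding is
    ``P_free/(P_free + kd_labeled)``. The labeled species is dropped from
    the balance when below ``trace_threshold`` of the protein
    concentration. kd_labeled and p_total are fixed from prior direct
    measurement; only kd_competitor (plus optional A, O) is estimated.
    """

    model_id = "competition"

    def __init__(self, p_total: float | None = None,
                 kd_labeled: float | None = None,
                 r_total_labeled: float = 0.0,
                 free_amplitude: bool = True, free_offset: bool = False,
                 trace_threshold: float = 0.01,
                 min_transition: float = 0.3):
        self.p_total = p_total
        self.kd_labeled = kd_labeled
        self.r_total_labeled = r_total_labeled
        self.free_amplitude = free_amplitude
        self.free_offset = free_offset
        self.trace_threshold = trace_threshold
        self.min_transition = min_transition

    def _labeled_fraction(self, c_arr, kd_c):
        r_lab = self.r_total_labeled
        if r_lab < self.trace_threshold * self.p_total:
            r_lab = 0.0
        out = np.empty(len(c_arr))
        for j, c in enumerate(c_arr):
            pf = solve_free_protein(self.p_total, r_lab, self.kd_labeled,
                                    c_total=float(c),
                                    kd_competitor=kd_c if c > 0 else None)
            out[j] = pf / (pf + self.kd_labeled)
        return out

    def fit(self, X, y):
        if self.p_total is None or self.p_total <= 0:
            raise ValueError("p_total must be set (> 0)")
        if self.kd_labeled is None or self.kd_labeled <= 0:
            raise ValueError("kd_labeled must be set (> 0)")
        c = _column(X)
        y = np.asarray(y, dtype=float)
        _require_points(len(c))
        if np.all(c == 0):
            raise ValueError("all competitor concentrations are zero: "
                             "no competitor kd is estimable")
        warns = []
        if float(np.ptp(y)) < self.min_transition:
            warns.append("competitor range does not bracket the binding "
                         "transition (signal change < "
                         f"{self.min_transition:g})")

        # coarse log-grid search for the initial competitor kd
        cpos = c[c > 0]
        grid = np.geomspace(self.kd_labeled * 1e-4,
                            max(cpos.max(), self.kd_labeled) * 1e2, 25)
        sse = [float(np.sum((y - self._labeled_fraction(c, g)) ** 2))
               for g in grid]
        kd0 = float(grid[int(np.argmin(sse))])

        names = ["kd_competitor"]
        p0 = [kd0]
        lower, upper = [0.0], [np.inf]
        if self.free_amplitude:
            names.append("amplitude")
            p0.append(max(float(np.max(y)), 0.1))
            lower.append(0.0)
            upper.append(np.inf)
        if self.free_offset:
            names.append("offset")
            p0.append(0.0)
            lower.append(-np.inf)
            upper.append(np.inf)

        def func(cc, *theta):
            d = dict(zip(names, theta))
            return (d.get("amplitude", 1.0)
                    * self._labeled_fraction(cc, d["kd_competitor"])
                    + d.get("offset", 0.0))

        res = _nls_fit(func, c, y, names, p0, lower, upper,
                       self.model_id, "kd_competitor")
        res.estimates.setdefault("amplitude", 1.0)
        res.estimates.setdefault("offset", 0.0)
        res.warnings.extend(warns)
        if warns:
            res.identifiability = POORLY_DEFINED
        self.result_ = res
        self.kd_competitor_ = res.estimates["kd_competitor"]
        self.amplitude_ = res.estimates["amplitude"]
        self.offset_ = res.estimates["offset"]
        return self

    def predict(self, X):
        c = _column(X)
        return (self.amplitude_ * self._labeled_fraction(c, self.kd_competitor_)
                + self.offset_)


# --------------------------------------------------------------------------
# wrapper functions over the estimators
# --------------------------------------------------------------------------

def fit_hyperbolic(series: TitrationSeries, free_amplitude: bool = True,
                   free_offset: bool = True,
                   kd_init: float | None = None) -> FitResult:
    """Binding-regime fit of a titration series; see HyperbolicIsotherm."""
    est = HyperbolicIsotherm(free_amplitude=free_amplitude,
                             free_offset=free_offset, kd_init=kd_init)
    est.fit(series.p_total, series.fraction_bound)
    return est.result_


def fit_quadratic(series: TitrationSeries, free_amplitude: bool = True,
                  free_offset: bool = True, kd_init: float | None = None,
                  r_total: float | None = None,
                  titration_ceiling: float = 10.0) -> FitResult:
    """Depletion-corrected fit; r_total defaults to the series' lower bound.

    When the series carries distinct (low, high) bounds on the
    limiting-species concentration the fit is repeated at the upper bound
    and the spread of kd is reported as systematic uncertainty in
    ``extras``.
    """
    r = series.r_total_low if r_total is None else r_total
    est = QuadraticIsotherm(r_total=r, free_amplitude=free_amplitude,
                            free_offset=free_offset, kd_init=kd_init,
                            titration_ceiling=titration_ceiling)
    est.fit(series.p_total, series.fraction_bound)
    res = est.result_
    if (r_total is None and series.r_total_high > series.r_total_low > 0):
        est_hi = QuadraticIsotherm(
            r_total=series.r_total_high, free_amplitude=free_amplitude,
            free_offset=free_offset, kd_init=kd_init,
            titration_ceiling=titration_ceiling)
        est_hi.fit(series.p_total, series.fraction_bound)
        kd_hi = est_hi.result_.estimates["kd"]
        res.extras["kd_at_r_high"] = kd_hi
        if res.converged and est_hi.result_.converged:
            res.extras["kd_systematic_spread"] = abs(
                kd_hi - res.estimates["kd"])
    return res


def fit_exponential(trace: KineticTrace,
                    free_offset: bool = False) -> FitResult:
    """Single-exponential fit of a kinetic trace; k_obs = koff for a chase."""
    est = ExponentialKinetics(mode=trace.mode, free_offset=free_offset)
    est.fit(trace.t, trace.fraction_bound)
    return est.result_


def fit_kon_koff(k_obs_points, weights=None,
                 active_fraction: float = 1.0) -> FitResult:
    """Linear k_obs-vs-[P] analysis from a list of (p, k_obs) pairs."""
    pts = np.asarray(k_obs_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("k_obs_points must be a sequence of (p, k_obs) pairs")
    est = ObservedRateLine(weights=weights, active_fraction=active_fraction)
    est.fit(pts[:, 0], pts[:, 1])
    return est.result_


def fit_active_fraction_breakpoint(titration: TitrationSeries,
                                   ligand_total: float,
                                   measured_kd: float | None = None,
                                   ) -> ActiveFractionResult:
    """Active fraction from the two-line breakpoint construction."""
    est = BreakpointTitration(ligand_total=ligand_total,
                              measured_kd=measured_kd)
    est.fit(titration.p_total, titration.fraction_bound)
    if not np.isfinite(est.breakpoint_ratio_):
        raise ValueError("no breakpoint: " + "; ".join(est.flags_))
    return ActiveFractionResult(breakpoint_ratio=est.breakpoint_ratio_,
                                active_fraction=est.active_fraction_,
                                method="breakpoint", flags=est.flags_)


def fit_active_fraction_quadratic(titration: TitrationSeries,
                                  ligand_total: float,
                                  free_amplitude: bool = True,
                                  free_offset: bool = False,
                                  kd_init: float | None = None,
                                  ) -> ActiveFractionResult:
    """Active fraction as a coefficient of the quadratic isotherm."""
    est = ActiveSiteQuadratic(r_total=ligand_total,
                              free_amplitude=free_amplitude,
                              free_offset=free_offset, kd_init=kd_init)
    est.fit(titration.p_total, titration.fraction_bound)
    res = est.result_
    f = res.estimates["active_fraction"]
    return ActiveFractionResult(
        breakpoint_ratio=1.0 / f if f > 0 else math.inf,
        active_fraction=f, method="quadratic-coefficient",
        flags=list(res.warnings), fit=res)


def fit_competition(comp: CompetitionSeries, free_amplitude: bool = True,
                    free_offset: bool = False) -> FitResult:
    """Competitor K_D from a displacement series; see CompetitionBinding."""
    est = CompetitionBinding(p_total=comp.p_total,
                             kd_labeled=comp.kd_labeled,
                             r_total_labeled=comp.r_total_labeled,
                             free_amplitude=free_amplitude,
                             free_offset=free_offset)
    est.fit(comp.c_total, comp.fraction_bound)
    return est.result_


def bootstrap_ci(estimator, X, y, param: str, n_boot: int = 200,
                 seed: int = 0, level: float = 0.95) -> tuple[float, float]:
    """Seeded residual-resampling bootstrap CI for one fitted parameter.

    A small-sample alternative to the asymptotic intervals: refits the
    (cloned) estimator on fitted values plus resampled residuals.
    """
    from sklearn.base import clone

    base = clone(estimator).fit(X, y)
    yhat = base.predict(X)
    resid = np.asarray(y, float) - yhat
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_boot):
        yb = yhat + rng.choice(resid, size=len(resid), replace=True)
        try:
            eb = clone(estimator).fit(X, yb)
            v = eb.result_.estimates[param]
            if np.isfinite(v):
                vals.append(v)
        except (ValueError, RuntimeError):
            continue
    if len(vals) < max(10, n_boot // 4):
        raise RuntimeError("too few successful bootstrap refits")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
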