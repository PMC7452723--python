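"""Required controls and regime logic for equilibrium binding campaigns.

Two empirical controls are mandatory before a fitted K_D can be called an
equilibrium constant:

* **equilibration** — the binding curve must be invariant to incubation
  time (tested over at least a 10-fold time span), and
* **titration** — the fitted K_D must be invariant to the limiting-species
  concentration (tested over at least a 5-fold span).

Both checks compare per-condition K_D fits with a CI-aware rule: a *fail*
requires the point-estimate fold-change to exceed the tolerance AND the
95% confidence intervals to be disjoint, so noise alone cannot fail a
campaign. An observed, CI-supported change is evidence against equilibrium
regardless of the span tested; the minimum-span rule only downgrades
would-be passes to ``insufficient-design``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import TitrationSeries
from .fit import FitResult, fit_hyperbolic, fit_quadratic
from .models import BindingParameters, dissociation_remaining, half_saturation_point
from .simulate import SimulationDesign, simulate_titration_series

__all__ = [
    "RegimeAssessment",
    "ControlVerdict",
    "WashSurvival",
    "REGIME_THRESHOLDS",
    "classify_regime",
    "check_equilibration",
    "check_titration",
    "recovery_study",
    "wash_survival",
]

#: (binding_upper, intermediate_upper) excess-ratio boundaries per profile.
#: The binding boundary is 0.15 rather than a strict 0.1 so that a
#: limiting-species excess of ~0.15 over K_D — comfortably trace in
#: practice — still classifies as the binding regime. High-precision
#: techniques that resolve each titration increment (ITC-class data)
#: tolerate up to 1000-fold excess before the fit loses K_D information.
REGIME_THRESHOLDS = {
    "generic": (0.15, 10.0),
    "high-precision": (0.15, 1000.0),
}


@dataclass(frozen=True)
class RegimeAssessment:
    """Classification of a titration's concentration regime."""

    regime: str               # binding | intermediate | titration
    excess_ratio: float       # r_total / kd
    k_half: float             # expected half-saturation point (M)
    thresholds_used: tuple
    technique_profile: str


@dataclass
class ControlVerdict:
    """Outcome of an invariance control (equilibration or titration)."""

    control: str              # equilibration | titration
    status: str               # pass | fail | insufficient-design
    evidence: list            # per-condition dicts: condition, kd, ci95
    fold_span_tested: float
    fold_change_observed: float
    messages: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "control": self.control,
            "status": self.status,
            "fold_span_tested": float(self.fold_span_tested),
            "fold_change_observed": float(self.fold_change_observed),
            "evidence": self.evidence,
            "messages": list(self.messages),
        }


@dataclass(frozen=True)
class WashSurvival:
    """Complex surviving a wash step, with a categorical interpretation."""

    fraction: float
    interpretation: str       # detectable | marginal | lost
    cutoffs: tuple


def classify_regime(kd_estimate: float, r_total: float,
                    profile: str = "generic") -> RegimeAssessment:
    """Classify binding / intermediate / titration from r_total / kd."""
    if kd_estimate <= 0 or r_total < 0:
        raise ValueError("kd_estimate must be > 0 and r_total >= 0")
    try:
        lower, upper = REGIME_THRESHOLDS[profile]
    except KeyError:
        raise ValueError(f"unknown profile {profile!r}; "
                         f"choose from {sorted(REGIME_THRESHOLDS)}") from None
    ratio = r_total / kd_estimate
    if ratio <= lower:
        regime = "binding"
    elif ratio <= upper:
        regime = "intermediate"
    else:
        regime = "titration"
    return RegimeAssessment(regime=regime, excess_ratio=ratio,
                            k_half=half_saturation_point(r_total, kd_estimate),
                            thresholds_used=(lower, upper),
                            technique_profile=profile)


# --------------------------------------------------------------------------
# invariance controls
# --------------------------------------------------------------------------

def _fit_series(series: TitrationSeries, model) -> FitResult:
    if callable(model):
        return model(series)
    if model == "hyperbolic":
        return fit_hyperbolic(series)
    if model == "quadratic":
        return fit_quadratic(series)
    raise ValueError("model must be 'hyperbolic', 'quadratic' or a callable")


def _ci_disjoint(a: tuple, b: tuple) -> bool:
    return a[1] < b[0] or b[1] < a[0]


def _invariance_verdict(control: str, conditions: list, fits: list,
                        tolerance: float, min_span: float) -> ControlVerdict:
    evidence = []
    for cond, res in zip(conditions, fits):
        evidence.append({
            "condition": float(cond),
            "kd": float(res.estimates.get("kd", math.nan)),
            "ci95": [float(v) for v in res.ci95.get("kd", (math.nan,) * 2)],
            "converged": bool(res.converged),
            "identifiability": res.identifiability,
        })
    conds = np.asarray(conditions, float)
    span = float(conds.max() / conds.min()) if conds.min() > 0 else math.inf
    kds = np.array([e["kd"] for e in evidence])
    usable = np.isfinite(kds) & (kds > 0)
    messages = []
    if usable.sum() < 2:
        return ControlVerdict(control=control, status="insufficient-design",
                              evidence=evidence, fold_span_tested=span,
                              fold_change_observed=math.nan,
                              messages=["fewer than two usable fits"])
    fold = float(kds[usable].max() / kds[usable].min())

    # CI-aware failure: point-estimate change beyond tolerance AND
    # statistically resolved (disjoint 95% CIs) for at least one pair
    failed = False
    idx = np.flatnonzero(usable)
    for ii in range(len(idx)):
        for jj in range(ii + 1, len(idx)):
            a, b = evidence[idx[ii]], evidence[idx[jj]]
            pair_fold = max(a["kd"], b["kd"]) / min(a["kd"], b["kd"])
            if pair_fold > tolerance and _ci_disjoint(tuple(a["ci95"]),
                                                      tuple(b["ci95"])):
                failed = True
    if failed:
        status = "fail"
        messages.append(
            f"kd varies {fold:.2g}-fold across conditions with disjoint CIs")
    elif span < min_span:
        status = "insufficient-design"
        messages.append(
            f"condition span {span:.2g}-fold is below the required "
            f"{min_span:g}-fold minimum")
    else:
        status = "pass"
        if fold > tolerance:
            messages.append(
                f"kd fold-change {fold:.2g} exceeds tolerance but CIs "
                "overlap; treated as noise")
    return ControlVerdict(control=control, status=status, evidence=evidence,
                          fold_span_tested=span, fold_change_observed=fold,
                          messages=messages)


def check_equilibration(series_by_time: list, model="hyperbolic",
                        tolerance: float = 1.5,
                        min_time_span: float = 10.0) -> ControlVerdict:
    """Equilibration control: K_D invariance across incubation times.

    Each series must carry ``incubation_time``. Fails when apparent K_D
    changes more than ``tolerance``-fold between times with disjoint CIs;
    a change-free design spanning under ``min_time_span``-fold in time is
    insufficient to certify equilibration.
    """
    if len(series_by_time) < 2:
        return ControlVerdict(control="equilibration",
                              status="insufficient-design", evidence=[],
                              fold_span_tested=1.0,
                              fold_change_observed=math.nan,
                              messages=["need series at >= 2 incubation times"])
    times = []
    for s in series_by_time:
        if s.incubation_time is None or s.incubation_time <= 0:
            raise ValueError("every series needs a positive incubation_time")
        times.append(s.incubation_time)
    fits = [_fit_series(s, model) for s in series_by_time]
    return _invariance_verdict("equilibration", times, fits,
                               tolerance, min_time_span)


def check_titration(series_by_rtotal: list, model="hyperbolic",
                    tolerance: float = 1.5,
                    min_rtotal_span: float = 5.0) -> ControlVerdict:
    """Titration control: K_D invariance across limiting-species levels."""
    if len(series_by_rtotal) < 2:
        return ControlVerdict(control="titration",
                              status="insufficient-design", evidence=[],
                              fold_span_tested=1.0,
                              fold_change_observed=math.nan,
                              messages=["need series at >= 2 limiting "
                                        "concentrations"])
    rts = []
    for s in series_by_rtotal:
        if s.r_total_low <= 0:
            raise ValueError("every series needs r_total_low > 0")
        rts.append(s.r_total_low)
    fits = [_fit_series(s, model) for s in series_by_rtotal]
    return _invariance_verdict("titration", rts, fits,
                               tolerance, min_rtotal_span)


# --------------------------------------------------------------------------
# replicate recovery study
# --------------------------------------------------------------------------

def recovery_study(r_totals, noise_sds, truth: BindingParameters,
                   n_replicates: int = 10, seed: int = 0,
                   dilution_factor: float = 2.0):
    """Parameter-recovery benchmark over a limiting-concentration x noise grid.

    For each (r_total, noise_sd) condition, ``n_replicates`` synthetic
    titrations are generated and fit individually — with the hyperbolic
    model when the limiting species is trace (r_total <= 0.01 * kd), the
    quadratic model (r_total fixed to truth) otherwise. Returns a pandas
    DataFrame with one row per condition: median and IQR of recovered kd,
    median fold error, median CI fold-span, and the rate of
    poorly-defined / non-converged fits. Fit failures are tallied, not
    raised. Fully reproducible from ``seed``.
    """
    import pandas as pd

    rows = []
    for ci, r in enumerate(r_totals):
        for cj, sd in enumerate(noise_sds):
            design = SimulationDesign(
                params=truth, r_total=r, noise_sd=sd,
                n_replicates=n_replicates,
                dilution_factor=dilution_factor,
                seed=(int(seed) * 10007 + ci * 101 + cj) % (2 ** 31))
            model = ("hyperbolic" if design.in_trace_regime else "quadratic")
            kds, folds, poorly, failures = [], [], 0, 0
            for series in simulate_titration_series(design):
                try:
                    res = _fit_series(series, model)
                except ValueError:
                    failures += 1
                    continue
                if not res.converged:
                    failures += 1
                    poorly += 1
                    continue
                kds.append(res.estimates["kd"])
                folds.append(res.identifiability_metric)
                if res.identifiability != "well-defined":
                    poorly += 1
            kds = np.asarray(kds)
            rows.append({
                "r_total": r,
                "noise_sd": sd,
                "model": model,
                "excess_ratio": r / truth.kd,
                "n_fits": len(kds),
                "n_failed": failures,
                "kd_median": float(np.median(kds)) if len(kds) else math.nan,
                "kd_iqr": (float(np.subtract(*np.percentile(kds, [75, 25])))
                           if len(kds) else math.nan),
                "fold_error_median": (float(np.median(
                    np.maximum(kds / truth.kd, truth.kd / kds)))
                    if len(kds) else math.nan),
                "ci_fold_median": (float(np.median(folds))
                                   if folds else math.nan),
                "poorly_defined_rate": poorly / n_replicates,
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# wash survival
# --------------------------------------------------------------------------

#: survival-fraction cutoffs: >= first -> detectable, >= second -> marginal
WASH_CUTOFFS = (0.25, 0.01)


def wash_survival(koff: float, wash_time: float,
                  cutoffs: tuple = WASH_CUTOFFS) -> WashSurvival:
    """Fraction of complex surviving a wash, with an interpretation.

    'No binding' in a separation-based assay (pull-down, gel shift) may
    simply mean the complex dissociated during washing: survival is
    exp(-koff * t). Interpretation: ``detectable`` (>= cutoffs[0]),
    ``marginal`` (>= cutoffs[1]) or ``lost``.
    """
    frac = float(dissociation_remaining(koff, wash_time))
    if frac >= cutoffs[0]:
        label = "detectable"
    elif frac >= cutoffs[1]:
        label = "marginal"
    else:
        label = "lost"
    return WashSurvival(fraction=frac, interpretation=label, cutoffs=cutoffs)
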