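"""Closed-form equations for 1:1 non-cooperative binding equilibria and kinetics.

All quantities are strict SI: concentrations in molar (M), times in seconds,
rate constants in s^-1 (dissociation) or M^-1 s^-1 (association). Unit
conversions (nM, pM, hours, ...) belong at the I/O boundary, never here.

The model is the elementary scheme

    P + R  <=>  P·R        K_D = k_off / k_on

with P the variable ("excess") partner and R the limiting ("trace") partner.
Three descriptions of the equilibrium are provided:

* ``fraction_bound_free``       — exact in the *free* P concentration,
* ``fraction_bound_hyperbolic`` — the binding-regime approximation
  ([P]_free ≈ [P]_total, valid when [R]_total << K_D),
* ``fraction_bound_quadratic``  — the exact mass-balance (ligand-depletion)
  solution in *total* concentrations, valid outside the titration regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BindingParameters",
    "ConcentrationState",
    "KineticPrediction",
    "fraction_bound_free",
    "fraction_bound_hyperbolic",
    "fraction_bound_quadratic",
    "solve_free_protein",
    "equilibration_rate",
    "equilibration_time",
    "fraction_bound_at_time",
    "dissociation_remaining",
    "half_saturation_point",
    "ceil_to_sigfigs",
    "round_to_sigfigs",
    "format_equilibration_time",
    "equilibration_time_table",
]

LN2 = math.log(2.0)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingParameters:
    """The thermodynamic/kinetic parameter set of a 1:1 interaction.

    Parameters
    ----------
    kd : float
        Equilibrium dissociation constant (M). Required, > 0.
    kon : float, optional
        Association rate constant (M^-1 s^-1), > 0 when given.
    koff : float, optional
        Dissociation rate constant (s^-1), > 0 when given.
    active_fraction : float
        Fraction of the variable partner competent to bind, in (0, 1].
    rtol : float
        Relative tolerance for the thermodynamic consistency check
        kd == koff/kon when both rate constants are supplied.
    """

    kd: float
    kon: float | None = None
    koff: float | None = None
    active_fraction: float = 1.0
    rtol: float = 0.01

    def __post_init__(self) -> None:
        if not (self.kd > 0):
            raise ValueError(f"kd must be > 0, got {self.kd!r}")
        for name in ("kon", "koff"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise ValueError(f"{name} must be > 0 when given, got {v!r}")
        if not (0 < self.active_fraction <= 1):
            raise ValueError(
                f"active_fraction must be in (0, 1], got {self.active_fraction!r}"
            )
        if self.kon is not None and self.koff is not None:
            implied = self.koff / self.kon
            if abs(implied - self.kd) > self.rtol * self.kd:
                raise ValueError(
                    f"inconsistent parameters: koff/kon = {implied:.4g} M but "
                    f"kd = {self.kd:.4g} M (relative tolerance {self.rtol})"
                )

    @classmethod
    def from_rates(cls, kon: float, koff: float, active_fraction: float = 1.0
                   ) -> "BindingParameters":
        """Build a parameter set from rate constants, with kd = koff/kon."""
        return cls(kd=koff / kon, kon=kon, koff=koff,
                   active_fraction=active_fraction)


@dataclass(frozen=True)
class ConcentrationState:
    """Total and free concentrations of one equilibrium condition (molar)."""

    p_total: float
    r_total: float
    p_free: float
    c_total: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_total", "r_total", "p_free", "c_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.p_free > self.p_total * (1 + 1e-12):
            raise ValueError("p_free cannot exceed p_total")


@dataclass(frozen=True)
class KineticPrediction:
    """Equilibration kinetics summary: rate, half-life and n-half-life time."""

    k_equil: float
    t_half: float
    t_equil: float
    n_halflives: float = 5.0

    def __post_init__(self) -> None:
        if not (self.k_equil > 0 and self.t_half > 0 and self.t_equil > 0):
            raise ValueError("all kinetic quantities must be positive")
        if not math.isclose(self.t_half, LN2 / self.k_equil, rel_tol=1e-9):
            raise ValueError("t_half must equal ln2 / k_equil")
        if not math.isclose(self.t_equil, self.n_halflives * self.t_half,
                            rel_tol=1e-9):
            raise ValueError("t_equil must equal n_halflives * t_half")


# --------------------------------------------------------------------------
# equilibrium isotherms
# --------------------------------------------------------------------------

def _check_kd(kd) -> None:
    if np.any(np.asarray(kd) <= 0):
        raise ValueError("kd must be > 0")


def fraction_bound_free(p_free, kd):
    """Fraction of R bound at free variable-partner concentration ``p_free``.

    This is the exact Langmuir isotherm in the free concentration:
    ``p_free / (p_free + kd)``. It holds universally for 1:1 binding but
    requires knowing the *free* concentration.
    """
    _check_kd(kd)
    p_free = np.asarray(p_free, dtype=float)
    if np.any(p_free < 0):
        raise ValueError("p_free must be >= 0")
    return p_free / (p_free + kd)


def fraction_bound_hyperbolic(p_total, kd):
    """Binding-regime isotherm: ``p_total / (p_total + kd)``.

    Substitutes total for free concentration; valid only when the limiting
    partner is trace relative to K_D ([R]_total << kd), so that depletion of
    P by binding is negligible.
    """
    _check_kd(kd)
    p_total = np.asarray(p_total, dtype=float)
    if np.any(p_total < 0):
        raise ValueError("p_total must be >= 0")
    return p_total / (p_total + kd)


def fraction_bound_quadratic(p_total, r_total, kd):
    """Exact 1:1 mass-balance ("quadratic") fraction of R bound.

    Solves [PR] from the coupled conservation equations at totals
    ``p_total`` and ``r_total``. Evaluated in the cancellation-free root
    form ``2 p / (S + sqrt(S^2 - 4 r p))`` with ``S = r + p + kd``, which is
    numerically stable even deep in the titration regime where the textbook
    ``(S - sqrt(...)) / 2r`` form loses all precision.
    """
    _check_kd(kd)
    p = np.asarray(p_total, dtype=float)
    r = np.asarray(r_total, dtype=float)
    if np.any(p < 0):
        raise ValueError("p_total must be >= 0")
    if np.any(r <= 0):
        raise ValueError(
            "r_total must be > 0 (use fraction_bound_hyperbolic for trace R)")
    s = r + p + kd
    disc = s * s - 4.0 * r * p
    if np.any(disc < 0):  # impossible for valid concentrations
        raise ArithmeticError("negative discriminant in quadratic isotherm")
    return 2.0 * p / (s + np.sqrt(disc))


def solve_free_protein(p_total: float, r_total: float, kd: float,
                       c_total: float = 0.0,
                       kd_competitor: float | None = None) -> float:
    """Free variable-partner concentration from coupled 1:1 mass balance.

    Solves for P_free in

        p_total = P_free * (1 + r_total/(P_free + kd)
                              + c_total/(P_free + kd_competitor))

    i.e. total P partitioned between free form, the complex with the
    limiting species R (dissociation constant ``kd``) and the complex with
    an optional unlabeled competitor C (``kd_competitor``). The root is
    unique on [0, p_total]; it is bracketed and found with Brent's method.
    """
    if p_total < 0 or r_total < 0 or c_total < 0:
        raise ValueError("concentrations must be >= 0")
    _check_kd(kd)
    if c_total > 0:
        if kd_competitor is None or kd_competitor <= 0:
            raise ValueError("kd_competitor must be > 0 when c_total > 0")
    if p_total == 0:
        return 0.0

    def balance(pf: float) -> float:
        tot = pf + pf * r_total / (pf + kd)
        if c_total > 0:
            tot += pf * c_total / (pf + kd_competitor)
        return tot - p_total

    lo, hi = 0.0, p_total
    if balance(lo) > 0 or balance(hi) < -1e-9 * p_total:
        raise ArithmeticError("mass balance root not bracketed")  # pragma: no cover
    return brentq(balance, lo, hi, xtol=1e-30, rtol=4 * np.finfo(float).eps)


def half_saturation_point(r_total: float, kd: float) -> float:
    """Variable-partner total concentration K_1/2 giving half-maximal binding.

    Exactly ``kd + r_total/2`` for the 1:1 quadratic model: in the binding
    regime K_1/2 = K_D, while in the titration regime it degenerates to half
    the (active) limiting-species concentration and carries no affinity
    information.
    """
    _check_kd(kd)
    if r_total < 0:
        raise ValueError("r_total must be >= 0")
    return kd + r_total / 2.0


# --------------------------------------------------------------------------
# kinetics
# --------------------------------------------------------------------------

def equilibration_rate(kon: float, p: float, koff: float) -> float:
    """Rate constant for approach to equilibrium, ``kon * [P] + koff``.

    At [P] -> 0 this reduces to koff, the slowest (and therefore
    design-limiting) equilibration rate in a titration.
    """
    if kon < 0 or koff < 0 or p < 0:
        raise ValueError("kon, koff and p must be >= 0")
    k = kon * p + koff
    if k == 0:
        raise ValueError("kon*p + koff = 0: no approach to equilibrium")
    return k


def equilibration_time(kd: float, kon: float,
                       n_halflives: float = 5.0) -> KineticPrediction:
    """Time to equilibrate a trace-limiting titration, from kd and kon.

    Uses the limiting rate k_equil = koff = kd * kon (the [P] -> 0 limit)
    and returns t_equil = n_halflives * ln2 / koff. Five half-lives
    (~96.9% completion) is the conventional default.
    """
    if kd <= 0 or kon <= 0:
        raise ValueError("kd and kon must be > 0")
    if n_halflives <= 0:
        raise ValueError("n_halflives must be > 0")
    koff = kd * kon
    t_half = LN2 / koff
    return KineticPrediction(k_equil=koff, t_half=t_half,
                             t_equil=n_halflives * t_half,
                             n_halflives=n_halflives)


def fraction_bound_at_time(t, k_equil: float, equilibrium_fraction: float):
    """Single-exponential approach to equilibrium.

    ``equilibrium_fraction * (1 - exp(-t * k_equil))``; monotone in t and
    bounded above by the equilibrium amplitude.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if k_equil <= 0:
        raise ValueError("k_equil must be > 0")
    if not (0 <= equilibrium_fraction <= 1):
        raise ValueError("equilibrium_fraction must be in [0, 1]")
    return equilibrium_fraction * (-np.expm1(-t * k_equil))


def dissociation_remaining(koff: float, t) -> float:
    """Fraction of complex surviving first-order dissociation for time t."""
    if koff < 0:
        raise ValueError("koff must be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = np.exp(-koff * t)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# presentation helpers (Table-style rounding)
# --------------------------------------------------------------------------

def ceil_to_sigfigs(x: float, sigfigs: int = 1) -> float:
    """Round *up* to ``sigfigs`` significant figures (0.0347 -> 0.04, 962.5 -> 1000).

    The conservative convention for quoting equilibration times: an
    incubation is never presented shorter than the calculation demands.
    A tiny relative tolerance keeps exactly-representable values fixed.
    """
    if x == 0:
        return 0.0
    if x < 0:
        raise ValueError("x must be >= 0")
    exp = math.floor(math.log10(x)) - (sigfigs - 1)
    scale = 10.0 ** exp
    return math.ceil(x / scale - 1e-9) * scale


def round_to_sigfigs(x: float, sigfigs: int = 1) -> float:
    """Round to nearest at ``sigfigs`` significant figures (32.96 -> 30)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x))) - (sigfigs - 1)
    scale = 10.0 ** exp
    return round(x / scale) * scale


#: raw seconds at/above which equilibration times are quoted in hours
_HOUR_CUTOFF_S = 1800.0


def format_equilibration_time(t_seconds: float) -> tuple[float, str]:
    """Present a raw equilibration time the way design tables quote it.

    Times of half an hour or more are expressed in hours, shorter ones in
    seconds, then rounded *up* to one significant figure. Returns
    ``(value, unit)`` with unit ``"s"`` or ``"hr"``.
    """
    if t_seconds <= 0:
        raise ValueError("t_seconds must be > 0")
    if t_seconds >= _HOUR_CUTOFF_S:
        return ceil_to_sigfigs(t_seconds / 3600.0, 1), "hr"
    return ceil_to_sigfigs(t_seconds, 1), "s"


def equilibration_time_table(kds, kons, n_halflives: float = 5.0):
    """Grid of equilibration times over affinities and association rates.

    Returns a pandas DataFrame with one row per (kd, kon) combination,
    carrying the raw time in seconds plus the presentation value/unit from
    :func:`format_equilibration_time`.
    """
    import pandas as pd

    rows = []
    for kd in kds:
        for kon in kons:
            pred = equilibration_time(kd, kon, n_halflives=n_halflives)
            value, unit = format_equilibration_time(pred.t_equil)
            rows.append({
                "kd_M": kd,
                "kon_per_M_s": kon,
                "koff_per_s": pred.k_equil,
                "t_equil_s": pred.t_equil,
                "display_value": value,
                "display_unit": unit,
            })
    return pd.DataFrame(rows)
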