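"""Experiment containers: titration series, kinetic traces, competition series.

Concentrations are molar, times seconds. The limiting-species concentration
of a titration may be known only as a (low, high) pair — e.g. when a labeled
ligand concentration is bracketed by scintillation counting (lower limit)
and input mass (upper limit) — hence the bound-pair convention here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TitrationSeries", "KineticTrace", "CompetitionSeries"]

#: minimum observations for any nonlinear fit
MIN_FIT_POINTS = 4


def _as_array(x, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class TitrationSeries:
    """One equilibrium binding experiment.

    ``p_total``: variable-partner total concentrations (M), strictly > 0.
    ``fraction_bound``: observed bound fraction of the limiting partner
    (may stray slightly outside [0, 1] through measurement noise).
    ``r_total_low``/``r_total_high``: bounds on the limiting-partner
    concentration (equal when known exactly).
    """

    p_total: np.ndarray
    fraction_bound: np.ndarray
    r_total_low: float = 0.0
    r_total_high: float | None = None
    incubation_time: float | None = None
    temperature: float | None = None
    label: str = ""
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.p_total = _as_array(self.p_total, "p_total")
        self.fraction_bound = _as_array(self.fraction_bound, "fraction_bound")
        if len(self.p_total) != len(self.fraction_bound):
            raise ValueError("p_total and fraction_bound must be equal length")
        if np.any(self.p_total <= 0):
            raise ValueError("p_total values must be > 0")
        if self.r_total_high is None:
            self.r_total_high = self.r_total_low
        if self.r_total_low < 0 or self.r_total_high < self.r_total_low:
            raise ValueError("require 0 <= r_total_low <= r_total_high")

    def __len__(self) -> int:
        return len(self.p_total)

    @property
    def r_total(self) -> float:
        """Limiting-species concentration used by default in fits (lower bound)."""
        return self.r_total_low


@dataclass
class KineticTrace:
    """A time course of fraction bound at fixed concentrations."""

    t: np.ndarray
    fraction_bound: np.ndarray
    p_total: float
    mode: str = "association"
    chase_concentration: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.t = _as_array(self.t, "t")
        self.fraction_bound = _as_array(self.fraction_bound, "fraction_bound")
        if len(self.t) != len(self.fraction_bound):
            raise ValueError("t and fraction_bound must be equal length")
        if np.any(self.t < 0):
            raise ValueError("times must be >= 0")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("times must be sorted ascending")
        if self.mode not in ("association", "dissociation"):
            raise ValueError("mode must be 'association' or 'dissociation'")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class CompetitionSeries:
    """Labeled-species binding vs unlabeled competitor concentration.

    ``kd_labeled`` is fixed from a prior direct fit; the competitor K_D is
    the quantity estimated from this series.
    """

    c_total: np.ndarray
    fraction_bound: np.ndarray
    p_total: float
    kd_labeled: float
    r_total_labeled: float = 0.0
    incubation_time: float | None = None
    temperature: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.c_total = _as_array(self.c_total, "c_total")
        self.fraction_bound = _as_array(self.fraction_bound, "fraction_bound")
        if len(self.c_total) != len(self.fraction_bound):
            raise ValueError("c_total and fraction_bound must be equal length")
        if np.any(self.c_total < 0):
            raise ValueError("c_total values must be >= 0")
        if self.p_total <= 0 or self.kd_labeled <= 0:
            raise ValueError("p_total and kd_labeled must be > 0")

    def __len__(self) -> int:
        return len(self.c_total)
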