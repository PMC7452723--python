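"""Synthetic equilibrium and kinetic binding experiments.

The generator reproduces the standard in-silico benchmark for binding-curve
analysis: noiseless fractions bound from the exact 1:1 mass-balance isotherm
(or its binding-regime hyperbola when the limiting species is trace,
r_total <= 0.01 * kd), a two-fold serial protein dilution spanning two
decades either side of the expected half-saturation point, and additive,
homoscedastic, *unclipped* Gaussian noise on fraction bound — excursions
outside [0, 1] are left in place for the amplitude/offset terms of the fit
to absorb, exactly as a real normalized gel quantification would behave.

Ten replicates per condition and noise SDs of {0.01, 0.05, 0.1} are the
default study conditions. Randomness uses numpy's PCG64 ``default_rng``
seeded with the pair (seed, replicate_index), so every replicate has an
independent, platform-stable stream and identical seeds give byte-identical
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import KineticTrace, TitrationSeries
from .models import (
    BindingParameters,
    equilibration_rate,
    fraction_bound_at_time,
    fraction_bound_hyperbolic,
    fraction_bound_quadratic,
    dissociation_remaining,
    half_saturation_point,
)

__all__ = [
    "DEFAULT_NOISE_SDS",
    "SimulationDesign",
    "dilution_grid",
    "simulate_titration_series",
    "simulate_preequilibrium_series",
    "simulate_kinetic_trace",
]

#: default noise standard deviations on fraction bound
DEFAULT_NOISE_SDS = (0.01, 0.05, 0.1)

#: r_total/kd at or below which the hyperbolic (binding-regime) mean is used
TRACE_RATIO = 0.01


def dilution_grid(k_half: float, dilution_factor: float = 2.0,
                  span: float = 100.0) -> np.ndarray:
    """Serial-dilution concentration grid bracketing a half-saturation point.

    Ascending concentrations from ``k_half/span`` up to at least
    ``k_half*span`` in steps of ``dilution_factor`` (default two-fold, the
    representative design for equilibrium titrations). ``span=100`` gives a
    15-point grid covering four decades.
    """
    if k_half <= 0 or dilution_factor <= 1 or span <= 1:
        raise ValueError("require k_half > 0, dilution_factor > 1, span > 1")
    lo = k_half / span
    n = int(np.ceil(np.log(span * span) / np.log(dilution_factor))) + 1
    return lo * dilution_factor ** np.arange(n)


@dataclass
class SimulationDesign:
    """Design of one simulated titration condition.

    ``p_grid`` defaults to a two-fold dilution series spanning 100-fold
    below to 100-fold above the expected half-saturation point
    K_1/2 = kd + r_total/2.
    """

    params: BindingParameters
    r_total: float
    p_grid: np.ndarray | None = None
    dilution_factor: float = 2.0
    noise_sd: float = 0.05
    n_replicates: int = 10
    seed: int = 0
    incubation_time: float | None = None

    def __post_init__(self) -> None:
        if self.r_total < 0:
            raise ValueError("r_total must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.p_grid is None:
            k_half = half_saturation_point(self.r_total, self.params.kd)
            self.p_grid = dilution_grid(k_half, self.dilution_factor)
        else:
            self.p_grid = np.atleast_1d(np.asarray(self.p_grid, dtype=float))
            if len(self.p_grid) == 0:
                raise ValueError("p_grid must not be empty")
            if np.any(self.p_grid <= 0) or np.any(np.diff(self.p_grid) <= 0):
                raise ValueError("p_grid must be strictly positive and ascending")

    @property
    def in_trace_regime(self) -> bool:
        return self.r_total <= TRACE_RATIO * self.params.kd

    def mean_fraction_bound(self) -> np.ndarray:
        """Noiseless equilibrium fractions bound on the design grid."""
        if self.in_trace_regime:
            return fraction_bound_hyperbolic(self.p_grid, self.params.kd)
        return fraction_bound_quadratic(self.p_grid, self.r_total,
                                        self.params.kd)


def _rng(seed: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng((int(seed), int(replicate)))


def simulate_titration_series(design: SimulationDesign) -> list[TitrationSeries]:
    """Generate replicate equilibrium titration series for one condition.

    Means come from the exact quadratic isotherm (hyperbolic when the
    limiting species is trace); Gaussian noise of SD ``design.noise_sd`` is
    added per point and never clipped. Replicate ``i`` draws from the
    stream seeded with ``(design.seed, i)``.
    """
    mean = design.mean_fraction_bound()
    series = []
    for i in range(design.n_replicates):
        noise = 0.0
        if design.noise_sd > 0:
            noise = _rng(design.seed, i).normal(0.0, design.noise_sd,
                                                size=mean.shape)
        series.append(TitrationSeries(
            p_total=design.p_grid.copy(),
            fraction_bound=mean + noise,
            r_total_low=design.r_total,
            r_total_high=design.r_total,
            incubation_time=design.incubation_time,
            replicate_id=i,
            label=f"sim kd={design.params.kd:.3g}M r={design.r_total:.3g}M "
                  f"sd={design.noise_sd:g} rep={i}",
        ))
    return series


def simulate_preequilibrium_series(design: SimulationDesign,
                                   t: float) -> TitrationSeries:
    """Titration series observed after a finite incubation time ``t``.

    Each concentration approaches its equilibrium value (binding-regime
    amplitude, [P] taken as [P]_total) as a single exponential with rate
    kon*[P] + koff. Short incubations suppress the low-concentration limb
    — the low end equilibrates slowest — shifting the apparent K_1/2 upward
    and compressing real affinity differences between tight binders.
    """
    p = design.params
    if p.kon is None or p.koff is None:
        raise ValueError("params must include kon and koff")
    if t <= 0:
        raise ValueError("t must be > 0")
    grid = design.p_grid
    amp = fraction_bound_hyperbolic(grid, p.kd)
    frac = np.array([
        fraction_bound_at_time(t, equilibration_rate(p.kon, pc, p.koff), a)
        for pc, a in zip(grid, amp)
    ])
    if design.noise_sd > 0:
        frac = frac + _rng(design.seed, 0).normal(0.0, design.noise_sd,
                                                  size=frac.shape)
    return TitrationSeries(
        p_total=grid.copy(), fraction_bound=frac,
        r_total_low=design.r_total, r_total_high=design.r_total,
        incubation_time=t,
        label=f"pre-equilibrium t={t:g}s kd={p.kd:.3g}M",
    )


def simulate_kinetic_trace(params: BindingParameters, p: float,
                           t_grid, mode: str = "association",
                           noise_sd: float = 0.0, seed: int = 0,
                           initial_fraction: float | None = None,
                           ) -> KineticTrace:
    """Single-exponential association or dissociation (chase) time course.

    Association: amplitude p/(p + kd), rate kon*p + koff. Dissociation:
    first-order decay at koff from ``initial_fraction`` (defaults to the
    equilibrium fraction bound at ``p``).
    """
    if params.kon is None or params.koff is None:
        raise ValueError("params must include kon and koff")
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if np.any(t_grid < 0) or np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be sorted and nonnegative")
    if mode == "association":
        k = equilibration_rate(params.kon, p, params.koff)
        amp = fraction_bound_hyperbolic(p, params.kd)
        frac = fraction_bound_at_time(t_grid, k, float(amp))
    elif mode == "dissociation":
        f0 = (fraction_bound_hyperbolic(p, params.kd)
              if initial_fraction is None else initial_fraction)
        frac = float(f0) * dissociation_remaining(params.koff, t_grid)
    else:
        raise ValueError("mode must be 'association' or 'dissociation'")
    if noise_sd > 0:
        frac = frac + _rng(seed, 0).normal(0.0, noise_sd, size=frac.shape)
    return KineticTrace(t=t_grid, fraction_bound=frac, p_total=p, mode=mode)
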