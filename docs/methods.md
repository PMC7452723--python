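# Methods

## Model and scope

Everything in `equibind` assumes one-step, non-cooperative, 1:1 binding,

    P + R ⇌ P·R,    K_D = k_off / k_on,

with P the variable ("excess") partner and R the limiting partner whose
bound fraction is observed. Internal units are strict SI — molar, seconds,
s⁻¹, M⁻¹s⁻¹ — and every pM/nM/hour conversion happens at the I/O boundary.
Cooperative and multi-site models, Hill coefficients, temperature
extrapolation, and instrument-specific reductions (ITC heats, SPR
sensorgrams, mass-transport corrections) are deliberately out of scope.

## Equilibrium descriptions and regimes

Three interchangeable descriptions of the same equilibrium are exposed,
because which one is *valid* depends on the concentration regime:

* exact in the free concentration: f = [P]_free/([P]_free + K_D);
* **binding regime** ([R]ₜ ≪ K_D): [P]_free ≈ [P]_total, giving the
  hyperbola f = [P]ₜ/([P]ₜ + K_D);
* any regime short of titration: the exact mass-balance ("quadratic")
  solution in totals. It is evaluated as f = 2[P]ₜ/(S + √(S² − 4[R]ₜ[P]ₜ))
  with S = [R]ₜ+[P]ₜ+K_D. This is algebraically identical to the textbook
  (S − √…)/2[R]ₜ root but adds the two positive quantities instead of
  subtracting two nearly equal ones, so it keeps full precision deep into
  the titration regime where the textbook form loses all significant
  digits.

The half-saturation point of the quadratic curve is exactly
K_1/2 = K_D + [R]ₜ/2 (property-tested against a bisection mass-balance
oracle). In the titration regime ([R]ₜ ≫ K_D) the midpoint therefore
measures stoichiometry, not affinity — the canonical failure mode the
titration control exists to catch.

Regime boundaries (configurable, logged in every `RegimeAssessment`):
binding for [R]ₜ/K_D ≤ 0.15, intermediate to 10 (generic profile) or 1000
(high-precision profile, for techniques that resolve each titration
increment), titration above. The binding boundary is 0.15 rather than a
strict 0.10 because a ~0.15 excess ratio is still comfortably trace in
practice: at K_1/2 the depletion error is [R]ₜ/2 ≈ 7%, well inside typical
measurement uncertainty.

Competition is exact coupled mass balance, never an IC50 approximation:
free protein solves [P]ₜ = P_f·(1 + [R]ₜ/(P_f+K_D) + [C]ₜ/(P_f+K_C)) by
Brent root finding on [0, [P]ₜ] (xtol 1e-30 M, rtol 4·eps), and the
labeled signal is P_f/(P_f+K_D). The trace labeled species is dropped from
the balance when below 1% of the protein concentration (configurable).

## Kinetics

Approach to equilibrium is single-exponential with
k_equil = k_on[P] + k_off; the design-limiting rate is the [P] → 0 limit
k_equil = k_off. Equilibration times are quoted at five half-lives,
t_equil = 5·ln2/k_off — 1 − 2⁻⁵ = 96.875% completion (conventionally
rounded to "~97%"; one often-quoted figure of 96.6% is a slight
misprint of this exact value). Presentation of design tables uses
*ceiling* to one significant figure (0.0347 s → 0.04 s, 9.6 hr → 10 hr):
an advised incubation is never shorter than the calculation demands. Raw
seconds are always retained alongside; ordinary nearest-rounding helpers
are provided for summary statements (32.96 hr → 30 hr).

## The synthetic-data generator

`SimulationDesign` reproduces a typical equilibrium titration benchmark:

* concentration grid: two-fold serial dilution spanning 100-fold below to
  100-fold above the expected K_1/2 (15 points) unless a grid is given;
* means: the quadratic isotherm, or the hyperbola when
  [R]ₜ ≤ 0.01·K_D (at that ratio the two differ by < 0.5% everywhere);
* noise: additive, homoscedastic, *unclipped* Gaussian on fraction bound,
  default SDs {0.01, 0.05, 0.1}; excursions outside [0, 1] are kept, as a
  normalized gel quantification would produce, and the fits absorb them in
  amplitude/offset terms;
* replicates: ten per condition by default; replicate i draws from numpy
  PCG64 seeded with the pair (seed, i), so streams are independent,
  platform-stable and byte-reproducible;
* pre-equilibrium titrations: each concentration approaches its
  binding-regime amplitude as 1 − exp(−t·(k_on[P]+k_off)), which
  reproduces the signature artifacts of short incubations (right-shifted
  apparent K_1/2; compression of 100-fold affinity differences to
  near-identity when t ≪ 1/k_off of the tight binder).

What it does **not** emulate: heteroscedastic or correlated noise,
gel-loading losses, detection nonlinearity, pipetting error on the
concentration axis, partner inactivation over time. Passing recovery tests
therefore demonstrate the statistical behavior of the estimators under the
stated noise model, not robustness to every laboratory artifact.

## Fitting

All curve fits are trust-region nonlinear least squares
(`scipy.optimize.curve_fit`, trf) behind sklearn-style estimators. Default
isotherm models carry a free amplitude A and offset O (y = A·f(p) + O);
strict mode pins A = 1, O = 0 for theory-clean data. K_D is constrained
positive and initialized from the interpolated half-saturation point of
the data (minus [R]ₜ/2 for quadratic fits, floored at 10⁻⁴ of the data
midpoint). Because molar-scale parameters (~10⁻¹² M) and order-one
amplitudes differ by ten decades, every fit is performed in normalized
parameter space (each parameter divided by its initial magnitude);
without this, finite-difference trust-region steps stall several percent
from the optimum on noiseless data. Tolerances are ftol = xtol = gtol =
1e-12; noiseless round trips recover inputs to better than 10⁻⁶ relative.

Uncertainties are asymptotic: SEs from the Jacobian covariance at the
optimum, intervals at t(0.975, n−k). For the strictly positive key
parameter of each model (K_D, k_obs, competitor K_D) the 95% CI is
reported on the log scale by the delta method, K_D·exp(±t·SE/K_D). A
symmetric linear CI on a positive parameter crosses zero whenever the
relative SE exceeds ~0.5, which misclassifies moderately noisy but usable
fits; the log-scale interval cannot cross zero, and calibrates well (on
200 simulated binding-regime series the 95% CI covers the truth ≥ 90% of
the time — asymptotic intervals are approximate, so coverage rather than
exactness is the test). A seeded residual-resampling bootstrap
(`bootstrap_ci`) is available for small-n series.

**Identifiability rule**: a fit is `poorly-defined` iff the key
parameter's 95% CI spans more than a 100-fold ratio, or the estimate sits
within 1% of an imposed finite bound, or the fit failed to converge. This
operationalizes "no meaningful K_D can be extracted": under it, quadratic
fits of ten-replicate noisy data stay predominantly well-defined up to
10-fold limiting-species excess at all default noise levels, survive
100-fold excess only at the lowest noise, and are predominantly flagged at
1000-fold excess.

Other estimators: the k_obs-vs-[P] line is ordinary least squares by
default (slope = k_on, intercept = k_off, K_D = k_off/k_on with
first-order error propagation; inverse-variance weighting optional; a
negative intercept is reported as an upper limit on k_off; the slope is
divided by the active fraction when one is supplied). The breakpoint
titration searches contiguous two-segment splits exhaustively (≥ 3 points
per side), minimizing total SSE with ties broken toward the
ligand-equivalence point; segments within 2° of parallel yield no
breakpoint rather than a wild intersection. The quadratic-coefficient
alternative fits f_active and K_D jointly with [R]ₜ pinned to the known
ligand concentration; estimates above 1.05 are flagged rather than
silently truncated.

When the limiting-species concentration is known only as a (low, high)
pair, quadratic fits run at both bounds and report the K_D spread as
systematic uncertainty alongside the statistical CI.

## Invariance controls

`check_equilibration` (incubation times) and `check_titration`
(limiting-species levels) fit each condition and compare K_D estimates
with a CI-aware rule: **fail** requires both a point-estimate fold-change
beyond tolerance (default 1.5-fold) *and* disjoint 95% CIs for at least
one pair, so noise alone cannot fail a campaign. A change-free design is a
**pass** only when the tested span reaches the minimum (10-fold in time,
5-fold in [R]ₜ); otherwise it is `insufficient-design`. Precedence matters:
an observed, CI-supported K_D change is evidence against equilibrium
regardless of how narrow the span was, so `fail` is never downgraded by
the span rule — only would-be passes are.

## Checklist gating

The final K_D in a `ChecklistReport` is a pure function of the verdicts:
an unqualified constant only when both required controls pass; otherwise
an explicit upper limit (K_D ≤ value), since both insufficient
equilibration and titration inflate the apparent K_D. The apparent value
is multiplied by the active protein fraction when one was determined, and
the correction factor is recorded. Conflicting duplicate verdicts are a
validation error, not a silent overwrite. The K_D is labeled with its
conditions (temperature, buffer) because it is only a constant at a given
set of conditions.

## Problem sizes and determinism

The shipped tests and the acceptance script use desk-scale problems: ten
replicates per condition on 15-point grids for recovery studies (a
4 × 3 condition grid runs in about a second), 200 series for CI
calibration, and single noiseless series for round trips. All randomness
flows through explicit integer seeds; identical seeds give byte-identical
data on any platform.

## Known limitations

* Asymptotic CIs undercover for very small n or near-singular designs;
  use the bootstrap there.
* The breakpoint construction assumes the ligand is 100% active and the
  complex stoichiometry is known; violations bias the active fraction.
* The equilibration check interprets invariance as equilibrium; a
  reaction stalled by, e.g., protein inactivation can mimic invariance.
  The controls bound what can be concluded, they do not prove mechanism.
* Apparent K_D values from fits of depleted (quadratic-regime) data with
  the hyperbola land near K_D + [R]ₜ/2 but 5–20% below it, because the
  least-squares compromise over a wide grid is not exactly the curve
  midpoint; only the midpoint itself obeys the law exactly.
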