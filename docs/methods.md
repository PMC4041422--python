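# Methods

## Binding model

All kinetics derive from the one-step reversible bimolecular mechanism

    R + P  ⇌  RP,        d[RP]/dt = k_on [R][P] − k_off [RP],

with concentrations in µM, time in s, k_on in µM⁻¹ s⁻¹ and k_off in s⁻¹.
K_d = k_off/k_on is reported in nM (the natural scale for these complexes);
the µM→nM conversion is isolated in `compute_Kd` and the
`RateParameters.K_d` property so no other code carries unit factors.
Under pseudo-first-order conditions (the titrated species in excess over
the observed one) the observable relaxes mono-exponentially with

    k_obs = k_on [titrant] + k_off,

so a titration gives k_on and k_off as slope and intercept.  Two further
closed forms are used: the equilibrium complex concentration from the
mass-balance quadratic (evaluated as 2RP/(b + √(b² − 4RP)) to avoid
cancellation), and the relaxation rate of small perturbations about
equilibrium, 1/τ = k_on([R]ᶠʳᵉᵉ + [P]ᶠʳᵉᵉ) + k_off.  The mean complex
lifetime uses the same form with post-mixing *total* concentrations,
τ = 1/(k_on([R]+[P]) + k_off), matching how such lifetimes are
conventionally quoted for these experiments.

The mass-action ODE (`simulate_binding_ode`) integrates the complex
concentrations for one or two proteins with LSODA at rtol 1e-9 /
atol 1e-12 — stiff-capable because observed rates span ~5–430 s⁻¹ while
traces span milliseconds to seconds.  Tiny negative excursions
(< 1e-9 µM) are clipped; anything larger raises.  An optional
`active_fraction` multiplier (default 1.0) models preparations in which
only part of the nominal protein is binding-competent.

## Two-protein competition

The equilibrium partition of one RNA between two proteins solves
g(r) = r + Σᵢ Pᵢ·r/(K_dᵢ + r) − R_tot = 0 for free RNA r by bounded
Brent root-finding on [0, R_tot]; g is strictly increasing, so the root is
unique and the solver cannot mis-select a branch (the reason this form was
chosen over the cubic's closed form).  The kinetic partition is the
instantaneous-flux approximation: the fraction of free RNA captured first
by protein i is k_on,ᵢPᵢ / Σⱼ k_on,ⱼPⱼ, ignoring rebinding.  Both views
are exposed deliberately: with rising Mn²⁺ the rate constants of the
repressor (IRP1) and the activator (eIF4F) move in opposite directions
more steeply than the equilibrium constants, so which protein "wins" can
be decided kinetically; the full time-resolved answer is always available
from the ODE.

## Synthetic traces

The generator emulates the acquisition characteristics of a stopped-flow
fluorimeter: 1 ms dead time (no points recorded earlier), 1000 points per
shot on a uniform grid, 5–7 shots averaged per trace, per-point i.i.d.
Gaussian noise.  Signal maps:

* anisotropy (labeled RNA): r(t) = r_free + span·[RP](t)/R_tot, defaults
  r_free = 0.05, span = 0.15, σ = 0.002;
* fluorescence (protein): F(t) = F₀(1 − q·[RP](t)/P_tot), defaults
  F₀ = 1.0, q = 0.3, σ = 0.005.

These signal constants are synthetic inventions — chosen once so that
amplitude/σ ≈ 50, i.e. visibly clean single-exponential traces of the kind
that motivate single-exponential analysis in the first place.  The default
time window is max(10/k_obs, 50 ms).

Two kinetic trace models exist, and the distinction matters:

* `kinetics="observed"` (default): the complex course is an exact
  exponential at the pseudo-first-order rate k_on[titrant]+k_off, running
  from the initial complex concentration to the exact mass-action
  equilibrium.  This is the phenomenology measured traces of this system
  follow across the whole time course (flat residuals under a
  single-exponential fit), and it is the model the standard k_obs
  regression analysis presumes.  The titrant is the species not carrying
  the signal: the protein for anisotropy designs, the RNA for
  fluorescence designs.
* `kinetics="mass_action"`: the full ODE solution.  Its relaxation is not
  exactly exponential, and the single-exponential rate fitted to it
  deviates from the linear law by roughly R_tot/P_tot (≈5 % at 20-fold
  protein excess, >7 % at equimolar mixing).  Feeding such traces through
  the regression pipeline biases K_d low by tens of percent — a real and
  documented property of analysing low-excess titration points with
  pseudo-first-order formulas, reproduced here on purpose rather than
  silently mixed into the default generator.

Dilution traces pre-equilibrate the concentrated mix, divide all
concentrations by the dilution factor, optionally switch rate constants to
the post-dilution condition (e.g. metal-containing buffer), and decay at
the linearized relaxation rate (observed mode) or by the ODE.  Because the
rebinding correction applied in analysis, k_off = k_obs/(1 + [P]_tot/K_d),
uses the *total* protein concentration while the true relaxation involves
the *free* concentrations, the recovered k_off carries a small systematic
bias (≈5 % under the standard design).  This mirrors the practical
observation that intercept-based and dilution-based k_off estimates of the
same complex differ by more than their nominal errors; the package reports
both routes and resolves nothing.

Seeding: a master seed is mapped to per-shot, per-condition child seeds by
fixed integer arithmetic (modulo 2³¹−1), so multi-shot averaging and whole
titration series are reproducible shot by shot; `seed=None` gives fresh
noise.  Noise is homoscedastic Gaussian; real anisotropy-ratio noise is
heteroscedastic, which is out of scope and listed under limitations.

## Fitting and model selection

Traces are fitted by unweighted nonlinear least squares (lmfit
Levenberg–Marquardt, xtol/ftol 1e-12, ≤2000 function evaluations) to
Δr·e^(−k_obs t) + r_f or the two-component sum.  Initialisation is
deterministic and data-driven: offset from the tail mean (last 10 % of
points), amplitude from first point minus tail, rate from a log-linear
regression of |signal − tail| over the first half of the decay; the double
fit starts at k/3 and 3k with the amplitude split evenly.  Rates are
bounded below by zero; double-fit components are reported sorted by rate.
Flat traces are flagged (`amplitude_near_zero`, `rate_unidentifiable`)
rather than failed, and non-convergence is always flagged.

Single vs double is decided by the extra-sum-of-squares F-test at
α = 0.05, with ties and numerically perfect single fits resolved toward
the single model (parsimony).  Because a 5 % test run over many traces
occasionally prefers a spurious second component, the pipeline takes the
*dominant* rate of whichever model wins: components are ranked by the
signal change they actually produce inside the observation window,
|Δr|·(1 − e^(−k·T)), which discards degenerate near-zero-rate components
that merely imitate baseline drift.

Residual diagnostics report the residual SD, lag-1 autocorrelation and a
Wald–Wolfowitz runs test (implemented directly; a ten-line normal
approximation) — structured residuals from a mis-specified model show up
as |ρ₁| near 1 and a collapsed runs count.

## Secondary analysis

The k_obs regression is ordinary (unweighted) least squares via
statsmodels; with equal replication at every concentration there is
nothing to weight by.  A non-positive slope is an error (no association to
quantify); a negative intercept is reported as-is with a warning — never
clamped — because clamping would bias the K_d column.  Two points define
an exact line but carry no standard errors (flagged).  Condition tables
assemble k_on, k_off, K_d and condition/control ratio columns over Mn²⁺
(the same machinery serves a KCl axis).  Displayed values follow the
conventional rounding (K_d to 3 significant figures, folds to one
decimal); JSON output keeps full precision.

## Problem sizes

The reference analyses run in the noiseless limit at the designed sizes:
four protein concentrations (0.05/0.2/0.5/1.0 µM against 0.05 µM RNA) per
anisotropy series, three RNA concentrations (0.1/0.2/0.5 µM against
0.1 µM protein) per fluorescence series, four Mn²⁺ levels per condition
table, 1000 points per trace.  Stochastic recovery checks use 50
independent seeds of the four-trace titration at default noise; the
ODE-vs-closed-form equilibrium cross-check uses 100 random two-protein
systems.

## Known limitations

* The observed-mode generator asserts, rather than derives, single-
  exponential relaxation at the Eq-style rate; parameter recovery from it
  demonstrates the correctness of the analysis chain, not the adequacy of
  the pseudo-first-order approximation for low-excess titration points
  (the mass-action mode exists precisely to probe that gap).
* Noise is homoscedastic and Gaussian; no photobleaching, lamp drift or
  instrument response beyond the hard dead-time cutoff.
* No conformational (two-step, induced-fit) binding models; the package is
  scoped to the one-step mechanism the concentration-linearity of k_obs
  supports.
* Standard errors are first-order (local linearization); no error
  propagation beyond that, and no cross-condition hypothesis testing.
* Global simultaneous fitting of multiple traces is not implemented; each
  averaged trace is fitted on its own.
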