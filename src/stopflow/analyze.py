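"""From observed rates to rate constants, K_d tables and competition summaries.

This layer turns per-trace observed rates into the quantities reported for
a binding study: k_on and k_off from the linear concentration dependence
k_obs = k_on [P] + k_off (ordinary least squares; slope and intercept),
K_d = k_off/k_on, dissociation rates from dilution relaxations corrected
for rebinding, condition tables over Mn2+ (or KCl) with fold-change
columns against a control, complex lifetimes, and the repressor/activator
competition summary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .fit import fit_double_exponential, fit_single_exponential, select_model
from .models import (
    RateParameters,
    complex_lifetime,
    equilibrium_partition,
    kinetic_partition,
)
from .presets import DesignPreset, get_preset
from .simulate import KineticTrace, generate_titration_series

__all__ = [
    "LinearFit",
    "TitrationResult",
    "LifetimeComparison",
    "TitrationReport",
    "fit_kobs_vs_concentration",
    "analyze_dilution",
    "build_condition_table",
    "fold_change",
    "fold_decrease",
    "compare_complex_lifetimes",
    "run_titration_analysis",
]


@dataclass(frozen=True)
class LinearFit:
    """Straight-line fit of k_obs against concentration."""

    slope: float  # uM^-1 s^-1
    intercept: float  # s^-1
    slope_se: float | None
    intercept_se: float | None
    r_squared: float
    n: int
    flags: tuple[str, ...] = ()


def fit_kobs_vs_concentration(points: Sequence[tuple], label: str = "",
                              ) -> RateParameters:
    """k_on (slope) and k_off (intercept) from a k_obs titration.

    ``points`` is a sequence of (concentration uM, k_obs s^-1) or
    (concentration, k_obs, se) tuples.  The regression is ordinary
    (unweighted) least squares, matching the equal-replicate averaging of
    the standard analysis.  A negative fitted intercept is reported with a
    warning, not clamped; a non-positive slope is an error (no
    association).  Two points define an exact line but carry no standard
    errors (flagged).
    """
    pts = [(float(p[0]), float(p[1])) for p in points]
    concs = np.array([p[0] for p in pts])
    kobs = np.array([p[1] for p in pts])
    if len(np.unique(concs)) < 2:
        raise ValueError("at least 2 distinct concentrations are required")

    flags: list[str] = []
    X = sm.add_constant(concs)
    fit = sm.OLS(kobs, X).fit()
    intercept, slope = (float(v) for v in fit.params)
    if len(pts) <= 2:
        int_se = slope_se = None
        flags.append("se_undefined")
        r2 = 1.0
    else:
        int_se, slope_se = (float(v) for v in fit.bse)
        r2 = float(fit.rsquared)

    if slope <= 0:
        raise ValueError(f"non-positive slope ({slope:.3g}); no association detected")
    if intercept < 0:
        warnings.warn(f"negative fitted intercept ({intercept:.3g} s^-1); "
                      "k_off is poorly determined", stacklevel=2)
        flags.append("negative_intercept")

    linear = LinearFit(slope, intercept, slope_se, int_se, r2, len(pts), tuple(flags))
    rp = RateParameters(slope, intercept, slope_se, int_se, label)
    object.__setattr__(rp, "_linear_fit", linear)  # diagnostic rider
    return rp


def linear_fit_of(rate: RateParameters) -> LinearFit | None:
    """Regression diagnostics attached by :func:`fit_kobs_vs_concentration`."""
    return getattr(rate, "_linear_fit", None)


def analyze_dilution(k_obs_fitted: float, protein_conc_uM: float,
                     K_d_prior_nM: float | None) -> float:
    """k_off from a dilution relaxation rate, corrected for rebinding.

    Inverts k_obs = k_off ([P]/K_d + 1): the relaxation of a diluted
    complex is faster than pure dissociation because free protein rebinds
    the RNA; with an independently known K_d the rebinding term can be
    divided out.  ``K_d_prior_nM=None`` (or inf) means no rebinding
    correction, i.e. k_off = k_obs.
    """
    if k_obs_fitted <= 0 or protein_conc_uM < 0:
        raise ValueError("k_obs must be positive and concentration non-negative")
    if K_d_prior_nM is None or math.isinf(K_d_prior_nM):
        return k_obs_fitted
    if K_d_prior_nM <= 0:
        raise ValueError("K_d prior must be positive")
    return k_obs_fitted / (1.0 + protein_conc_uM * 1000.0 / K_d_prior_nM)


@dataclass(frozen=True)
class TitrationResult:
    """Condition table: one row per condition, rate constants and ratios.

    The machine-readable form of a metal-ion (or salt) dependence table:
    columns k_on, k_off, K_d_nM plus ``*_ratio`` columns of each condition
    against the control row.
    """

    axis: str  # e.g. "mn_uM", "kcl_mM", "protein_uM"
    table: pd.DataFrame
    control: float

    def row(self, condition: float) -> pd.Series:
        return self.table.loc[condition]


def build_condition_table(results: dict[float, RateParameters], control: float,
                          axis: str = "mn_uM") -> TitrationResult:
    """Assemble per-condition rates into a table with condition/control ratios."""
    if control not in results:
        raise ValueError(f"control condition {control} missing from results")
    conds = sorted(results)
    ctrl = results[control]
    rows = []
    for c in conds:
        r = results[c]
        rows.append({
            axis: c,
            "k_on": r.k_on, "k_on_se": r.k_on_se,
            "k_off": r.k_off, "k_off_se": r.k_off_se,
            "K_d_nM": r.K_d,
            "k_on_ratio": fold_change(r.k_on, ctrl.k_on),
            "k_off_ratio": fold_change(r.k_off, ctrl.k_off),
            "K_d_ratio": fold_change(r.K_d, ctrl.K_d),
        })
    table = pd.DataFrame(rows).set_index(axis)
    return TitrationResult(axis, table, control)


def fold_change(value_condition: float, value_control: float) -> float:
    """Plain ratio condition/control."""
    if value_control == 0:
        raise ValueError("control value is zero; fold change undefined")
    return value_condition / value_control


def fold_decrease(value_condition: float, value_control: float) -> float:
    """Fold decrease formatted the conventional way: control/condition."""
    if value_condition == 0:
        raise ValueError("condition value is zero; fold decrease undefined")
    return value_control / value_condition


@dataclass(frozen=True)
class LifetimeComparison:
    tau1_s: float
    tau2_s: float

    @property
    def ratio(self) -> float:
        return self.tau1_s / self.tau2_s


def compare_complex_lifetimes(rate1: RateParameters, rate2: RateParameters,
                              conc1: tuple[float, float],
                              conc2: tuple[float, float]) -> LifetimeComparison:
    """Lifetimes of two complexes at their respective (RNA, protein) uM pairs."""
    tau1 = complex_lifetime(rate1, *conc1)
    tau2 = complex_lifetime(rate2, *conc2)
    return LifetimeComparison(tau1, tau2)


# ------------------------------------------------------- end-to-end pipeline

@dataclass(frozen=True)
class ConditionAnalysis:
    """One condition's trace-level results within a titration."""

    concentrations_uM: tuple[float, ...]
    k_obs: tuple[float, ...]
    k_obs_se: tuple[float | None, ...]
    model_choices: tuple[str, ...]
    rates: RateParameters


@dataclass(frozen=True)
class TitrationReport:
    """Full result of a titration analysis run."""

    preset: str
    seed: int | None
    noise_sd: float | None
    alpha: float
    conditions: dict[float, ConditionAnalysis]
    table: TitrationResult | None

    def rates_at(self, condition: float) -> RateParameters:
        return self.conditions[condition].rates

    def to_json_dict(self) -> dict:
        out = {
            "preset": self.preset, "seed": self.seed,
            "noise_sd": self.noise_sd, "alpha": self.alpha,
            "conditions": {},
        }
        for cond, ca in self.conditions.items():
            r = ca.rates
            out["conditions"][str(cond)] = {
                "concentrations_uM": list(ca.concentrations_uM),
                "k_obs": list(ca.k_obs),
                "model_choices": list(ca.model_choices),
                "k_on": r.k_on, "k_on_se": r.k_on_se,
                "k_off": r.k_off, "k_off_se": r.k_off_se,
                "K_d_nM": r.K_d,
            }
        if self.table is not None:
            out["condition_table"] = self.table.table.reset_index().to_dict("records")
        return out


def _titrant_of(trace: KineticTrace) -> float:
    return (trace.condition.protein_uM if trace.signal_kind == "anisotropy"
            else trace.condition.rna_uM)


def analyze_traces(traces: Sequence[KineticTrace], alpha: float = 0.05,
                   label: str = "") -> ConditionAnalysis:
    """Fit every trace of one condition and regress k_obs on concentration."""
    if not traces:
        raise ValueError("no traces supplied")
    concs, kobs, ses, choices = [], [], [], []
    for tr in traces:
        f1 = fit_single_exponential(tr)
        f2 = fit_double_exponential(tr)
        sel = select_model(f1, f2, alpha)
        chosen = f1 if sel.choice == "single" else f2
        idx = chosen.dominant_index
        concs.append(_titrant_of(tr))
        kobs.append(chosen.rates[idx])
        ses.append(chosen.rate_ses[idx])
        choices.append(sel.choice)
    rates = fit_kobs_vs_concentration(list(zip(concs, kobs)), label=label)
    return ConditionAnalysis(tuple(concs), tuple(kobs), tuple(ses),
                             tuple(choices), rates)


def run_titration_analysis(preset: DesignPreset | str, seed: int | None = None,
                           noise_sd: float | None = None, alpha: float = 0.05,
                           n_shots: int | None = None,
                           kinetics: str = "observed") -> TitrationReport:
    """Generate a preset's traces and run them through the whole pipeline.

    traces -> exponential fits -> single/double model selection -> k_obs
    regression per condition -> condition table (when the preset spans
    several Mn2+ levels).  Deterministic given the seed.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    traces = generate_titration_series(preset, seed=seed, noise_sd=noise_sd,
                                       n_shots=n_shots, kinetics=kinetics)
    by_mn: dict[float, list[KineticTrace]] = {}
    for tr in traces:
        by_mn.setdefault(tr.condition.mn_uM, []).append(tr)

    conditions: dict[float, ConditionAnalysis] = {}
    for mn, group in sorted(by_mn.items()):
        label = f"{preset.rna_id}/{preset.protein_id} @ {mn:g} uM Mn2+"
        conditions[mn] = analyze_traces(group, alpha=alpha, label=label)

    table = None
    if len(conditions) > 1:
        table = build_condition_table({m: c.rates for m, c in conditions.items()},
                                      control=min(conditions), axis="mn_uM")
    return TitrationReport(preset.name, seed, noise_sd, alpha, conditions, table)


def competition_summary(rna_uM: float, irp1_uM: float, eif4f_uM: float,
                        mn_levels_uM: Sequence[float] = (0.0, 5.0, 25.0, 50.0),
                        interpolate: bool = False) -> pd.DataFrame:
    """Equilibrium and kinetic partition of an IRE-RNA between IRP1 and eIF4F.

    For each Mn2+ level the tabulated FRT rate constants of the two
    proteins are looked up and the RNA partition computed both ways: the
    coupled two-ligand equilibrium (thermodynamic control) and the
    instantaneous association-flux split (kinetic control).  Rising Mn2+
    slows/loosens IRP1 and speeds/tightens eIF4F, so both columns cross
    from repressor-dominated to activator-dominated.
    """
    from .presets import rate_lookup

    rows = []
    for mn in mn_levels_uM:
        r_irp = rate_lookup(("FRT", "IRP1"), mn, interpolate=interpolate)
        r_eif = rate_lookup(("FRT", "eIF4F"), mn, interpolate=interpolate)
        eq = equilibrium_partition(rna_uM, irp1_uM, eif4f_uM, r_irp.K_d, r_eif.K_d)
        kin = kinetic_partition(irp1_uM, eif4f_uM, r_irp, r_eif)
        rows.append({
            "mn_uM": mn,
            "Kd_IRP1_nM": r_irp.K_d, "Kd_eIF4F_nM": r_eif.K_d,
            "kon_IRP1": r_irp.k_on, "kon_eIF4F": r_eif.k_on,
            "eq_bound_IRP1": eq.fraction_bound[0],
            "eq_bound_eIF4F": eq.fraction_bound[1],
            "eq_free": eq.fraction_free,
            "kinetic_capture_IRP1": kin[0],
            "kinetic_capture_eIF4F": kin[1],
        })
    return pd.DataFrame(rows).set_index("mn_uM")
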