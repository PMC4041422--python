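"""Synthetic stopped-flow traces: instrument model and experiment generators.

Emulates a stopped-flow instrument with a 1-ms dead time recording 1000
points per shot, 5-7 shots averaged per trace.  Two observables are
supported:

* **anisotropy** of a fluorescein-labeled RNA, which rises as the RNA is
  bound by a large protein:  r(t) = r_free + span * [RP](t) / R_total;
* **fluorescence** of the protein (intrinsic tryptophan signal), quenched
  by RNA binding:  F(t) = F0 * (1 - q * [RP](t) / P_total).

Two kinetic trace models are available:

* ``kinetics="observed"`` (default) — the relaxation observed on the
  instrument: a single exponential at the pseudo-first-order rate
  k_obs = k_on [titrant] + k_off (the concentration of the unlabeled,
  titrated species), running from the initial complex concentration to the
  exact mass-action equilibrium.  This is the phenomenology the standard
  analysis (exponential fit, then k_obs vs concentration regression)
  assumes, and measured traces of this system follow it across the whole
  time course.
* ``kinetics="mass_action"`` — the full mass-action ODE solution.  At low
  titrant excess its relaxation is visibly non-exponential and its
  effective rate deviates from the linear law by roughly R_total/P_total;
  it is the right model for mechanism studies and for checking the
  pseudo-first-order approximation itself.

Noise is i.i.d. Gaussian per point (homoscedastic), with a master-seed ->
per-shot child-seed scheme so that multi-shot averaging is reproducible
shot by shot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .models import (
    BindingSystem,
    Protein,
    RateParameters,
    equilibrium_complex,
    kobs_linear,
    linearized_relaxation_rate,
    simulate_binding_ode,
)
from .presets import DesignPreset, get_preset, rate_lookup

__all__ = [
    "Condition",
    "KineticTrace",
    "SignalModel",
    "ANISOTROPY_DEFAULT",
    "FLUORESCENCE_DEFAULT",
    "generate_trace",
    "average_shots",
    "generate_titration_series",
    "generate_dilution_trace",
]

#: default signal constants (synthetic; chosen so amplitude/sigma ~ 50,
#: i.e. visibly clean single-exponential traces)
ANISOTROPY_DEFAULT_BASELINE = 0.05
ANISOTROPY_DEFAULT_SPAN = 0.15
ANISOTROPY_DEFAULT_NOISE = 0.002
FLUORESCENCE_DEFAULT_F0 = 1.0
FLUORESCENCE_DEFAULT_QUENCH = 0.3
FLUORESCENCE_DEFAULT_NOISE = 0.005


@dataclass(frozen=True)
class Condition:
    """Solution condition and species identity attached to one trace."""

    rna_id: str = ""
    protein_id: str = ""
    rna_uM: float = 0.0
    protein_uM: float = 0.0
    mn_uM: float = 0.0
    kcl_mM: float = 100.0
    temperature_C: float = 25.0


@dataclass(frozen=True)
class KineticTrace:
    """One stopped-flow time course.

    ``times`` start at the instrument dead time (nothing is recorded while
    the cell is filling) and increase strictly; ``signal`` is anisotropy
    (dimensionless) or fluorescence (arbitrary units).
    """

    times: np.ndarray
    signal: np.ndarray
    signal_kind: str
    condition: Condition = field(default_factory=Condition)
    n_shots_averaged: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        s = np.asarray(self.signal, float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", s)
        if t.size < 2:
            raise ValueError("a trace needs at least 2 points")
        if t.size != s.size:
            raise ValueError("times and signal must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t[0] < 0:
            raise ValueError("times must be non-negative")
        if self.signal_kind not in ("anisotropy", "fluorescence"):
            raise ValueError(f"unknown signal kind {self.signal_kind!r}")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class SignalModel:
    """Map from complex concentration to the recorded observable.

    For anisotropy, ``baseline`` is r_free and ``span`` is r_bound - r_free
    (signal rises with binding).  For fluorescence, ``baseline`` is F0 and
    ``span`` is the quench fraction q in [0, 1] (signal falls with
    binding).  ``noise_sd`` is the per-point Gaussian sigma in signal
    units.
    """

    kind: str
    baseline: float
    span: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.kind not in ("anisotropy", "fluorescence"):
            raise ValueError(f"unknown signal kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.kind == "fluorescence" and not (0 <= self.span <= 1):
            raise ValueError("fluorescence quench fraction must be in [0, 1]")

    def map(self, complex_uM, rna_total_uM: float, protein_total_uM: float):
        c = np.asarray(complex_uM, float)
        if self.kind == "anisotropy":
            if rna_total_uM <= 0:
                raise ValueError("anisotropy signal requires labeled RNA present")
            return self.baseline + self.span * c / rna_total_uM
        if protein_total_uM <= 0:
            raise ValueError("fluorescence signal requires protein present")
        return self.baseline * (1.0 - self.span * c / protein_total_uM)


ANISOTROPY_DEFAULT = SignalModel("anisotropy", ANISOTROPY_DEFAULT_BASELINE,
                                 ANISOTROPY_DEFAULT_SPAN, ANISOTROPY_DEFAULT_NOISE)
FLUORESCENCE_DEFAULT = SignalModel("fluorescence", FLUORESCENCE_DEFAULT_F0,
                                   FLUORESCENCE_DEFAULT_QUENCH, FLUORESCENCE_DEFAULT_NOISE)


def default_signal_model(kind: str, noise_sd: float | None = None) -> SignalModel:
    base = ANISOTROPY_DEFAULT if kind == "anisotropy" else FLUORESCENCE_DEFAULT
    return base if noise_sd is None else replace(base, noise_sd=noise_sd)


def _child_seed(master: int | None, index: int) -> int | None:
    # fixed arithmetic so every shot of every condition is reproducible
    if master is None:
        return None
    return (int(master) * 100003 + index * 101) % (2**31 - 1)


def _observed_complex_course(system: BindingSystem, signal_kind: str,
                             times: np.ndarray) -> np.ndarray:
    """Closed-form relaxation of [RP](t) at the observed (Eq.-style) rate.

    The titrant whose concentration enters k_obs is the species that does
    not carry the signal: the protein for anisotropy traces (labeled RNA
    fixed), the RNA for fluorescence traces (protein fluorescence watched).
    The end point is the exact mass-action equilibrium, so amplitudes are
    always thermodynamically consistent.
    """
    if len(system.proteins) != 1:
        raise ValueError("observed-kinetics traces are defined for one protein")
    p = system.proteins[0]
    titrant = p.active_uM if signal_kind == "anisotropy" else system.rna_total_uM
    k_obs = kobs_linear(p.rates, titrant)
    c0 = p.initial_complex_uM
    c_eq = equilibrium_complex(system.rna_total_uM, p.active_uM, p.rates.K_d)
    return c_eq + (c0 - c_eq) * np.exp(-k_obs * times)


def expected_kobs(system: BindingSystem, signal_kind: str) -> float:
    """Observed rate the default trace model relaxes at (s^-1)."""
    p = system.proteins[0]
    titrant = p.active_uM if signal_kind == "anisotropy" else system.rna_total_uM
    return kobs_linear(p.rates, titrant)


def generate_trace(system: BindingSystem, signal_model: SignalModel,
                   n_points: int = 1000, t_end: float | None = None,
                   dead_time: float = 1e-3, seed: int | None = None,
                   n_shots: int = 1, kinetics: str = "observed",
                   condition: Condition | None = None) -> KineticTrace:
    """Generate one (multi-shot averaged) stopped-flow trace.

    The time grid is uniform on [dead_time, t_end]; by default
    ``t_end = max(10 / k_obs_expected, 0.05)`` s so the trace spans ten
    relaxation times but never less than 50 ms.  With ``n_shots > 1``,
    independent noisy shots are generated from per-shot child seeds and
    averaged, as an instrument operator would.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    if kinetics not in ("observed", "mass_action"):
        raise ValueError(f"unknown kinetics model {kinetics!r}")
    if signal_model.kind == "fluorescence" and len(system.proteins) != 1:
        raise ValueError("fluorescence traces require exactly one protein")
    k_exp = expected_kobs(system, signal_model.kind)
    if t_end is None:
        t_end = max(10.0 / k_exp if k_exp > 0 else 0.05, 0.05)
    if t_end <= dead_time:
        raise ValueError("t_end must exceed the dead time")
    times = np.linspace(dead_time, t_end, n_points)

    if kinetics == "observed":
        course = _observed_complex_course(system, signal_model.kind, times)
    else:
        course = simulate_binding_ode(system, times).complex_total()
    p_total = system.proteins[0].total_uM
    clean = signal_model.map(course, system.rna_total_uM, p_total)

    if signal_model.noise_sd > 0:
        shots = np.empty((n_shots, n_points))
        for i in range(n_shots):
            rng = np.random.default_rng(_child_seed(seed, i))
            shots[i] = clean + rng.normal(0.0, signal_model.noise_sd, n_points)
        signal = shots.mean(axis=0)
    else:
        signal = clean

    if condition is None:
        p = system.proteins[0]
        condition = Condition(protein_id=p.name, rna_uM=system.rna_total_uM,
                              protein_uM=p.total_uM)
    return KineticTrace(times, signal, signal_model.kind, condition,
                        n_shots_averaged=n_shots, seed=seed)


def average_shots(traces: list[KineticTrace]) -> KineticTrace:
    """Pointwise mean of repeated shots recorded on an identical grid."""
    if not traces:
        raise ValueError("no traces to average")
    first = traces[0]
    for t in traces[1:]:
        if len(t) != len(first) or not np.allclose(t.times, first.times, rtol=0, atol=1e-12):
            raise ValueError("shots must share an identical time grid")
        if t.signal_kind != first.signal_kind or t.condition != first.condition:
            raise ValueError("shots must share signal kind and condition")
    if all(np.array_equal(t.signal, first.signal) for t in traces[1:]):
        signal = first.signal.copy()  # identical shots average to themselves exactly
    else:
        signal = np.mean([t.signal for t in traces], axis=0)
    return KineticTrace(first.times, signal, first.signal_kind, first.condition,
                        n_shots_averaged=sum(t.n_shots_averaged for t in traces),
                        seed=first.seed)


def generate_titration_series(preset: DesignPreset | str, seed: int | None = None,
                              noise_sd: float | None = None,
                              n_shots: int | None = None,
                              kinetics: str = "observed",
                              mn_levels_uM: tuple[float, ...] | None = None,
                              ) -> list[KineticTrace]:
    """All traces of a titration design: one averaged trace per (Mn2+, conc).

    Rate constants come from :func:`stopflow.presets.rate_lookup` for the
    preset's RNA/protein pair at each Mn2+ level.  ``noise_sd=0`` gives the
    noiseless limit used for pipeline validation; ``noise_sd=None`` uses the
    signal-kind default.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    mns = preset.mn_levels_uM if mn_levels_uM is None else mn_levels_uM
    shots = preset.n_shots if n_shots is None else n_shots
    traces = []
    idx = 0
    for mn in mns:
        rates = rate_lookup((preset.rna_id, preset.protein_id), mn)
        for titrant in preset.titrant_uM:
            rna_uM, prot_uM = preset.system_concentrations(titrant)
            system = BindingSystem.single(rna_uM, prot_uM, rates,
                                          name=preset.protein_id)
            model = default_signal_model(preset.signal_kind, noise_sd)
            cond = Condition(preset.rna_id, preset.protein_id, rna_uM, prot_uM,
                             mn, preset.kcl_mM, preset.temperature_C)
            traces.append(generate_trace(
                system, model, n_points=preset.n_points,
                dead_time=preset.dead_time_s,
                seed=_child_seed(seed, 7919 * idx), n_shots=shots,
                kinetics=kinetics, condition=cond))
            idx += 1
    return traces


def generate_dilution_trace(pre_system: BindingSystem, dilution_factor: float,
                            post_rates: RateParameters | None = None,
                            signal_model: SignalModel | None = None,
                            n_points: int = 1000, t_end: float | None = None,
                            dead_time: float = 1e-3, seed: int | None = None,
                            n_shots: int = 1, kinetics: str = "observed",
                            condition: Condition | None = None) -> KineticTrace:
    """Relaxation trace after rapid dilution of a pre-equilibrated complex.

    The pre-mix system is solved to equilibrium, all concentrations are
    divided by ``dilution_factor`` (2 for the standard equal-volume mix),
    and the rate constants are switched to ``post_rates`` (e.g. the values
    in 50 uM Mn2+ when the complex is diluted into metal-containing
    buffer).  In the default ``observed`` mode the trace decays at the
    linearized relaxation rate k_on([R]free,eq + [P]free,eq) + k_off of the
    post-dilution system; ``mass_action`` integrates the full ODE.
    """
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    if len(pre_system.proteins) != 1:
        raise ValueError("dilution traces are defined for one protein")
    pre = pre_system.proteins[0]
    rates = pre.rates if post_rates is None else post_rates
    c_pre = equilibrium_complex(pre_system.rna_total_uM, pre.active_uM, pre.rates.K_d)

    rna = pre_system.rna_total_uM / dilution_factor
    prot = pre.total_uM / dilution_factor
    c0 = c_pre / dilution_factor
    post = BindingSystem.single(rna, prot, rates, name=pre.name,
                                initial_complex_uM=c0,
                                active_fraction=pre.active_fraction)

    if signal_model is None:
        signal_model = ANISOTROPY_DEFAULT
    p_active = post.proteins[0].active_uM
    c_eq = equilibrium_complex(rna, p_active, rates.K_d)

    k_relax = linearized_relaxation_rate(rna, p_active, rates)
    if t_end is None:
        t_end = max(10.0 / k_relax, 0.05)
    if t_end <= dead_time:
        raise ValueError("t_end must exceed the dead time")
    times = np.linspace(dead_time, t_end, n_points)

    if kinetics == "observed":
        course = c_eq + (c0 - c_eq) * np.exp(-k_relax * times)
    elif kinetics == "mass_action":
        course = simulate_binding_ode(post, times).complex_total()
    else:
        raise ValueError(f"unknown kinetics model {kinetics!r}")
    clean = signal_model.map(course, rna, prot)

    if signal_model.noise_sd > 0:
        shots = np.empty((n_shots, n_points))
        for i in range(n_shots):
            rng = np.random.default_rng(_child_seed(seed, i))
            shots[i] = clean + rng.normal(0.0, signal_model.noise_sd, n_points)
        signal = shots.mean(axis=0)
    else:
        signal = clean

    if condition is None:
        condition = Condition(protein_id=pre.name, rna_uM=rna, protein_uM=prot)
    return KineticTrace(times, signal, signal_model.kind, condition,
                        n_shots_averaged=n_shots, seed=seed)
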