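"""One-step bimolecular binding: rate laws, equilibria, lifetimes, competition.

The mechanism throughout is the single-step reversible association of an
RNA stem-loop (R) with a binding protein (P),

    R + P  <=>  RP        (forward k_on, reverse k_off)

with k_on in uM^-1 s^-1 and k_off in s^-1.  Under pseudo-first-order
conditions (protein in excess over labeled RNA) the relaxation of the
observable is a single exponential with observed rate

    k_obs = k_on * [P] + k_off,

so a titration of k_obs against protein concentration yields k_on (slope)
and k_off (intercept), and the equilibrium dissociation constant follows as
K_d = k_off / k_on.  Internal units are uM for concentrations and seconds
for time; K_d is reported in nM, the conventional scale for the
nanomolar-affinity RNA/protein complexes this package models.  The unit
conversion lives only in :func:`compute_Kd` and :attr:`RateParameters.K_d`.

A two-protein extension covers the regulatory competition between a
translational repressor (IRP1) and the initiation factor eIF4F for the same
RNA: both the equilibrium partition of the RNA and the kinetic
(initial-capture) partition are exposed, because which protein wins can be
decided by rates rather than by affinities alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "RateParameters",
    "Protein",
    "BindingSystem",
    "Trajectory",
    "LifetimeInput",
    "PartitionResult",
    "single_exponential",
    "double_exponential",
    "kobs_linear",
    "kobs_dilution",
    "compute_Kd",
    "complex_lifetime",
    "equilibrium_complex",
    "linearized_relaxation_rate",
    "simulate_binding_ode",
    "equilibrium_partition",
    "kinetic_partition",
]

_UM_TO_NM = 1000.0


@dataclass(frozen=True)
class RateParameters:
    """Rate constants of one RNA/protein pair under one solution condition.

    Parameters
    ----------
    k_on : float
        Association rate constant, uM^-1 s^-1. Must be positive.
    k_off : float
        Dissociation rate constant, s^-1. Must be non-negative.
    k_on_se, k_off_se : float, optional
        Standard errors in the same units.
    label : str
        Free-text condition tag, e.g. ``"FRT/IRP1 @ 25 uM Mn2+"``.
    """

    k_on: float
    k_off: float
    k_on_se: float | None = None
    k_off_se: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        # k_on = 0 is admitted as the pure-dissociation limit (K_d -> inf)
        if self.k_on < 0:
            raise ValueError(f"k_on must be non-negative, got {self.k_on}")
        if self.k_off < 0:
            # a fitted intercept may legitimately come out slightly negative;
            # it is reported as-is (never clamped) but is not physical
            import warnings

            warnings.warn(f"negative k_off ({self.k_off:.3g} s^-1) is not "
                          "physical; treat as a statistical artefact of the fit",
                          RuntimeWarning, stacklevel=2)

    @property
    def K_d(self) -> float:
        """Equilibrium dissociation constant k_off/k_on, in nM (inf if k_on=0)."""
        if self.k_on == 0:
            return math.inf
        return compute_Kd(self.k_on, self.k_off)

    @property
    def K_d_se(self) -> float | None:
        """First-order propagated standard error of K_d, in nM."""
        if self.k_on_se is None or self.k_off_se is None:
            return None
        rel = math.hypot(self.k_off_se / self.k_off if self.k_off else 0.0,
                         self.k_on_se / self.k_on)
        return self.K_d * rel

    def with_label(self, label: str) -> "RateParameters":
        return replace(self, label=label)


@dataclass(frozen=True)
class Protein:
    """One protein species in a binding system (totals are post-mixing)."""

    name: str
    total_uM: float
    rates: RateParameters
    initial_complex_uM: float = 0.0
    #: fraction of the nominal protein that is binding-competent
    active_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.total_uM < 0:
            raise ValueError("protein total must be non-negative")
        if self.initial_complex_uM < 0:
            raise ValueError("initial complex must be non-negative")
        if not (0 < self.active_fraction <= 1):
            raise ValueError("active_fraction must be in (0, 1]")

    @property
    def active_uM(self) -> float:
        return self.total_uM * self.active_fraction


@dataclass(frozen=True)
class BindingSystem:
    """Species inventory for a mixing experiment: one RNA, one or two proteins."""

    rna_total_uM: float
    proteins: tuple[Protein, ...]

    def __post_init__(self) -> None:
        if self.rna_total_uM < 0:
            raise ValueError("RNA total must be non-negative")
        if not 1 <= len(self.proteins) <= 2:
            raise ValueError("a BindingSystem holds one or two proteins")
        if sum(p.initial_complex_uM for p in self.proteins) > self.rna_total_uM + 1e-12:
            raise ValueError("initial complexes exceed total RNA")
        for p in self.proteins:
            if p.initial_complex_uM > p.active_uM + 1e-12:
                raise ValueError(f"initial complex exceeds active {p.name}")

    @classmethod
    def single(cls, rna_total_uM: float, protein_total_uM: float,
               rates: RateParameters, name: str = "protein",
               initial_complex_uM: float = 0.0,
               active_fraction: float = 1.0) -> "BindingSystem":
        return cls(rna_total_uM,
                   (Protein(name, protein_total_uM, rates,
                            initial_complex_uM, active_fraction),))


@dataclass(frozen=True)
class Trajectory:
    """Mass-action time course: per-species concentrations in uM."""

    times: np.ndarray
    rna_free: np.ndarray
    protein_free: dict[str, np.ndarray]
    complexes: dict[str, np.ndarray]

    def complex_total(self) -> np.ndarray:
        return np.sum(list(self.complexes.values()), axis=0)

    def to_frame(self):
        import pandas as pd

        cols = {"time_s": self.times, "rna_free_uM": self.rna_free}
        for name, y in self.protein_free.items():
            cols[f"{name}_free_uM"] = y
        for name, y in self.complexes.items():
            cols[f"{name}_complex_uM"] = y
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class LifetimeInput:
    """Inputs of the complex-lifetime relation 1/tau = k_on([R]+[P]) + k_off."""

    rate: RateParameters
    rna_final_uM: float
    protein_final_uM: float

    def __post_init__(self) -> None:
        if self.rna_final_uM < 0 or self.protein_final_uM < 0:
            raise ValueError("final concentrations must be non-negative")


# ----------------------------------------------------------------- rate laws

def single_exponential(t, delta_r: float, k_obs: float, r_f: float):
    """Single-exponential relaxation  r(t) = delta_r * exp(-k_obs t) + r_f.

    ``delta_r`` is the (signed) amplitude and ``r_f`` the final plateau; the
    curve relaxes monotonically from ``delta_r + r_f`` at t=0 toward ``r_f``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time is not allowed")
    if k_obs < 0:
        raise ValueError("k_obs must be non-negative")
    out = delta_r * np.exp(-k_obs * t) + r_f
    return out if out.ndim else float(out)


def double_exponential(t, delta_r1: float, k_obs1: float,
                       delta_r2: float, k_obs2: float, r_f: float):
    """Biphasic relaxation: sum of two exponential terms plus an offset.

    Reduces to :func:`single_exponential` when ``delta_r2 == 0``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time is not allowed")
    if k_obs1 < 0 or k_obs2 < 0:
        raise ValueError("rates must be non-negative")
    out = delta_r1 * np.exp(-k_obs1 * t) + delta_r2 * np.exp(-k_obs2 * t) + r_f
    return out if out.ndim else float(out)


def kobs_linear(rate: RateParameters, protein_conc_uM: float) -> float:
    """Pseudo-first-order observed rate, k_obs = k_on [P] + k_off (s^-1)."""
    if protein_conc_uM < 0:
        raise ValueError("concentration must be non-negative")
    return rate.k_on * protein_conc_uM + rate.k_off


def kobs_dilution(k_off: float, K_d_nM: float, protein_conc_uM: float) -> float:
    """Observed relaxation rate after dilution, k_obs = k_off ([P]/K_d + 1).

    Algebraically identical to :func:`kobs_linear` with k_on = k_off/K_d;
    the form used when K_d is known and k_off is the quantity sought.
    """
    if K_d_nM <= 0:
        raise ValueError("K_d must be positive")
    if protein_conc_uM < 0:
        raise ValueError("concentration must be non-negative")
    return k_off * (protein_conc_uM * _UM_TO_NM / K_d_nM + 1.0)


def compute_Kd(k_on: float, k_off: float) -> float:
    """K_d = k_off/k_on, converted from uM to nM."""
    if k_on <= 0:
        raise ValueError("k_on must be positive")
    if k_off < 0:
        raise ValueError("k_off must be non-negative")
    return k_off / k_on * _UM_TO_NM


def complex_lifetime(rate: RateParameters | LifetimeInput,
                     rna_final_uM: float | None = None,
                     protein_final_uM: float | None = None) -> float:
    """Mean lifetime of the complex, tau = 1/(k_on([R]+[P]) + k_off), in s.

    ``[R]`` and ``[P]`` are the final (post-mixing) total concentrations.
    Accepts either a :class:`LifetimeInput` or explicit arguments.
    """
    if isinstance(rate, LifetimeInput):
        inp = rate
        rate, rna_final_uM, protein_final_uM = inp.rate, inp.rna_final_uM, inp.protein_final_uM
    if rna_final_uM is None or protein_final_uM is None:
        raise TypeError("rna_final_uM and protein_final_uM are required")
    if rna_final_uM < 0 or protein_final_uM < 0:
        raise ValueError("concentrations must be non-negative")
    denom = rate.k_on * (rna_final_uM + protein_final_uM) + rate.k_off
    if denom <= 0:
        raise ValueError("total relaxation rate is zero; lifetime undefined")
    return 1.0 / denom


# ------------------------------------------------------------- equilibrium

def equilibrium_complex(rna_uM: float, protein_uM: float, K_d_nM: float) -> float:
    """Equilibrium complex concentration for one protein, in uM.

    Closed-form root of the mass-balance quadratic
    ``c^2 - (R + P + K_d) c + R P = 0``, written in the numerically stable
    form ``c = 2RP / (b + sqrt(b^2 - 4RP))`` to avoid cancellation when the
    complex is nearly stoichiometric.
    """
    if rna_uM < 0 or protein_uM < 0:
        raise ValueError("concentrations must be non-negative")
    if K_d_nM <= 0:
        raise ValueError("K_d must be positive")
    kd = K_d_nM / _UM_TO_NM
    b = rna_uM + protein_uM + kd
    disc = math.sqrt(b * b - 4.0 * rna_uM * protein_uM)
    return 2.0 * rna_uM * protein_uM / (b + disc)


def linearized_relaxation_rate(rna_total_uM: float, protein_total_uM: float,
                               rate: RateParameters) -> float:
    """Relaxation rate of small perturbations about the binding equilibrium.

    1/tau = k_on ([R]_free,eq + [P]_free,eq) + k_off — the exact decay rate
    of the mass-action system close to equilibrium, e.g. after a modest
    dilution of a pre-formed complex.
    """
    c_eq = equilibrium_complex(rna_total_uM, protein_total_uM, rate.K_d)
    r_free = rna_total_uM - c_eq
    p_free = protein_total_uM - c_eq
    return rate.k_on * (r_free + p_free) + rate.k_off


# -------------------------------------------------------------- simulation

def simulate_binding_ode(system: BindingSystem, times) -> Trajectory:
    """Integrate the mass-action kinetics of one RNA with one or two proteins.

    State variables are the complex concentrations c_i with

        dc_i/dt = k_on,i * R_free * P_i,free - k_off,i * c_i,

    R_free and P_i,free following from conservation of totals.  A
    stiff-capable integrator (LSODA) at rtol 1e-9 / atol 1e-12 is used
    because observed rates span roughly 5-430 s^-1 while traces span
    milliseconds to seconds.  Initial complexes (pre-equilibrated dilution
    experiments) are honoured.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("times must be a 1-D grid with at least 2 points")
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be non-negative and strictly increasing")

    prots = system.proteins
    y0 = np.array([p.initial_complex_uM for p in prots])

    def rhs(_t, y):
        r_free = system.rna_total_uM - y.sum()
        return np.array([
            p.rates.k_on * r_free * (p.active_uM - y[i]) - p.rates.k_off * y[i]
            for i, p in enumerate(prots)
        ])

    sol = solve_ivp(rhs, (0.0, float(times[-1])), y0, t_eval=times,
                    method="LSODA", rtol=1e-9, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")

    y = sol.y
    # clip tiny negative excursions from the integrator, fail on real ones
    if np.any(y < -1e-9):
        raise RuntimeError("integration produced significantly negative concentrations")
    y = np.clip(y, 0.0, None)

    complexes = {p.name: y[i] for i, p in enumerate(prots)}
    rna_free = np.clip(system.rna_total_uM - y.sum(axis=0), 0.0, None)
    protein_free = {p.name: np.clip(p.active_uM - y[i], 0.0, None)
                    for i, p in enumerate(prots)}
    return Trajectory(times, rna_free, protein_free, complexes)


# ------------------------------------------------------------- competition

@dataclass(frozen=True)
class PartitionResult:
    """Equilibrium partition of the RNA between free and bound states."""

    free_rna_uM: float
    complex_uM: tuple[float, ...]
    fraction_free: float
    fraction_bound: tuple[float, ...]

    @property
    def fractions(self) -> tuple[float, ...]:
        return (self.fraction_free, *self.fraction_bound)


def equilibrium_partition(rna_total_uM: float, p1_total_uM: float,
                          p2_total_uM: float, Kd1_nM: float,
                          Kd2_nM: float) -> PartitionResult:
    """Partition of one RNA between two competing proteins at equilibrium.

    Solves the coupled equilibria by a bounded scalar root-find on the free
    RNA concentration r:

        g(r) = r + sum_i  P_i,tot * r / (K_d,i + r)  -  R_tot = 0,

    which is strictly increasing in r, so the bracket [0, R_tot] always
    contains exactly one root.
    """
    if Kd1_nM <= 0 or Kd2_nM <= 0:
        raise ValueError("K_d values must be positive")
    if min(rna_total_uM, p1_total_uM, p2_total_uM) < 0:
        raise ValueError("concentrations must be non-negative")
    if rna_total_uM == 0:
        raise ValueError("RNA total must be positive to define fractions")
    kds = (Kd1_nM / _UM_TO_NM, Kd2_nM / _UM_TO_NM)
    ptots = (p1_total_uM, p2_total_uM)

    def g(r):
        return r + sum(p * r / (kd + r) for p, kd in zip(ptots, kds)) - rna_total_uM

    if g(rna_total_uM) <= 0:  # no protein at all
        r = rna_total_uM
    else:
        r = brentq(g, 0.0, rna_total_uM, xtol=1e-15, rtol=1e-14, maxiter=200)
    complexes = tuple(p * r / (kd + r) for p, kd in zip(ptots, kds))
    fracs = tuple(c / rna_total_uM for c in complexes)
    return PartitionResult(r, complexes, r / rna_total_uM, fracs)


def kinetic_partition(p1_total_uM: float, p2_total_uM: float,
                      rate1: RateParameters, rate2: RateParameters) -> tuple[float, float]:
    """Initial-capture fractions under the instantaneous-flux approximation.

    Immediately after mixing, free RNA is captured by protein i in
    proportion to its association flux k_on,i * P_i; rebinding and
    re-equilibration are ignored.  The full time-resolved answer is
    available through :func:`simulate_binding_ode`; both views are exposed
    because competition between a fast-binding repressor and a slower,
    tighter activator can be decided kinetically rather than
    thermodynamically.
    """
    if p1_total_uM < 0 or p2_total_uM < 0:
        raise ValueError("concentrations must be non-negative")
    f1 = rate1.k_on * p1_total_uM
    f2 = rate2.k_on * p2_total_uM
    total = f1 + f2
    if total <= 0:
        raise ValueError("total association flux is zero; partition undefined")
    return f1 / total, f2 / total
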