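"""Tabulated rate constants and named experimental designs.

The rate tables collect the measured association/dissociation constants for
the two IRE-RNA variants (ferritin FRT and mitochondrial aconitase ACO2)
binding the repressor IRP1, and for FRT binding the initiation factor
eIF4F, each as a function of Mn2+ concentration.  Mn2+ acts as an
air-stable surrogate for the physiological Fe2+ signal: it slows IRP1
association and speeds its dissociation, while doing the opposite for
eIF4F — the switch that flips the RNA from repressor-bound to
activator-bound.

Design presets bundle a rate table entry with the instrument acquisition
settings (concentration series, signal kind, shots averaged) of the
standard stopped-flow experiments so that synthetic data for a whole
figure-style titration can be generated from one name.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import RateParameters

__all__ = [
    "RATE_TABLE",
    "DILUTION_KOFF",
    "DesignPreset",
    "PRESETS",
    "rate_lookup",
    "get_preset",
]

# (k_on uM^-1 s^-1, k_off s^-1, k_on SE, k_off SE) by (rna, protein, mn_uM)
RATE_TABLE: dict[tuple[str, str], dict[float, tuple[float, float, float, float]]] = {
    ("FRT", "IRP1"): {
        0.0: (400.0, 6.2, 7.3, 0.3),
        5.0: (176.0, 9.7, 4.3, 0.4),
        25.0: (104.0, 11.7, 3.5, 0.3),
        50.0: (65.0, 12.0, 2.7, 0.5),
    },
    ("ACO2", "IRP1"): {
        0.0: (51.5, 7.0, 1.8, 0.4),
        5.0: (35.2, 7.6, 1.6, 0.3),
        25.0: (17.0, 7.8, 1.2, 0.3),
        50.0: (10.7, 8.0, 0.7, 0.4),
    },
    ("FRT", "eIF4F"): {
        0.0: (81.0, 4.8, 3.3, 0.3),
        5.0: (119.0, 3.3, 5.4, 0.2),
        25.0: (159.0, 2.5, 6.7, 0.1),
        50.0: (228.0, 1.8, 9.8, 0.06),
    },
}

#: dissociation rates measured directly by 2-fold dilution of the
#: pre-formed complex (s^-1); "buffer" = dilution into plain buffer,
#: "mn50" = dilution into buffer containing 50 uM Mn2+
DILUTION_KOFF: dict[tuple[str, str, str], tuple[float, float]] = {
    ("FRT", "IRP1", "buffer"): (8.3, 0.4),
    ("ACO2", "IRP1", "buffer"): (9.1, 0.6),
    ("FRT", "IRP1", "mn50"): (24.0, 1.5),
    ("ACO2", "IRP1", "mn50"): (16.4, 1.3),
}

def _normalize_pair(pair) -> tuple[str, str]:
    if isinstance(pair, str):
        for sep in ("·", "/", "-", "_"):
            if sep in pair:
                pair = tuple(pair.split(sep, 1))
                break
        else:
            raise KeyError(f"unknown RNA/protein pair: {pair!r}")
    rna, protein = pair
    for (r, p) in RATE_TABLE:
        if r.upper() == str(rna).upper() and p.upper() == str(protein).upper():
            return (r, p)
    raise KeyError(f"unknown RNA/protein pair: {(rna, protein)!r}")


def rate_lookup(pair, mn_uM: float = 0.0, interpolate: bool = False) -> RateParameters:
    """Rate constants for an RNA/protein pair at a given Mn2+ concentration.

    ``pair`` may be a (rna, protein) tuple or a string like ``"FRT/IRP1"``.
    Tabulated Mn2+ levels are 0, 5, 25 and 50 uM; with ``interpolate=True``
    the rate constants are interpolated log-linearly in Mn2+ between the
    tabulated points (rates change multiplicatively with the metal ion, so
    interpolation is done on log k).
    """
    rna, protein = _normalize_pair(pair)
    table = RATE_TABLE[(rna, protein)]
    label = f"{rna}/{protein} @ {mn_uM:g} uM Mn2+"
    if mn_uM in table:
        k_on, k_off, se_on, se_off = table[mn_uM]
        return RateParameters(k_on, k_off, se_on, se_off, label)
    if not interpolate:
        raise KeyError(f"Mn2+ = {mn_uM} uM not tabulated for {rna}/{protein}; "
                       "pass interpolate=True for log-linear interpolation")
    import numpy as np

    mns = sorted(table)
    if not (mns[0] <= mn_uM <= mns[-1]):
        raise ValueError(f"Mn2+ = {mn_uM} uM outside the tabulated range {mns[0]}-{mns[-1]}")
    log_kon = np.interp(mn_uM, mns, np.log([table[m][0] for m in mns]))
    log_koff = np.interp(mn_uM, mns, np.log([table[m][1] for m in mns]))
    return RateParameters(float(np.exp(log_kon)), float(np.exp(log_koff)),
                          label=label + " (interpolated)")


@dataclass(frozen=True)
class DesignPreset:
    """Template for one stopped-flow titration design.

    ``titrant_uM`` is the series of concentrations of the varied species
    (the protein for anisotropy designs with labeled RNA; the RNA for
    fluorescence designs that watch intrinsic protein fluorescence), and
    ``fixed_uM`` the constant concentration of the observed species.  All
    concentrations are final, i.e. after mixing in the stopped-flow cell.
    """

    name: str
    rna_id: str
    protein_id: str
    signal_kind: str  # "anisotropy" | "fluorescence"
    fixed_uM: float
    titrant_uM: tuple[float, ...]
    mn_levels_uM: tuple[float, ...] = (0.0,)
    kcl_mM: float = 100.0
    temperature_C: float = 25.0
    n_shots: int = 5
    n_points: int = 1000
    dead_time_s: float = 1e-3
    description: str = ""

    def system_concentrations(self, titrant: float) -> tuple[float, float]:
        """(rna_uM, protein_uM) for one titration point."""
        if self.signal_kind == "anisotropy":
            return self.fixed_uM, titrant
        return titrant, self.fixed_uM


_IRP1_SERIES = (0.05, 0.2, 0.5, 1.0)
_EIF4F_SERIES = (0.1, 0.2, 0.5)

PRESETS: dict[str, DesignPreset] = {p.name: p for p in [
    DesignPreset("fig2_frt", "FRT", "IRP1", "anisotropy", 0.05, _IRP1_SERIES,
                 description="IRP1 titration (0.05-1 uM) against 0.05 uM labeled FRT IRE-RNA"),
    DesignPreset("fig2_aco2", "ACO2", "IRP1", "anisotropy", 0.05, _IRP1_SERIES,
                 description="IRP1 titration against 0.05 uM labeled ACO2 IRE-RNA"),
    DesignPreset("fig3_frt_mn", "FRT", "IRP1", "anisotropy", 0.05, _IRP1_SERIES,
                 mn_levels_uM=(0.0, 5.0, 25.0, 50.0),
                 description="FRT/IRP1 titrations at 0, 5, 25 and 50 uM Mn2+"),
    DesignPreset("fig3_aco2_mn", "ACO2", "IRP1", "anisotropy", 0.05, _IRP1_SERIES,
                 mn_levels_uM=(0.0, 5.0, 25.0, 50.0),
                 description="ACO2/IRP1 titrations at 0, 5, 25 and 50 uM Mn2+"),
    DesignPreset("fig7_eif4f", "FRT", "eIF4F", "fluorescence", 0.1, _EIF4F_SERIES,
                 description="FRT IRE-RNA titration (0.1-0.5 uM) against 0.1 uM eIF4F, "
                             "intrinsic protein fluorescence"),
    DesignPreset("fig7_eif4f_mn", "FRT", "eIF4F", "fluorescence", 0.1, _EIF4F_SERIES,
                 mn_levels_uM=(0.0, 5.0, 25.0, 50.0),
                 description="FRT/eIF4F titrations at 0, 5, 25 and 50 uM Mn2+"),
]}


def get_preset(name: str) -> DesignPreset:
    try:
        return PRESETS[name.replace("-", "_")]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
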