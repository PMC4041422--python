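"""Dissociation rate from a 2-fold dilution relaxation experiment.

A pre-equilibrated IRE-RNA/IRP1 complex (0.1 uM RNA + 2 uM IRP1) is
rapidly diluted two-fold in the stopped-flow cell.  The anisotropy decays
toward the new equilibrium; the fitted relaxation rate, corrected for
protein rebinding through the known K_d, yields k_off.
"""

from stopflow import (
    BindingSystem,
    analyze_dilution,
    default_signal_model,
    fit_single_exponential,
    generate_dilution_trace,
    rate_lookup,
)

rates = rate_lookup(("FRT", "IRP1"), 0.0)
pre_mix = BindingSystem.single(0.1, 2.0, rates)

trace = generate_dilution_trace(pre_mix, dilution_factor=2.0,
                                signal_model=default_signal_model("anisotropy", 0.0))
fit = fit_single_exponential(trace)
k_off = analyze_dilution(fit.k_obs, protein_conc_uM=1.0, K_d_prior_nM=rates.K_d)

print(f"relaxation rate after dilution: k_obs = {fit.k_obs:.1f} s^-1")
print(f"rebinding correction: k_off = k_obs / (1 + [IRP1]/K_d)")
print(f"k_off = {k_off:.2f} s^-1   (generating value {rates.k_off} s^-1)")
print("\nThe observed relaxation is much faster than pure dissociation because")
print("free IRP1 (1 uM >> K_d) rebinds the RNA; dividing out the rebinding")
print("term recovers the dissociation rate to within a few percent.")
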