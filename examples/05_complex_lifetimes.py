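"""Mean lifetimes of the repressor and activator complexes.

tau = 1/(k_on([RNA] + [protein]) + k_off) at the post-mixing
concentrations of the standard experiments.  The short-lived IRP1 complex
can respond quickly to changes in cellular iron, while the longer-lived
eIF4F complex provides a stable platform for initiation-complex assembly.
"""

from stopflow import compare_complex_lifetimes, rate_lookup

cmp = compare_complex_lifetimes(
    rate_lookup(("FRT", "eIF4F"), 0.0), rate_lookup(("FRT", "IRP1"), 0.0),
    conc1=(0.5, 0.1),   # 0.5 uM RNA + 0.1 uM eIF4F
    conc2=(0.05, 1.0),  # 0.05 uM RNA + 1.0 uM IRP1
)

print(f"tau(eIF4F/FRT IRE)  = {cmp.tau1_s * 1e3:.2f} ms")
print(f"tau(IRP1/FRT IRE)   = {cmp.tau2_s * 1e3:.2f} ms")
print(f"ratio               = {cmp.ratio:.1f}x")
print("\nThe activator complex outlives the repressor complex ~8-fold under")
print("these conditions, even though IRP1 binds with higher affinity.")
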