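"""Competition of IRP1 (repressor) and eIF4F (activator) for one IRE-RNA.

At equal protein totals, the RNA's fate is computed two ways for each Mn2+
level: the coupled two-ligand binding equilibrium (thermodynamic control)
and the instantaneous association-flux split (kinetic control -- which
protein captures the free RNA first).
"""

from stopflow import competition_summary

df = competition_summary(rna_uM=0.01, irp1_uM=0.1, eif4f_uM=0.1)
print(df[["Kd_IRP1_nM", "Kd_eIF4F_nM", "eq_bound_IRP1", "eq_bound_eIF4F",
          "kinetic_capture_IRP1", "kinetic_capture_eIF4F"]]
      .to_string(float_format=lambda v: f"{v:.3g}"))

print("\nWithout metal the repressor wins on both counts (faster association")
print("AND tighter binding); at 50 uM Mn2+ both columns flip to eIF4F.")
print("Because the rate constants respond to metal more steeply than the")
print("equilibrium constants, the switch is largely kinetically controlled.")
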