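"""Association kinetics of IRP1 with ferritin IRE-RNA.

Generates a noiseless stopped-flow anisotropy titration (labeled RNA fixed
at 0.05 uM, IRP1 at 0.05-1.0 uM), fits each trace with a single
exponential, and regresses the observed rates on protein concentration.
The slope is the association rate constant k_on, the intercept the
dissociation rate k_off, and their ratio the equilibrium dissociation
constant K_d.
"""

from stopflow import run_titration_analysis
from stopflow.analyze import linear_fit_of

report = run_titration_analysis("fig2_frt", noise_sd=0.0)
cond = report.conditions[0.0]

print("IRP1 (uM)   k_obs (s^-1)")
for conc, k in zip(cond.concentrations_uM, cond.k_obs):
    print(f"  {conc:5.2f}     {k:8.2f}")

rates = cond.rates
lf = linear_fit_of(rates)
print(f"\nk_on  = {rates.k_on:.1f} uM^-1 s^-1  (slope, R^2 = {lf.r_squared:.6f})")
print(f"k_off = {rates.k_off:.2f} s^-1          (intercept)")
print(f"K_d   = {rates.K_d:.1f} nM            (k_off/k_on)")
print("\nThe observed rate grows linearly with [IRP1] -- the signature of a")
print("one-step bimolecular binding mechanism; K_d ~ 15.5 nM means IRP1")
print("binds the ferritin IRE with low-nanomolar affinity.")
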