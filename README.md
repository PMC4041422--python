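# stopflow

Stopped-flow kinetics of IRE-RNA/protein binding: trace simulation,
exponential relaxation fitting, and rate-constant analysis.

## The problem

Iron-responsive elements (IREs) are ~30-nucleotide mRNA stem-loops that sit
in the 5′ UTR of iron-metabolism mRNAs (ferritin, mitochondrial aconitase,
…) and bind two proteins with opposite effects: the repressor IRP1, which
blocks translation, and the initiation factor eIF4F, which promotes it.
Metal ions (Fe²⁺ in vivo; Mn²⁺ as its air-stable laboratory surrogate)
shift the balance between the two complexes, and the shift is visible not
only in the equilibrium constants but — more steeply — in the association
and dissociation *rates*.  Quantifying those rates is a job for stopped-flow
spectroscopy: rapid mixing, millisecond dead time, and relaxation traces
read out through fluorescence anisotropy (labeled RNA) or intrinsic protein
fluorescence.

`stopflow` packages that entire workflow for anyone analysing — or teaching,
or re-deriving — this kind of experiment:

* **binding model** — one-step bimolecular association R + P ⇌ RP with
  mass-action ODE integration, closed-form equilibria, observed-rate laws,
  complex lifetimes, and a two-protein competition extension
  (equilibrium partition and kinetic initial-capture partition);
* **synthetic data** — an instrument emulator (1-ms dead time, 1000 points
  per shot, multi-shot averaging, Gaussian noise) with named presets for the
  standard titration, metal-ion and dilution designs;
* **fitting** — single/double-exponential nonlinear least squares (lmfit),
  extra-sum-of-squares F-test model selection, residual diagnostics;
* **secondary analysis** — k_obs-vs-concentration regression
  (k_obs = k_on[P] + k_off, so slope → k_on, intercept → k_off,
  K_d = k_off/k_on), dilution relaxation analysis with rebinding
  correction, Mn²⁺ condition tables with fold changes, lifetime and
  competition summaries;
* **I/O + CLI** — self-describing CSV trace files, YAML/JSON run configs,
  and a thin `stopflow` command (`simulate`, `fit-trace`, `titration`,
  `dilution`, `compete`, `report`).

## Worked example

```python
from stopflow import run_titration_analysis

report = run_titration_analysis("fig2_frt", noise_sd=0.0)
rates = report.rates_at(0.0)
print(rates.k_on, rates.k_off, rates.K_d)
```

Running `python examples/01_association_kinetics.py` prints:

```
IRP1 (uM)   k_obs (s^-1)
   0.05        26.20
   0.20        86.20
   0.50       206.20
   1.00       406.20

k_on  = 400.0 uM^-1 s^-1  (slope, R^2 = 1.000000)
k_off = 6.20 s^-1          (intercept)
K_d   = 15.5 nM            (k_off/k_on)
```

The observed relaxation rate grows linearly with IRP1 concentration — the
signature of a one-step bimolecular mechanism — and the fitted line gives
the association rate constant (slope), the dissociation rate constant
(intercept) and a low-nanomolar equilibrium dissociation constant for the
ferritin IRE/IRP1 pair.  The other scripts in `examples/` walk through the
metal-ion response tables, dilution relaxations, repressor/activator
competition and complex lifetimes, each printing the numbers it computes
and a line on what they mean.

The same pipeline from the shell:

```bash
stopflow simulate --preset fig2_frt --noise 0 --seed 1 --out-dir traces/
stopflow titration --preset fig2_frt --noise 0 --out report.json
stopflow compete --mn 0,5,25,50 --rna 0.01 --p1 0.1 --p2 0.1
```

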