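# aobflux

Thermodynamic feasibility and stable-carbon-isotope back-flux analysis of
anaerobic butane oxidation (AOB).

Anaerobic alkane-oxidizing archaea run butane oxidation to CO₂ through an
alkyl-CoM reductase pathway in syntrophy with sulfate reducers. Because
every step of the pathway operates close to thermodynamic equilibrium,
the process is expected to be partly reversible: during net oxidation a
small back flux f₋ returns carbon from the CO₂ pool into butane. This
package, aimed at geomicrobiologists and isotope biogeochemists, provides
the two computational pieces needed to quantify that reversibility:

* **Pathway thermodynamics** — the 17-reaction catabolic model of AOB and
  its reverse (archaeal butane formation), with quasi-equilibrium solving
  of intermediate concentrations under proton-motive-force coupling
  (ΔG = 0 at equilibrium steps, n_H·Δµ_H⁺ at transduction steps, one
  dissipation slack ΔG_dis), feasibility assessment against a 1 µM–10 mM
  physiological window, and enumeration of proton stoichiometries.
* **Isotope mass balance** — converts ¹³C-DIC labeling time series
  (butane concentration and δ¹³C vs. time) into the back-flux extent

      µ(t) = f₋ / (n·f_net),

  via a first-order fit of the butane pool, a logistic fit of δ¹³C, and
  the closed-form isotope budget
  d[¹³C_Alk]/dt = f₋α₋F_CO₂ − n f₊α₊F_Alk. Includes the Rayleigh
  estimator of the forward fractionation factor (ε¹³C), flux-force
  diagnostics (f₋/f₊ = e^(ΔG/RT)), ensemble-MCMC posterior inference of
  the fit parameters with 95% credible bands on µ(t), synthetic
  experiment generators (parametric and mechanistic-ODE modes), and
  one-at-a-time sensitivity sweeps.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Simulate the default labeling experiment (6 mmol L⁻¹ butane, 18 mmol L⁻¹
DIC at 98 atom% ¹³C, sampled every 10 d with realistic noise), fit the
empirical models and evaluate the back flux:

```python
import numpy as np
from aobflux import ExperimentConfig, parametric_generate
from aobflux import fit_first_order, fit_logistic, back_flux_extent
from aobflux import IsotopeConstants, LabelingSetup

ts, truth = parametric_generate(ExperimentConfig(seed=42))
df = ts.averaged()                      # technical replicates averaged
fit = fit_first_order(df.time_d, df.butane_mmol_l)
lfit = fit_logistic(df.time_d, df.d13c_butane_permil)
print(f"first-order: c0={fit.c0:.3f} c1={fit.c1:.3f} lam={fit.lam:.4f}")
print(f"logistic:    d0={lfit.d0:.1f} d1={lfit.d1:.1f} d2={lfit.d2:.1f} k={lfit.k:.3f}")

t = np.linspace(0, 160, 1601)
traj = back_flux_extent(LabelingSetup(), fit, lfit, IsotopeConstants(), t)
print(f"mu_peak = {traj.mu_peak*1000:.2f} permil of net rate at t = {traj.t_peak:.0f} d")
```

Output:

```
first-order: c0=0.117 c1=6.000 lam=0.0408
logistic:    d0=-24.9 d1=80.0 d2=80.1 k=0.080
mu_peak = 2.02 permil of net rate at t = 85 d
```

The fitted decay constant (0.041 d⁻¹) and plateau (+80‰) recover the
generator truth; the back flux peaks mid-experiment at about 2‰ of the
net oxidation rate — the butane pool briefly "breathes back" two parts
per thousand of the carbon it oxidizes, then the back flux collapses as
butane is exhausted.

The same pipeline is scriptable from the shell:

```bash
aobflux simulate --seed 42 --out exp.csv
aobflux backflux --data exp.csv --out traj.csv
aobflux infer --data exp.csv --out post --chains 128 --steps 5000
aobflux thermo --direction aob --ex -0.22 --ratio 4 --json-out thermo.yaml
aobflux sensitivity --out sweep.csv
```

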