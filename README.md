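# chargemig

Desk-scale modelling of correlation-driven charge migration in ionised
adenine-like molecules.

## The problem

When an attosecond XUV pulse ionises adenine from an inner-valence
orbital, electron correlation can convert the hole into a *shake-up*
state: the hole relaxes while a second electron is promoted to a bound
excited orbital. A delayed few-fs NIR probe can then remove that excited
electron, producing an intact, doubly charged parent ion at the
half-integer mass-to-charge ratio m/z = 67.5 u/e. The delay dependence of
the dication yield therefore clocks a purely electronic, few-femtosecond
many-body process.

`chargemig` implements the full computational chain of such a study at
desk scale, on synthetic data and few-orbital model molecules:

1. **Synthetic pump-probe data** — delay-resolved seven-scan ion-yield
   datasets for the fragment channels (m/z 27, 38, 53, 108) and the
   parent dication (67.5), with Gaussian noise and a realistic SEM
   structure, plus rendered time-of-flight spectra.
2. **TOF extraction** — `t = k sqrt(m/z) + t0` calibration, mass-window
   integration, scan averaging, time-zero determination from a prompt
   step channel.
3. **Kinetic fitting** — two rate-equation curve models convolved
   analytically with the Gaussian instrument response
   (`FWHM_cc = sqrt(FWHM_pump^2 + FWHM_probe^2)`):

   * model A (step-decay): `y = b + A H(t-t0) exp(-(t-t0)/tau1)`
   * model B (rise-decay):
     `y = b + A tau2/(tau2-tau1) H(t-t0) [exp(-(t-t0)/tau2) - exp(-(t-t0)/tau1)]`

   fitted by weighted nonlinear least squares with seeded
   residual-resampling bootstrap 68% intervals
   (`KineticModel(...).fit() -> KineticFitResult.summary()`), plus the
   log-log intensity power law that counts the NIR photons.
4. **Golden-rule shake-up rates** —
   `Gamma(h->a) = (2 pi/hbar) sum_{i<j} |<ah||ij>|^2 delta_eta(e_i+e_j-e_h-e_a)`
   with a Lorentzian-broadened energy delta, statistically summed over
   XUV hole channels; characteristic time `tau_a = 1/Gamma_a` and the
   NIR-photon group `ceil(BE/1.77 eV)` per virtual.
5. **Many-body dynamics** — time-dependent Hartree-Fock, HF-GKBA at the
   second-Born level (time-local two-particle-correlation formulation),
   and an exact-CI oracle; NIR ionisation through an absorbing
   quasi-continuum; the observable is the NIR-induced depletion of the
   special shake-up state vs pump-probe delay.
6. **Real-space observable** — electron density integrated beyond ±3 Å
   from the molecular plane, with Gaussian-cube I/O.

The molecule generator is calibrated so the designated "special" virtual
has a golden-rule shake-up time of 2.5 fs and sits in the two-NIR-photon
window, while all other virtuals relax in a few hundred attoseconds —
the regime in which the delayed dication formation is a clock for the
shake-up process.

## Worked example

```python
import numpy as np
from chargemig import (irf_from_pulses, DatasetConfig,
                       simulate_pumpprobe_dataset, fit_ion_trace,
                       make_adenine_like_molecule, characteristic_times)

irf = irf_from_pulses(0.3, 4.0)                  # 0.3 fs XUV, 4 fs NIR
ds = simulate_pumpprobe_dataset(DatasetConfig(seed=1), irf)
frag = fit_ion_trace(ds.averaged("27"), model="A", irf=irf, n_boot=0)
fit = fit_ion_trace(ds.averaged("67.5"), model="B", irf=irf,
                    fix_t0=frag["t0"], n_boot=200, seed=1)
print(fit.summary())

mol = make_adenine_like_molecule(seed=0)          # calibrated
print(characteristic_times(mol).to_dataframe())
```

prints (seed 1):

```
Kinetic fit (model B), 81 points, residual rms 0.02221
     param        value                     68% CI
 amplitude       1.0542 [     1.0308,      1.0989]
  baseline       0.0091 [    -0.0046,      0.0091]
      tau1       2.7435 [     2.5331,      3.0324]
      tau2      22.6447 [    21.6515,     23.4566]
   virtual_id  energy_eV  gamma_per_fs    tau_fs  photon_group  special
0           8  -3.000000      0.400000  2.500000             2     True
1           9  -0.482438      1.274707  0.784494             1    False
```

The fitted rise time (2.74 fs for this noise realisation; 50-seed
ensemble mean 2.29 fs against a generator truth of 2.32 fs) is the
delayed onset of the dication channel; the rates table shows the special
state at its calibrated 2.5 fs characteristic time in the two-photon
group, with the fast virtual relaxing in under a femtosecond.

The same workflow is available from the shell:

```bash
chargemig run --seed 1 --out results/       # both arms, all artifacts
chargemig make-molecule --seed 0 --out mol.json
chargemig rates --molecule mol.json --out rates.csv
chargemig depletion --molecule mol.json --delays 0:8:0.5 --out depletion.csv
```

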