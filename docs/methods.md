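# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of `chargemig`. Units: fs and eV at
all public interfaces; Hartree atomic units inside the propagators
(1 a.u. time = 0.02418884 fs, 1 Ha = 27.21139 eV, atomic intensity unit
3.50945e16 W/cm²). Positive pump-probe delay means the NIR probe arrives
after the XUV pump.

## Pulses and instrument response

A pulse is a unit-peak envelope (cos² by default, compact support
`|t - c| <= FWHM`; Gaussian available) times a carrier
`cos(w(t-c) + CEP)`, with peak field `E0 = sqrt(I / 3.50945e16)` a.u.
Both envelope shapes are parameterised by the envelope FWHM, so they
agree at the peak and at the half-maximum points by construction. The
pump-probe instrument response is the Gaussian cross-correlation,
`FWHM_cc = sqrt(FWHM_pump² + FWHM_probe²)`; with the default 0.3 fs pump
and 4 fs probe, `sigma_irf = 1.703` fs.

## Kinetic curve models and fitting

Delay-dependent ion yields follow one of two rate-equation solutions,
convolved analytically with the Gaussian IRF via the exponentially
modified Gaussian,

    h(t; tau, sigma) = 1/2 exp(-t²/2sigma²) erfcx((sigma/tau - t/sigma)/sqrt2),

evaluated with `erfcx` so it is finite for any `sigma/tau`; for
arguments below -25 the closed exponential tail is used instead
(the erfcx branch would overflow there). Model A (prompt step with decay
`tau1`) describes the fragments; model B (rise `tau1`, slower decay
`tau2 > tau1`) describes the parent dication; its amplitude is defined
so that the unconvolved driving term `tau2/(tau2-tau1)(e^{-t/tau2} -
e^{-t/tau1})` carries prefactor `A`. The ordering constraint is enforced
smoothly by fitting `tau2 = tau1 + |delta|`.

Fits are weighted (1/sem²) nonlinear least squares
(Levenberg-Marquardt, trust-region fallback). 68% intervals come from
residual-resampling bootstrap (percentile method, seeded, default 500
replicates) rather than a parametric model, because real traces need
not be homoscedastic even though the synthetic ones are. The IRF width
may be fixed from the pulse durations or left free (a free step-width
parameter); both modes are exposed because either could have been used
experimentally. Time zero is anchored by fitting the prompt fragment
step (model A with free t0) and fixing that t0 in the dication fit;
a Gaussian-CDF step fit (`find_time_zero`) is provided for pure
reference steps without decay — applied to a decaying step it biases t0
early, which is why the pipeline uses the model-A anchor.

The NIR photon number is the rounded slope of log(yield) vs
log(intensity) over the explored 7e12-1.4e13 W/cm² range.

## Synthetic datasets

Five channels on a -20..+60 fs grid (1 fs step): positive steps with
slow decay at m/z 27, 38, 53 (tau1 = 60 fs, amplitudes 1.0/0.8/0.6 on
baseline 1), a negative step at 108 (amplitude -0.4, tau1 = 200 fs), and
the dication at 67.5 with model B at tau1 = 2.32 fs, tau2 = 24 fs,
baseline 0 — the experiment's fitted dication curve is the generator
truth. Noise is additive Gaussian, i.i.d. across delays and scans, with
standard deviation `noise_sigma * |amplitude|` (default 5%); seven scans
are drawn so the scan-mean SEM scales as `1/sqrt(7)`. TOF rendering
places Gaussian peaks (sd 0.05 u/e) at `t = 0.5 sqrt(m/z) + 1` µs on a
0.5 ns grid, scaled by 1000 counts per unit yield plus a constant
detector pedestal of 0.5 so counts stay nonnegative; the pedestal is a
rendering parameter, known to the tests, and is absorbed by the fitted
baselines in the pipeline. The 0.25 u/e default integration half-width
resolves the half-integer dication from its 67/68 neighbours.

What the generator does *not* emulate: drifting time zero between
scans, heteroscedastic or correlated detector noise, space-charge
saturation, and fragment channels sharing population with the dication.
Passing recovery tests therefore demonstrates the estimator chain is
unbiased at the stated noise structure, not robustness to systematic
drifts.

## Model molecules

A `ModelMolecule` stores spatial-orbital energies, real two-electron
integrals `<pq|rs>` (physicist notation, 8-fold permutational symmetry),
dipole elements, a designated inner-valence hole, a designated special
virtual, XUV hole weights and a global coupling scale `lambda` that
multiplies all two-electron integrals. Spin orbitals are
`p = 2*spatial + spin`; the neutral ground state is closed shell.

The default generator builds, per seed:

* two inner-valence hole channels at -14 eV (deep) and -12 eV (the
  designated hole, an HOMO-3 analogue), and six nearly degenerate
  shallow valence orbitals around -7.5 eV (irregularly spaced, ±0.3 eV);
* two bound virtuals: the special state at -3.0 eV — strictly inside the
  two-NIR-photon window (1.77, 3.54] eV — and a fast virtual placed at
  an exact two-hole-one-particle resonance of the deep channel;
* designed channel couplings added on full symmetry orbits over all 15
  shallow pairs: the designated hole couples only to the special state
  (g = 0.045 eV per pair before scaling), the deep hole only to the fast
  virtual(s) (g = 0.45 eV), on top of a small random 8-fold-symmetric
  background (sd 0.1 eV before symmetrisation);
* multiset-symmetric damping masks (factor 0.05) that remove cross
  couplings between the channels and the one-body (mean-field) matrix
  elements that would otherwise shift the designed detunings or mix the
  special state coherently as occupations evolve;
* XUV hole weights 0.9 on the designated hole and 0.1 on the deep
  channel — synthetic stand-ins for non-uniform ab-initio
  photoionisation probabilities. The weight split matters: the
  statistical sum defines `tau_special = 1/(w_h Gamma_h)`, while the
  dynamical rise of the special state after a hole in the designated
  channel proceeds at `Gamma_h`; with 0.9/0.1 the two agree within ~10%,
  keeping the rate table and the many-body dynamics consistent.

Calibration solves `lambda` so the statistically summed special-state
time equals 2.5 fs; the rate scales exactly as `lambda²`, so the closed
form lands on the target (a bisection guard refines to 1e-3 fs) and
recalibration is idempotent. Typical calibrated `lambda` is 0.8-1.1,
i.e. effective couplings stay well inside the second-Born validity
window. Fast-virtual times land at 0.2-0.8 fs, emulating the
few-hundred-attosecond background of the shake-up spectrum.

The shallow manifold is the quasi-continuum of two-hole final states:
six orbitals give 15 pair channels whose detunings sample the Lorentzian
weight irregularly over ±0.6 eV. Fewer channels make the special state's
population revive (two-level Rabi behaviour) instead of saturating; with
15 channels the exact dynamics is monotone to one part in ten over
13 fs, and the second-Born dynamics tracks it.

## Golden-rule rates

`Gamma(h->a) = (2 pi/hbar) sum_{i<j occ, i,j != h} |<ah|v|ij> - <ah|v|ji>|²
delta_eta(e_i + e_j - e_h - e_a)` with a Lorentzian `delta_eta`
(half-width 0.2 eV by default; the lineshape and width are package
choices, exposed in `FgrOptions` and swept in tests). Energies are bare
orbital (Koopmans) energies — no orbital relaxation — which is also how
the model Hamiltonian of the dynamics is defined, so the two modules
share one energy scale. The table sums both spin states of the promoted
electron and the weighted hole channels per spatial virtual; the
characteristic time is the inverse rate, with an infinity sentinel where
the rate vanishes. Photon grouping is `ceil(BE/1.77 eV)` with exact
multiples assigned to the lower group.

## Many-body dynamics

One model Hamiltonian serves all three propagators:
`H = sum h0 c+c + 1/4 sum <pq||rs> c+p c+q c_s c_r + E(t)·d`, with
`h0 = diag(eps) - V_HF[rho_neutral]` so the closed-shell ground state is
a mean-field stationary state with orbital energies `eps` exactly.
Sudden ionisation sets `rho0` to the neutral density matrix with one
hole; the CI oracle starts from the corresponding determinant.

* **Mean field**: exponential predictor-corrector stepping,
  `rho <- U rho U+` with `U = expm(-i h_mid dt)`, the corrector built
  from the averaged density and the midpoint field. Second order;
  halving the default step (0.8 a.u. = 0.019 fs) changes occupations by
  ~1e-6.
* **GKBA second Born**: implemented in the time-local form — the
  pair-correlation tensor
  `G2_{ijkl} = <c_k+ c_l+ c_j c_i> - (rho_ik rho_jl - rho_il rho_jk)`
  is transported by the mean-field propagator (the GKBA reconstruction),
  sourced by the Pauli-blocked second-order term
  `(1-rho)(1-rho) u rho rho - rho rho u (1-rho)(1-rho)`, and closes the
  equation of motion of `rho` through `-(i/2)(X - X+)`,
  `X_ij = sum u_iklm G2_{lmjk}`. This is equivalent to the second-Born
  collision-integral form with mean-field propagators but needs no
  history truncation and costs O(n^5) per step; the
  `PropagationGrid.memory_cutoff` field is retained for interface
  compatibility and is inert here. Occupations outside [-0.05, 1.05]
  raise an ansatz-breakdown warning. Near saturation the scheme
  overshoots the exact occupations by up to ~10% (a known second-Born
  artifact in finite systems); the rise itself tracks exact CI to a few
  per cent in the oracle fixtures.
* **Exact CI**: full Hamiltonian in the fixed-particle-number
  determinant basis (Slater-Condon elements), capacity-capped at 2^10
  determinants; eigendecomposition stepping when field-free, midpoint
  exponential otherwise. Norm and field-free energy are conserved to
  1e-10.

The correlated block may be a declared active space
(`ModelMolecule.active_spatial`): the packaged molecule excludes the
deep hole channel and the fast virtual — exact spectators for dynamics
started from the designated hole — which halves the correlated dimension
without touching the rate table.

### NIR ionisation surrogate and depletion

The probe continuum is a small absorbing ladder: a bridge level one NIR
photon (1.77 eV) above the special state, and six equally spaced levels
from the ionisation threshold upward (0.25 eV spacing), each with a
diagonal width `-i gamma/2` (gamma = 0.5 eV) so the photo-electron
leaves irreversibly; the bridge makes reaching the continuum from the
special state a two-photon process, matching the measured intensity
scaling. These levels carry no Coulomb integrals — a one-body escape
channel only.

`depletion_vs_delay` runs the dynamics with and without the NIR pulse
centred at each delay and averages the special-state occupation
difference over a 1 fs window after the pulse. The difference-of-runs
definition is a package choice (an absolute-drop definition would also
be possible). The no-NIR reference is propagated once and branched at
checkpoints, so each delay costs only the NIR window. All runs start at
the ionisation instant t = 0; any part of the NIR pulse preceding it is
ignored (the neutral molecule is not modelled). The finite pump is
handled by birth-time averaging: the depletion curve is averaged over
hole-creation times drawn from the pump intensity envelope (3 quantile
nodes by default), by interpolation on the delay grid.

Problem sizes used by the packaged scans: the default molecule gives a
16-spin-orbital correlated block inside a 30-spin-orbital one-body
space; the 0-8 fs depletion scan (0.5 fs steps, 17 delays) propagates
roughly 2e4 steps and completes in about two minutes on one core.

## Out-of-plane density

`Q(t) = sum_k n_k(t) * integral_{|d| >= distance} |phi_k|² dV` over both
half-spaces, with voxel membership decided by the voxel centre (no
partial-voxel weighting) and `distance = 0` recovering the full
integral. The membership rule is first-order accurate at a generic
grid/boundary alignment; the packaged fixtures and the refinement tests
use boundary-commensurate grids (the ±3 Å planes bisect voxel centres),
where it is second order. The plane defaults to the best-fit plane of
the supplied atom records (smallest principal axis). Cube files follow
the standard Bohr dialect; a negative voxel count in the header is
honoured as the Angstrom dialect on read.

## Known limitations

* The model molecules are designed, not ab-initio: they reproduce the
  *structure* of the problem (a slow, weakly coupled, two-photon-window
  shake-up state above an attosecond background) with the published
  characteristic time imposed by calibration; absolute rates carry no
  predictive content.
* The 24 fs decay of the dication signal is a non-adiabatic (nuclear)
  effect and is present only in the synthetic data generator, not in
  the electron dynamics.
* Second-Born overshoot near saturation limits quantitative statements
  about the depletion curve above ~6 fs delay to the ~10% level.
* The TOF model has no detector response beyond Gaussian peak shapes,
  and helium gating is emulated simply by starting spectra above
  m/z 4.
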