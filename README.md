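# liouvex

Liouville-space simulation of NMR spin dynamics with stochastic
exchange, phenomenological relaxation, and thermalization.

Most NMR simulation packages treat rigid spin systems; characterizing
*dynamics* — conformational exchange, reorientational motion, tumbling,
paramagnetic effects — requires propagating the density matrix in
Liouville space, where coherent evolution, chemical/spin exchange and
relaxation all enter one generator. `liouvex` is built for that use
case: it targets spectroscopists who want to simulate R<sub>1ρ</sub>,
CEST, EXSY, REDOR, exchange-induced T<sub>1</sub>/NOE, or pseudocontact
shifts with a few lines of Python, in solution, static or
magic-angle-spinning conditions, in the rotating or full lab frame.

## The model

The state is the column-stacked density matrix ρ̂(t); evolution is
generated by

```
L = L_coh + L_ex + L_relax
L_coh = -i (H ⊗ 1 − 1 ⊗ Hᵀ)
```

* **Coherent part.** Interactions are rank-0/2 spherical tensors in
  their principal axis system (A₂₀ = √(3/2) δ, A₂±₂ = −δη/2), rotated
  PAS → molecular → rotor frame by Wigner matrices, and assembled into
  rotating components Ĥₙ with Ĥ(t) = Σₙ e^(−inω_r t) Ĥₙ. Spherical
  tensor operators are truncated per spin according to the rotating/lab
  frame choice (secular approximation); continuous lab-frame RF uses a
  two-step-per-Larmor-cycle square-wave scheme.
* **Exchange.** N replicas of the system (with modulated interaction
  magnitudes or orientations) occupy diagonal blocks; a
  population-conserving rate matrix couples corresponding states,
  k_ex ⊗ 1. Spin exchange (state swaps within one replica, e.g. methyl
  rotation) is also available.
* **Relaxation.** T₁ as a one-spin random-field superoperator (with the
  implicit T₂ pruned off), T₂ as the squared z-commutator — along the
  Cartesian axes or in the Hamiltonian eigenbasis for tilted/mixed
  systems. Thermalization either by the Lindblad detailed-balance
  construction (W_{r→s}/W_{s→r} = e^(−βω_sr)) or by the "dynamic"
  scheme that inserts L·ρ_eq into the identity-aligned columns of L so
  exchange-induced relaxation recovers ρ_eq ∝ exp(−Ĥ/k_BT).
* **Propagation.** Piecewise-constant steps over the rotor grid and RF
  breakpoints; eigenbasis powers for repeated application (Dⁿ on the
  eigenvalue vector); γ-recycling of rotor-step propagators; exact basis
  reduction that discards Liouville blocks not connecting the initial
  state to a detector.

Tumbling models mimic isotropic reorientation with N-site exchange over
β-only, two-angle or three-angle orientation sets, detailed-balanced
rates ∝ 1/D², scaled so τ_c = (Σ A_i k_i)⁻¹, with `l2a_diagnostics`
reporting S², site populations, the correlation-time spectrum and the
amplitudes A_i.

## Worked example: R1rho from a dipole hop

A ¹H–¹³C dipole (δ = 44 kHz) hops by 15° between two sites with
τ_c = 1 μs; a 50 kHz ¹³C spin lock is applied under 10 kHz MAS:

```python
import numpy as np
import liouvex as lx

ex0 = lx.SpinSystem(B0=9.4, isotopes=["1H", "13C"], vr=10e3, n_gamma=30,
                    powder="JCP59")
ex0.add_interaction("dipole", (0, 1), delta=44e3, euler=[(0, 0, 0)])
ex1 = ex0.copy_with_new_orientation(0, [(0, np.radians(15), 0)])
L = lx.Liouvillian([ex0, ex1], kex=lx.two_site_kex(tauc=1e-6))

seq = L.sequence().add_channel("13C", amplitude=50e3)
rho = L.rho("13Cx", detect="13Cp")
signal = rho.det_prop(seq, n=400)      # one detection per rotor period

y = np.real(signal["13Cp"])
sel = (np.arange(y.size) >= 10) & (y > 0.1 * y[0])
rate = -np.polyfit(signal.t[sel], np.log(y[sel]), 1)[0]
print(f"Liouvillian dimension: {L.dim} (reduced to "
      f"{rho._map.dim} during DetProp)")
print(f"R1rho = {rate:.1f} s^-1 at a 50 kHz spin lock")
```

This prints

```
Liouvillian dimension: 32 (reduced to 16 during DetProp)
R1rho = 144.3 s^-1 at a 50 kHz spin lock
```

— the two 16-dimensional site Liouvillians form a 32×32 generator, of
which only 16 basis states connect ¹³Cx to the ¹³C⁺ detector (the basis
reduction keeps exactly those), and the stochastic reorientation of the
dipole produces a spin-lock decay of about 144 s⁻¹.

Declarative YAML configs cover the same ground from the shell:

```sh
liouvex simulate --config myexp.yaml --out outdir   # signal.csv + spectra
liouvex validate                                    # closed-form oracle checks
```

Packaged example configurations (R1rho, RECRR blocks, EXSY, CEST,
tumbling T₁/NOE, REDOR, pseudocontact shift) are in
`liouvex.fixtures.fixtures()`.

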