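# Methods

This note records the model, the conventions the package fixes where
the physics leaves a free choice, the numerical decisions, and the
known limits of what the test suite demonstrates.

## State, generator, detection

The density matrix is column-stacked into a vector (columns collected
one after the other), so for a d×d Hilbert space the identity operator
occupies Liouville indices 0, d+1, 2(d+1), …. Coherent evolution is
generated by L = −i(H ⊗ 1 − 1 ⊗ Hᵀ) — note the transpose, not the
adjoint. The sign is fixed so that ⟨Ŝ⁺⟩ under H = ωŜ_z evolves as
e^(−iωt); an isotropic shift of +ν Hz therefore appears at +ν Hz in the
spectrum (the FFT axis is flipped accordingly). Detection is the raw
inner product ⟨Ô⟩ = vec(Ô)†·vec(ρ), powder-weighted, with no
normalization by spin count or Boltzmann factors; `SpinSystem.
equilibrium_reference` supplies the thermal values to compare against.

Conventions fixed here (and verified end-to-end by the free-precession
and pulse-phase tests, since no external standard forces them):

* Larmor frequency ω₀ = −γB₀.
* Euler rotations are z-y-z, active; multiple sets on one interaction
  apply in order (PAS → molecular frame), then the powder orientation
  (molecular → rotor frame), then the rotor tilt and phase.
* RF phase 0 is +x; a +x π/2 pulse takes Ŝ_z to −Ŝ_y.
* Frequencies are entered in Hz everywhere in the API and converted to
  rad/s at the Hamiltonian boundary; angles are radians in the API and
  degrees in YAML configs.
* Anisotropies use the Haeberlen-style δ (A₂₀ = √(3/2)δ, A₂±₂ = −δη/2).
  For a dipolar coupling δ is the full anisotropy of the coupling as
  entered: an aligned static pair shows a ±δ/4 splitting pattern of the
  2ŜzÎz term. g-tensor values are unitless and converted through
  μ_B·B₀/ħ.

## Frames and truncation

Each spin is simulated in the rotating or the lab frame. Rotating-frame
spins lose their Zeeman term and their interactions keep only the
secular tensor components (heteronuclear two-spin terms reduce to
(2/√6)Ŝ₁zŜ₂z; homonuclear pairs keep the flip-flop term); lab-frame
spins keep all components. Continuous irradiation of a lab-frame spin
is implemented as a square wave, ±(π/2)ω₁Ŝ_y over half Larmor cycles of
the carrier (the π/2 rescales the square wave's fundamental to ω₁); the
one-cycle propagator is raised through its eigendecomposition to span a
rotor step, with the square-wave phase reset at each step. More steps
per cycle sample the cosine at midpoints with a 1/sinc(1/s) gain
correction. Fractional cycle counts use principal-branch eigenvalue
powers; the resulting sub-cycle phase approximation is irrelevant for
the slow observables these simulations target but means lab-frame FIDs
should be sampled stroboscopically or downmixed.

Thermal equilibrium always uses lab-frame energies: ρ_eq ∝
exp(−ħĤ_lab/k_BT) with the Zeeman terms of rotating-frame spins
re-added. Without this, thermalizing a rotating-frame simulation would
drive the polarization to ~0 rather than to tanh(ħω₀/2k_BT).

## Relaxation and thermalization

* T₁ (Cartesian): −(1/4T₁)(L⁺L⁻ + L⁻L⁺) from the ladder commutator
  superoperators, with diagonal damping terms that have no off-diagonal
  partner removed. That pruning is deliberately unphysical — it
  separates T₁ from the transverse decay it would otherwise imply — so
  adding T₁ without T₂ emits a warning.
* T₂ (Cartesian): −(1/T₂)L_z², which damps a coherence at
  (Δm)²-weighted rates and leaves populations untouched.
* Eigenbasis ("OS") mode: the T₁ superoperator is transformed into the
  Hamiltonian eigenbasis; the m largest off-diagonal magnitudes (m =
  the number of single-quantum transitions of that spin) are set to
  1/(2T₁) times the phase of the transformed element, with −1/(2T₁)
  column compensation so populations are conserved; ties across the
  selection boundary are resolved by taking all tied elements, and a
  failure to find m transitions raises. T₂ keeps only the diagonal of
  the transformed L_x²+L_y²+L_z², excluding population positions, at
  −1/(2T₂). In the untilted limit both reduce to the Cartesian forms
  (tested to 1e−10). Not recommended for S > 1 (one rate cannot serve
  several inequivalent transitions).
* Lindblad thermalization adds the antisymmetric part that enforces
  W_{r→s}/W_{s→r} = e^(−β_θ ω_sr) exactly, with β_θ = ħ/k_BT and ω_s
  the mean of the two Hamiltonian diagonal elements (eigenvalues in OS
  mode) behind Liouville index s. Off-diagonal additions retain the
  complex phase; diagonals use the absolute value with the sign of
  (1 − e^(−β_θω)).
* Dynamic thermalization inserts −L·ρ_eq into every identity-aligned
  column; since those state components sum to the (conserved) trace,
  dρ/dt = Lρ − Lρ_eq and ρ_eq is stationary. For numerical stability
  the correction columns are scaled up and the identity components of
  the state scaled down by a norm-balancing factor f (chosen so the
  correction block is commensurate with ‖L‖, clipped to [1, 1e12]);
  this is an exact similarity transform applied transparently in
  propagation and undone in detection.

## Propagation, caching, reduction

Time dependence is piecewise-constant over the union of the n_γ rotor
steps and the sequence breakpoints, evaluating L at each step midpoint
(second-order accurate; halving the step shrinks signal changes ~4×,
which the suite checks). Propagators are lazy; powers and the DetProp
driver use the eigendecomposition, resetting |λ| > 1 to the unit circle
and — for thermalized, unreduced systems — pinning the eigenvalue
nearest 1 to exactly 1. U ** inf zeroes every mode except that one.

Rotor-step propagators are recycled across the uniform γ grid whenever
(γ−γ′)/Δγ ≡ m′−m (mod n_γ) and the RF state matches; caches are kept
per RF field state (10 states by default, LRU). `Defaults["cache"]`
and `Defaults["parallel"]` (joblib powder loop, off by default) are the
global switches.

Exact basis reduction builds a superset sparsity pattern from the
tensor operators of every interaction, the RF operators of the supplied
sequences, exchange, relaxation and thermalization columns, splits it
into connected components and keeps only components overlapping both
the initial state and a detector. The superset guarantees exactness
(reduced and full detection agree to 1e−10 in randomized tests) at the
cost of reducing less when eigenbasis relaxation is active (its pattern
is orientation-dependent, so the whole site block is kept — consistent
with the pseudocontact-shift case, which does not reduce).

## Powder averages and tumbling

Packaged REPULSION-style tables (10/20/30/66/100 orientations,
three-column `alpha beta weight` text, degrees) were generated with an
electrostatic repulsion optimizer; ZCW-type sets come from the
Fibonacci construction; "JCP59" is a number-theoretic three-angle
lattice with stratified cos β and coprime generators for α and γ, with
sizes {q=2: 49, 3: 99, 4: 143, 5: 199, 6: 299} and default quality
q = 2 (49 orientations). α/β-only sets are γ-stepped with n_γ uniform
angles unless `gamma_encoded` is set; single-orientation sets default
to γ-encoded.

Tumbling models replicate the system over β-only (10q uniformly spaced
β, 2 neighbors), two-angle (3 axes at q=0, tetrahedral at q=1,
REPULSION for q ≥ 2; 2/3/5/6 neighbors) or three-angle (JCP59, 15
neighbors) orientation sets. Each orientation is coupled to its n
nearest neighbors by squared angular distance D² (sum of squared
angular distances of the frame axes, ties broken by index order; the
graph is then symmetrized by union, so a handful of node degrees can
exceed n). Base rates ∝ 1/D² are split pairwise to satisfy detailed
balance against the orientation weights, making the stationary
distribution equal the weights exactly. The global scale matches
τ_c = (Σ A_i k_i)⁻¹, where k_i are the nonzero exchange eigenvalues and
A_i the squared projections of a z-aligned rank-2 interaction's rotated
components onto the corresponding eigenmodes (normalized to 1); the
`l2a_diagnostics` routine reports the same A_i, S² (the zero-mode
amplitude fraction), populations and 1/k_i per interaction. Two-angle
models at q ≤ 1 are flagged qualitative. Three-angle q = 1 is
unsupported.

For β-only sets the angles are placed at interval midpoints of [0, π]
(sin β weighting would vanish at the poles and break the
detailed-balance rates).

## Example configurations

`fixtures()` packages representative experiments; parameter values not
dictated by the physics are typical literature numbers, stated in the
configs. Two regime choices matter and are easy to get wrong:

* R1rho from a dipolar hop: the spin-lock amplitude is 50 kHz = 5
  nutation cycles per rotor period, so rotor-synchronized detection is
  stroboscopic with the lock nutation; incommensurate amplitudes show
  large (real) rotary transients in the sampled points. Even so the
  powder average makes the exchange contribution to R1rho
  orientation-distributed, so the decay is only approximately
  monoexponential: over the first decade, skipping the initial
  transient, the log-linear fit reaches R² ≈ 0.998.
* Pseudocontact shift: the electron T₁/T₂ must be shorter than the
  tumbling correlation time, otherwise the electron polarization cannot
  follow the orientation-dependent (g-tilted) quantization axis and the
  temperature-dependent shift vanishes. The fixture uses 2 ps
  relaxation against 50 ps tumbling; shifts are measured against a
  hot-temperature reference simulation to separate the paramagnetic
  contribution from temperature-independent second-order shifts.

## What the tests do and do not show

The synthetic systems are small (≤ 3 spins, ≤ 49 exchange sites) with
idealized phenomenological relaxation; agreement with the
Bloch-McConnell lineshape (<1% of peak), the fast-exchange R1rho
dispersion (<5%), two-level Boltzmann polarization (1e−6) and exact
detailed balance validates the generator algebra, not any particular
molecule. Orientation-dependent relaxation maps, Redfield rates from
spectral densities, approximate (spin-order) basis reduction, shaped
pulses beyond piecewise-constant, and systems beyond ~6 spin-1/2 are
out of scope. Brute-force comparisons at 10× finer steps agree to
1e−6 only where the working grid is converged; for strongly coupled
MAS problems the discretization error at n_γ = 30 dominates any
fast-path effect, so machinery (cache/reduction/eigenbasis) is instead
validated exactly on a shared grid. Problem sizes in the suite (≤ 150
rotor steps, ≤ 8192 detection points, 49-site tumbling) keep the full
run under a minute while exercising every code path.
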