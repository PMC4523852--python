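# Methods

## Model and conventions

The system is a two-site excitonic dimer treated as a spin-boson
problem.  In the site basis {|1⟩, |−1⟩},

    H_sys = (ω0/2)·σ_z + J·σ_x,

with the site splitting ω0 and the tunneling (excitonic coupling) J
given in cm⁻¹.  Internally ħ = 1, time is in femtoseconds and every
energy is an angular frequency, ω = 2πc·ν̃ (rad/fs).  This convention is
pinned by the bath-relaxation times it implies: γ = 50 cm⁻¹ ↔ 1/γ ≈
106 fs and γ = 20 cm⁻¹ ↔ 265 fs.  Observables are reported in the
delocalized (exciton) basis |χ±⟩, the eigenbasis of H_sys with mixing
angle tan 2θ = 2J/ω0, θ ∈ [0, π/4], and splitting 2·sqrt((ω0/2)² + J²).

**Bath.**  Each site couples linearly to its own independent harmonic
bath with the Drude–Lorentz (overdamped Brownian oscillator) spectral
density J(ω) = (2λγ/π)·ω/(ω² + γ²), normalized so that the
reorganization energy is ∫J(ω)/ω dω = λ.  For two sites with
anticorrelated, statistically independent baths this reduces exactly to
a single collective bath coupled through

    V = σ_z/√2    (model.COUPLING_SCALE),

with the single-site correlation function G(t).  The factor is isolated
in one constant.  The per-site convention was selected because it is
the standard one in the photosynthetic-dimer literature and because it
simultaneously reproduces the two quantitative behaviors the benchmark
is calibrated against: the TC2 concurrence revival near 100 fs at
(ω0, J, λ, γ, T) = (40, 100, 5, 50 cm⁻¹, 200 K) and the TC2–HEOM
population overlap (≤ 0.01) at λ = 5 cm⁻¹, T = 250 K.  The collective
convention V = σ_z (a global λ → 2λ rescaling) retains the revival but
puts the weak-coupling population deviation at ≈ 0.02; V = σ_z/2
produces no revival at all.

**Correlation function.**  G(t) = ∫₀^∞ dω J(ω)[coth(βω/2)cos ωt −
i·sin ωt] is represented as a Drude pole plus K Matsubara exponentials:

    c₀ = λγ(cot(βγ/2) − i),  ν₀ = γ,
    c_k = (4λγ/β)·ν_k/(ν_k² − γ²),  ν_k = 2πk/β,

with the truncated tail summarized by its Markovian weight
Δ = Σ_{k>K} c_k/ν_k (Ishizaki–Tanimura-style white-noise terminator; the
infinite sum is evaluated from the closed form of Σ 1/(k² − a²)).  The
imaginary part is exactly −λγe^{−γt} at any K and T.  The default
K = 10 is converged to better than 1e-5 relative against direct
quadrature for T ≥ 200 K and t ≥ 5 fs; when the HEOM participates in an
experiment cell, all three solvers share the (smaller) converged K of
the hierarchy plus terminator, so every method sees identical bath
statistics.

An independent quadrature oracle integrates the definition directly
(scipy `quad` with cos/sin weights) up to ω_max = 50·max(γ, k_BT/ħ) and
adds the analytic large-ω remainder of the Drude integrand in Si/Ci
functions.  At exactly t = 0 the real part of G is logarithmically
divergent for a Drude bath (the integrand decays only as 1/ω); the
quadrature value at t = 0 is therefore cutoff-regularized, and all
expansion-vs-quadrature comparisons are made for t ≥ 5 fs where both
representations are well defined.

## Solvers

All three propagators work on the vectorized density matrix in the
exciton basis and share the exciton-basis coupling matrix
S = U·V·Uᵀ.

**TC2 (time-nonlocal).**  With the exponential kernel, each convolution
term is replaced exactly by an auxiliary variable
A_k obeying dA_k/dt = −ν_k A_k − i[H, A_k] + c_k Sρ − c_k*ρS, giving a
linear time-invariant system of dimension 4(n_terms + 1).  The kernel
is constructed in the interaction picture and rotated back once; output
is Schrödinger-picture.  Because the extended generator is LTI, the
primary propagation route is exact matrix-exponential stepping (one
`expm` per unique grid step); this is preferred over an adaptive stiff
integrator because it is exact for the reduced system, deterministic
and byte-reproducible.  Two verification routes are provided: (i) the
Laplace-transform route — poles are the eigenvalues of the extended
generator, the inverse transform is the residue sum over the
eigendecomposition, with a logged, multiplicity-aware fallback for
near-degenerate poles — and (ii) a brute-force Volterra solver that
discretizes the memory integral directly with implicit-trapezoid
product integration.  The Volterra step defaults to 0.05 fs so its own
O(h²) discretization error (≈3e-7 over a 150 fs window at the dimer's
Bohr frequency) sits below the 1e-6 agreement it certifies.

**TL2 (time-local).**  Pulling ρ(t) out of the integral leaves the
coefficient matrix Σ(t)_{μν} = S_{μν}·(Σ_k c_k(1 − e^{−(ν_k+iΩ_{μν})t})
/(ν_k + iΩ_{μν}) + Δ) in closed form (series fallback below |z| = 1e-15);
no quadrature appears in propagation.  The generator is genuinely
time-dependent, so TL2 uses DOP853 with rtol 1e-10/atol 1e-12,
evaluating coefficients lazily at the integrator's internal points.
The imaginary (level-shift) parts of the coefficients are retained by
default; a `lamb_shift=False` switch drops them.  At J = 0 the equation
is exact and reproduces the analytic pure-dephasing law
|ρ₊₋(t)| ∝ exp(−(S₀₀−S₁₁)²∫₀^t∫₀^s Re G).

**HEOM (reference).**  Standard hierarchy over the K+1 exponential
modes, truncated at tier depth N_c, with scaled ADOs (stable beyond
depth ~6; no effect on tier-0 physics) and the same white-noise
terminator applied as −Δ[S,[S,·]] to every ADO.  Adiabatic elimination
of tier 1 recovers the TC2 kernel, which fixes all sign/factor
conventions consistently across solvers.  The generator is assembled
sparsely (ADO count C(N_c + K + 1, N_c), capped); propagation uses the
exact exponential action (`expm_multiply`), so the config carries no
integrator tolerances.

**Truncation search.**  `converge_heom` returns the smallest (depth, K)
such that one further step in either direction changes the probe
trajectory by less than `tol` (max absolute element deviation over a
0–800 fs grid, dt = 4 fs).  The probe is a pure state with both
population asymmetry and coherence so that population relaxation *and*
dephasing channels are exercised (a diagonal probe is blind to pure
dephasing).  Deviations are logged; hitting a cap raises an error
carrying the deviation history.  Experiment presets use tol = 1e-3,
which is an order of magnitude below every trajectory-level tolerance
used in the benchmark; the K direction converges slowly at much tighter
tolerances because the terminator residual decays only algebraically,
which is why deep-hierarchy exactness checks pin (depth, K) explicitly
instead of asking the search for 1e-6.

## Benchmark layer

The Choi state (Φ_t ⊗ I)(|Ψ⟩⟨Ψ|) is assembled as ½ΣΦ_t(|i⟩⟨j|) ⊗ |i⟩⟨j|
from the four matrix-unit propagations (the solvers accept non-Hermitian
initial data; a fallback reconstructs the cross units from four
Hermitian, unit-trace preparations for propagators that refuse).
TC2/TL2 are not guaranteed completely positive, so their Choi matrices
can have small negative eigenvalues; the Wootters spin-flip spectrum is
clamped at zero and a positivity-violation flag is raised beyond −1e-6
rather than rejecting the state — the benchmark is most informative
exactly where the approximations become unphysical.

The RHP-style measure N = 2·Σ max(0, ΔE − ε) is accumulated over the
fixed window [0, t_max] (default 800 fs, dt = 1 fs, matching the
plotted dynamics window; no optimization over initial states or
sub-intervals).  The noise threshold ε = 1e-6 per 1-fs increment
suppresses sub-resolution ripple so that genuinely monotone series
report exactly N = 0; it is configurable and echoed in every result.
N is stable to ~2% under grid refinement past 1 fs.

## Study conditions

The main parameter family is ω0 = 70, J = 100, γ = 50 cm⁻¹ with
T ∈ {200, 250, 300} K; the reduced-splitting study sets ω0 = 40 and the
slow-bath study additionally γ = 20 cm⁻¹, both at λ = 5 cm⁻¹.  Only
λ = 5 cm⁻¹ is fixed by the source material; the default λ grid
{5, 20, 50, 100} cm⁻¹ spans weak-to-intermediate coupling and is fully
configurable.  Qualitative large-λ regressions (population beating,
coherence over/under-estimation, measure orderings) are evaluated at
λ = 100 cm⁻¹ where the contrast is strongest; the HEOM
temperature-crossing check uses λ = 50 cm⁻¹ so that equilibrium is
reached inside the 800 fs window.  TL2's populations are strictly
monotone up to λ = 20 cm⁻¹ and develop a small late-time wobble
(positive variation ≲ 2% of TC2's beating) from λ ≈ 50 cm⁻¹, so the
monotonicity regression is asserted at the moderate couplings.  The
default initial state for population dynamics is |χ₊⟩⟨χ₊| (exciton
basis), configurable to the site state |1⟩⟨1|.

## Limitations

* Drude–Lorentz bath only; structured/vibronic spectral densities and
  underdamped modes are out of scope, as are multi-site aggregates.
* The white-noise terminator is accurate at 200–300 K; no
  low-temperature (< 100 K) validity engineering is attempted.
* The coupling-operator normalization is a documented convention
  (COUPLING_SCALE); under a different convention all λ values rescale
  globally, which changes quantitative deviations but none of the
  qualitative orderings.
* The measure uses concurrence only; the monotone-name field in
  MeasureResult leaves a hook for other entanglement monotones, and no
  trace-distance (state-pair-optimized) measure is provided.
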