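# qmebench

Benchmarking perturbative quantum master equations for excitonic energy
transfer in a photosynthetic dimer, using entanglement and an
entanglement-based non-Markovianity measure as the yardstick.

## The problem

Open-quantum-system dynamics of light-harvesting complexes is usually
computed with approximate quantum master equations (QMEs).  Two common
second-order, non-Markovian choices are

* **TC2** — the time-convolution (time-nonlocal) equation, where memory
  enters through a convolution with the kernel built from the bath
  correlation function G(t);
* **TL2** — the time-local (time-convolutionless) equation, where the
  same kernel is integrated into time-dependent coefficients.

For the spin-boson dimer with a Drude–Lorentz bath,

  H_sys = (ω0/2)σ_z + J·σ_x,  J(ω) = (2λγ/π)·ω/(ω² + γ²),

the **HEOM** (hierarchical equations of motion) is numerically exact and
serves as the reference.  `qmebench` implements all three propagators on
*bit-identical* bath statistics (a shared Drude + Matsubara exponential
expansion of G(t) with a white-noise terminator), so that differences
between trajectories are method error, not bath-representation error.

To compare methods without choosing a basis, the dynamical map Φ_t of
each solver is Choi-extended: the system starts maximally entangled with
an isolated ancilla, (Φ_t ⊗ I)(|Ψ⟩⟨Ψ|) is assembled from the four
propagated matrix units, and the Wootters concurrence E(t) is tracked.
Any rise of E(t) signals broken CP-divisibility; the RHP measure

  N = 2·Σ_t max(0, ΔE(t) − ε)

accumulates those rises over a fixed window (default 800 fs, ε = 1e-6).

## Worked example

Slow bath (γ = 20 cm⁻¹, so the bath correlation time 1/γ ≈ 265 fs is
long compared with the system timescale): information flows back from
the environment and *every* method shows finite non-Markovianity.

```python
import numpy as np
import qmebench as qb
from qmebench.experiments import make_propagator

model = qb.DimerModel(omega0=40, J=100, lam=5, gamma=20, T=200)
grid = np.arange(0.0, 801.0, 1.0)

cfg = qb.converge_heom(model, 1e-3)
print(f"converged HEOM truncation: depth={cfg.depth}, K={cfg.K}")

for solver in ("tc2", "heom", "tl2"):
    prop = make_propagator(solver, model, K=cfg.K, heom_config=cfg)
    ext = qb.choi_propagate(prop, grid)
    res = qb.measure_from_extended(ext, epsilon=1e-6)
    print(f"{solver:>4}: N = {res.N:.4f}  (positivity violated: {res.positivity_violated})")
```

prints

```
converged HEOM truncation: depth=5, K=0
 tc2: N = 0.0836  (positivity violated: False)
heom: N = 0.0471  (positivity violated: False)
 tl2: N = 0.0627  (positivity violated: False)
```

Reading: the exact dynamics is genuinely non-Markovian here
(N_HEOM > 0).  TC2 over-estimates the memory effect (its coherence
over-shoot produces extra concurrence revivals), while TL2 lands much
closer to the exact value — the pattern that makes the measure a useful
one-number benchmark of QME quality.  In the fast-bath regime
(γ = 50 cm⁻¹, ω0 = 70 cm⁻¹) the same pipeline gives N = 0 for HEOM and
TL2 at all temperatures, and for TC2 at weak coupling (λ = 5 cm⁻¹).

The figure-level studies are packaged as presets:

```bash
qmebench run --preset fig6 --out results/fig6
qmebench sweep --solver tc2 --lambda-cm 5 --lambda-cm 50 \
               --temp-k 200 --temp-k 300 --out results/sweep.csv
qmebench converge-heom --lambda-cm 100 --temp-k 300 --tol 1e-3
```

Each preset writes trajectory CSVs (17 significant digits), a measure
table and a JSON metadata record of every setting used, including the
self-certified HEOM truncation per parameter cell; identical
configurations produce byte-identical outputs.

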