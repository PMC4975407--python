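# ratebif

Analytic and numerical bifurcation analysis of **small two-population
firing-rate networks** — fully connected circuits of `N_E` excitatory and
`N_I` inhibitory neurons whose finite size gives them dynamics that
mean-field theory cannot see, most notably spontaneous symmetry breaking of
the inhibitory population under strong self-inhibition.

The package is aimed at computational neuroscientists studying mesoscopic
circuits (a few to a few tens of neurons): it provides closed-form local
bifurcation curves, equilibrium solvers that find symmetry-broken states, a
dynamics engine (oscillation frequencies, Lyapunov spectra, torus
detection), and heterogeneous-weight Jacobian spectra.

## Model

Each neuron's membrane potential obeys

```
dV_i/dt = -V_i/τ_i + (1/(N-1)) Σ_{j≠i} J_ij A_j(V_j) + I_i
```

with the algebraic sigmoid `A(V) = (ν_max/2) [1 + (Λ/2)(V-V_T) /
√(1 + (Λ/2)²(V-V_T)²)]`. Weights are homogeneous per block
(`J_EE, J_IE > 0`, `J_EI < 0`, `J_II ≤ 0`) with no self-connections, so the
equations are equivariant under the permutation group `S_NE × S_NI`.

On the homogeneous branch the Jacobian spectrum is closed-form: a mean-mode
pair `λ₀,₁ = (Y+Z ± √((Y-Z)²+4X))/2` plus degenerate difference modes
`λ_E` (× `N_E-1`) and `λ_I = -[1/τ_I + J_II/(N-1) A_I'(μ_I)]` (× `N_I-1`).
The inhibition-strength parameter

```
ψ = τ_I |J_II| ν_I^max Λ_I / (4(N-1))
```

splits the phase diagram: for `ψ < 1` (weak inhibition) `λ_I < 0` always and
equilibria stay homogeneous; for `ψ ≥ 1` the condition `λ_I = 0` defines
**branching points** (pitchforks) where the inhibitory potentials split and
secondary equilibrium branches emerge. Saddle-node (`X = YZ`), Hopf
(`Y+Z = 0`, `(Y-Z)²+4X < 0`), Bogdanov–Takens, branching-point and
zero-Hopf loci are all parameterized analytically, on the primary branch and
(for `N_I = 2`) on the secondary branches; every emitted point is
re-verified against a dense eigensolve of the full Jacobian.

## Worked example

```python
import numpy as np
from ratebif import (table1_params, psi, solve_primary, solve_secondary_ni2,
                     codim2_diagram, scan_torus)

# benchmark circuit: N_E = 8, N_I = 2, J_EE = 10, J_EI = -70, J_IE = 70
weak = table1_params(J_II=-10, I_I=-10)
print(psi(weak))                                   # 0.5556 -> weak regime
print(len(solve_primary(weak.with_inputs(I_E=10))))  # 1 equilibrium
print(len(solve_primary(weak.with_inputs(I_E=13))))  # 3 equilibria (bistable fold)

strong = table1_params(J_II=-100, I_I=-10, I_E=5)
for q in solve_secondary_ni2(strong):
    print(q.mu_E, q.mu_I_values, q.stable)
# 1.2493 (-5.0906, 2.3789)  True    <- symmetry-broken swap pair, stable
# 1.2493 (2.3789, -5.0906)  True
# 1.4272 (1.6979,)          False   <- homogeneous state, unstable

diag = codim2_diagram(strong, n=200)
print(diag.verification_summary())
# every LP/H/BP/secondary sample and BT/ZH point passes the dense
# eigenvalue check, e.g. {'LP_primary': (400, 400), 'BP': (274, 274), ...}

onset, _ = scan_torus(table1_params(J_II=-100, I_I=-16),
                      np.arange(11.70, 11.92, 0.02))
print(onset)                                       # 11.80 -> torus onset
```

The torus onset means: below `I_E ≈ 11.80` the symmetry-broken attractor is
a limit cycle; above it, the cycle's peak amplitudes become modulated at an
incommensurate second frequency (quasi-periodic motion on a torus).

Frequencies are reported in Hz under an explicit time convention (default:
one model time unit = 10 ms, i.e. a 10 ms membrane time constant). For the
weak-inhibition circuit at `I_I = -13.3` the simulated oscillation
frequencies at `I_E = 0.216, 5.564, 11.85` come out at **34.9, 161.2 and
19.3 Hz** respectively — gamma-band oscillations that slow dramatically
near the homoclinic loop.

## Command line

```
ratebif equilibria --j-ii -100 --i-e 5 --i-i -10 --out run/
ratebif codim2 --j-ii -34 --plot --out run/
ratebif codim1 --j-ii -100 --i-i -10 --i-e-min 0.5 --i-e-max 2 --out run/
ratebif simulate --j-ii -10 --i-e 0.216 --i-i -13.3 --out run/
ratebif spectrum --sd-ee 1 --seed 0 --out run/
ratebif fixtures --out fixtures/
```

Each run writes CSV/JSON outputs plus a manifest with the fully resolved
configuration, so results are reproducible from the manifest alone.

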