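# Methods

## Model and assumptions

The package analyses a deterministic firing-rate network of `N = N_E + N_I`
neurons, fully connected without self-connections, with homogeneous
parameters within each population. Potentials evolve as
`dV_i/dt = -V_i/τ_i + (1/(N-1)) Σ_{j≠i} J_ij A_j(V_j) + I_i` with the
algebraic sigmoid activation. The `1/(N-1)` normalization matches the
number of presynaptic partners; `renormalize_weights` converts exactly to
the per-population-size convention `J_ab → (N-1)/N_b · J_ab` and back.
Axonal delays and noise are outside scope.

Key consequences exploited throughout:

* **Equivariance.** The equations are invariant under `S_NE × S_NI` index
  permutations, so the Jacobian at homogeneous (or clustered) states is a
  block matrix whose difference-mode eigenvalues are closed-form. The
  homogeneous subspace is flow-invariant: exact symmetry never breaks in a
  simulation, which is why symmetry-breaking protocols start from
  deterministically desymmetrized initial conditions (offsets of order
  1e-6–1e-3). Note also the converse pitfall: an offset that contracts
  below machine epsilon makes the trajectories bitwise identical forever,
  so ramp protocols should start near — not far below — the branching
  point they are meant to cross.
* **Boundedness.** Since `0 < A < ν_max`, every trajectory is ultimately
  confined to `|V| ≤ τ (Σ|J| ν_max + |I|)`; `potential_bound` returns this
  box and the equilibrium searches use a tighter activation-sensitive box
  `V_T ± 8/Λ` per variable (the sigmoid saturates well inside it), which is
  configurable.

## Analytic bifurcation structure

On the primary branch the spectrum is the mean-mode pair built from
`X, Y, Z` plus `λ_E` and `λ_I` with multiplicities `N_E-1`, `N_I-1`. The
curve parameterizations follow one pattern: fix the defining eigenvalue
condition, solve it for one activation slope as a function of the parameter
potential `v`, invert the slope (two potentials, symmetric about `V_T` —
both signs are always enumerated and filtered by feasibility), and read the
currents off the stationarity equations.

* **LP (saddle-node):** `X = YZ` gives `A_I'(μ_I)` as a rational function
  of `A_E'(v)`; the domain endpoints are where the required excitatory
  slope reaches its maximum. The curve is empty when
  `(N_E-1)/(N-1) J_EE ν_E Λ_E τ_E/4 ≤ 1` (excitation too weak to fold).
* **H (Hopf):** `Y + Z = 0` with negative discriminant. The two feasible
  windows of `v` end at the Bogdanov–Takens potentials, where the
  discriminant vanishes; samples with angular frequency below 2e-5 are
  excluded so that every emitted H point has a genuinely complex pair.
  The curve approaches BT with a square-root cusp in the parameterization,
  so membership of BT on the H curve is checked in the limit, not by
  nearest sampled point.
* **BP (branching point):** `λ_I = 0` fixes
  `μ_I = V_T ± (2/Λ_I)√(ψ^{2/3}-1)` (defined only for `ψ ≥ 1`); the
  excitatory potential follows from the inhibitory stationarity equation by
  inverting the monotone activation — a single-valued inverse, feasible
  when the required rate lies in `(0, ν_max)` — giving explicit curves
  `I_E = F_±(I_I)`. Infeasible ranges are reported as separate labeled
  segments, never bridged.
* **ZH (zero-Hopf):** both slope conditions are solved and all four sign
  combinations enumerated; combinations with a real mean-mode pair are
  discarded. Retained points lie on the BP curve by construction.
* **Secondary branches (`N_I = 2`):** the pair relation
  `φ(μ_I,0) = φ(μ_I,1)` with `φ(x) = x/τ_I + J_II/(N-1) A_I(x)` supplies
  the partner potential. Squaring the centered relation yields a quartic,
  expanded here by exact polynomial arithmetic; spurious roots (artifacts
  of squaring) are discarded when their residual in the unsquared relation
  exceeds 1e-8, and retained roots are polished by bisection. The LP
  condition fixes `A_E'` as a ratio of quadratics in the two inhibitory
  slopes; the H condition is a quadratic in `A_E'` (both roots tried).
  The H trace condition is also met by neutral saddles (a real ± pair), so
  candidates without a genuinely complex pure-imaginary pair are dropped.
  The feasible parameter window is found by scanning `v = μ_I,0` over the
  fold window of `φ` (bracketed from its turning points, which are the BP
  potentials) — the window is not available in closed form.
* **Cusps:** located on sampled curves where the tangent speed collapses
  and the tangent orientation reverses; this is a numerical detector, no
  closed form is attempted. Hopf criticality (super- vs subcritical) and
  generalized-Hopf points are likewise not computed analytically.

**Universal verification.** Every curve sample and codim-2 point is checked
against a dense eigensolve of the full `N × N` Jacobian at its equilibrium:
zero eigenvalue within 1e-6 for LP/BP, a conjugate pair with |Re| < 1e-6
for H, both for ZH, a double near-zero for BT. Diagrams carry per-kind
verification counts.

**Clustered spectra.** When the inhibitory population splits into clusters
of sizes `(P, Q, ...)`, each cluster of size `P` at potential `μ`
contributes the eigenvalue `-[1/τ_I + J_II/(N-1) A_I'(μ)]` with
multiplicity `P - 1` (its own within-cluster difference modes — verified
against the dense solver; both labeling conventions coincide for
`N_I = 2`). The remaining mean-mode eigenvalues are obtained by deflating
the known degenerate values out of a dense eigensolve rather than from a
reduced characteristic polynomial, which is only partially specified for
general partitions.

## Equilibrium solvers

`solve_primary` and `solve_secondary_ni2` run multi-start Newton (scipy
`hybr`) from a deterministic lattice over the activation-sensitive box,
keep roots with residual below 1e-10, and deduplicate at 1e-6.
`branch_continuation` sweeps `I_E` at a fixed step, re-running the
multi-start solver at every step (warm-started natural-parameter stepping
would miss branch births at pitchforks), links solutions between steps by
proximity, and refines events — `λ_I` sign changes (BP), mean-mode
real-part sign changes with a complex pair (H), and solution-count changes
(LP folds) — by bisection/Brent in `I_E` to 1e-6. Crossings that fall
exactly on a sweep grid point are returned directly when the tracked
eigenvalue is zero to 1e-9.

## Dynamics

Two integrator backends: adaptive `solve_ivp` (default RK45, rtol 1e-9 /
atol 1e-11) honoring local-error tolerances, and a compiled fixed-step RK4
kernel (numba, default dt = 0.002 model units) used for long scans; they
agree to ~1e-8 on benchmark trajectories, and the RK4 step is a few
hundredths of the fastest oscillation period.

* **Time units.** The equations are dimensionless with `τ = 1`. Hz values
  use one model time unit = 10 ms (a 10 ms membrane time constant) by
  default — the convention under which the benchmark circuit's oscillation
  periods (≈2.9, 0.62 and 5.2 model units) map to ≈35, 160 and 19 Hz. The
  convention is a single configurable factor stamped into every signature.
* **Frequency.** Dominant frequency from parabola-refined peak intervals of
  the mean excitatory potential after discarding a transient (default the
  first half of the window; the benchmark runs use 8000 model units and
  discard 75%, since the 160 Hz case approaches its cycle slowly), with a
  windowed-FFT spectral peak as cross-check.
* **Torus classification.** A limit cycle has numerically constant refined
  peak heights (relative spread < 1e-4). When the heights are modulated,
  the per-cycle modulation frequency (a rotation-number proxy, from the
  FFT of the peak-height sequence) is tested for irrationality by
  continued fractions: no rational approximation within 1e-3 with
  denominator ≤ 12, with at least three full modulation cycles observed,
  classifies the attractor quasi-periodic. Phase-locked period-k cycles
  give small denominators and stay limit cycles. `scan_torus` continues
  the attractor through the current sweep (each point starts from the
  previous endpoint) with 3000 model units of settling and 2000 of
  measurement per point; the benchmark scan uses a 0.02-current grid over
  the upper stable-cycle window.
* **Lyapunov exponents.** Benettin tangent-space method: state and k
  orthonormal tangent vectors advanced jointly by the compiled RK4 kernel,
  QR re-orthonormalization every 1 time unit, exponents from the
  accumulated log of the R diagonal; convergence compares running averages
  over the last half and the full horizon (defaults: 500–2000 units of
  transient, 1500–2000 of accumulation).
* **Symmetry-breaking detection.** Per-sample clustering of the sorted
  inhibitory potentials at a gap tolerance (default 1e-3), reporting the
  per-time cluster count, first split time, and final partition.

## Heterogeneous weights

`sample_heterogeneous_weights` draws i.i.d. Gaussian entries per block
(self-connections stay zero; zero standard deviation reproduces the
homogeneous matrix exactly). Spectra are computed at the homogeneous
equilibrium of the *mean* system, which isolates the effect of weight
disorder on the eigenvalues. The degenerate `λ_E`, `λ_I` split into
`N_E-1` and `N_I-1` simple eigenvalues around the unperturbed positions;
the predicted cloud radius defaults to `√N_α σ A'(μ̄_α)/(N-1)` (the
Ginibre scale of the fluctuation block) and is pluggable, validated by
containment fraction and linear-in-σ scaling rather than bit-exactly.

## Synthetic study conditions

All benchmark computations use the canonical parameter set (`N_E = 8`,
`N_I = 2`, `J_EE = 10`, `J_EI = -70`, `J_IE = 70`, `τ = ν_max = 1`,
`Λ = V_T = 2`) with `J_II` and the currents as bifurcation parameters;
`J_II = -10` exemplifies the weak regime and `-34`/`-100` the strong one.
These are idealized circuits — homogeneous parameters, full connectivity,
no delays or noise — so passing tests demonstrate correctness of the
analysis machinery on this model class, not robustness to the
heterogeneity, sparseness or stochasticity of biological recordings (the
heterogeneous-weight module probes only the first of those).

## Known limitations

* Global bifurcations (homoclinic loops, limit points of cycles, SNIC,
  cusps of cycles) are not continued; they require dedicated continuation
  machinery and appear here only indirectly (e.g. the slowing oscillation
  near a homoclinic).
* Secondary-branch formulas hold for `N_I = 2`; for larger inhibitory
  populations the cluster eigenvalues are exact but the remaining spectrum
  comes from the dense fallback, and secondary-branch *solving* beyond the
  two-cluster ansatz is out of scope.
* The torus classifier cannot distinguish a genuine irrational rotation
  number from a phase lock of very high order (> 12); near the onset this
  is immaterial at the scan resolution used.
* Non-degeneracy conditions of bifurcation theory (beyond the eigenvalue
  conditions) are not checked.
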