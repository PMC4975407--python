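"""Explicit symmetry breaking by heterogeneous synaptic weights.

Replacing each weight block by i.i.d. Gaussian entries
``J_ab ~ N(mean_ab, sd_ab^2)`` breaks the permutation symmetry explicitly
and lifts the degeneracy of the difference-mode eigenvalues: the
``N_E - 1``-fold ``lambda_E`` and ``N_I - 1``-fold ``lambda_I`` split into
clouds of simple eigenvalues, distributed (for small sd) according to a
circular law around the unperturbed values — a block-structured
generalization of Girko's law for the Jacobian
``-diag(1/tau) + W diag(A'(mu)) / (N-1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibria import solve_primary
from .model import activation_deriv
from .params import NetworkParams

__all__ = [
    "HeterogeneousWeights",
    "sample_heterogeneous_weights",
    "heterogeneous_spectrum",
    "default_cloud_radius",
    "circular_law_check",
]


@dataclass(frozen=True)
class HeterogeneousWeights:
    """A sampled N x N weight matrix with its block statistics."""

    W: np.ndarray
    means: dict[str, float]
    sds: dict[str, float]
    seed: int


def sample_heterogeneous_weights(params: NetworkParams,
                                 means: dict[str, float] | None = None,
                                 sds: dict[str, float] | None = None,
                                 seed: int = 0) -> HeterogeneousWeights:
    """Sample i.i.d. normal weights per block; self-connections stay zero.

    ``means`` defaults to the homogeneous weights in ``params``; ``sds``
    (keys ``"EE", "EI", "IE", "II"``) default to zero, which reproduces the
    homogeneous matrix exactly.
    """
    if means is None:
        means = {"EE": params.J_EE, "EI": params.J_EI,
                 "IE": params.J_IE, "II": params.J_II}
    sds = {"EE": 0.0, "EI": 0.0, "IE": 0.0, "II": 0.0} | (sds or {})
    if any(v < 0 for v in sds.values()):
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    NE, NI = params.N_E, params.N_I
    W = np.empty((params.N, params.N))
    W[:NE, :NE] = rng.normal(means["EE"], sds["EE"], (NE, NE))
    W[:NE, NE:] = rng.normal(means["EI"], sds["EI"], (NE, NI))
    W[NE:, :NE] = rng.normal(means["IE"], sds["IE"], (NI, NE))
    W[NE:, NE:] = rng.normal(means["II"], sds["II"], (NI, NI))
    W[:NE, :NE][np.diag_indices(NE)] = 0.0
    W[NE:, NE:][np.diag_indices(NI)] = 0.0
    return HeterogeneousWeights(W=W, means=dict(means), sds=dict(sds), seed=seed)


def _mean_equilibrium(params: NetworkParams, means: dict[str, float]):
    """Homogeneous equilibrium of the mean system (mean weights)."""
    p = params.replace(J_EE=means["EE"], J_EI=means["EI"],
                       J_IE=means["IE"], J_II=means["II"])
    eqs = solve_primary(p, n_grid=15)
    if not eqs:
        raise RuntimeError("no equilibrium of the mean system found")
    # linearize around the most stable point (max real part smallest)
    eq = min(eqs, key=lambda q: q.max_real_eigenvalue)
    return eq.mu_E, eq.mu_I


def heterogeneous_spectrum(weights: HeterogeneousWeights,
                           params: NetworkParams,
                           mu: tuple[float, float] | None = None) -> np.ndarray:
    """Jacobian eigenvalues with sampled weights at the mean-system equilibrium.

    The linearization point ``(mu_E, mu_I)`` is the homogeneous equilibrium
    of the system with the block-mean weights (computed if not supplied);
    the Jacobian then uses the sampled matrix.
    """
    if mu is None:
        mu = _mean_equilibrium(params, weights.means)
    mu_E, mu_I = mu
    slopes = np.concatenate([
        np.full(params.N_E, float(activation_deriv(mu_E, params.E))),
        np.full(params.N_I, float(activation_deriv(mu_I, params.I))),
    ])
    J = weights.W * (slopes / params.M)[None, :]
    J[np.diag_indices_from(J)] -= 1.0 / params.tau_vector()
    return np.linalg.eigvals(J)


def default_cloud_radius(N_alpha: int, N: int, sd: float, slope: float) -> float:
    """Predicted radius of a split difference-mode eigenvalue cloud.

    The fluctuation part of a within-population Jacobian block is an
    ``N_alpha``-dimensional Ginibre-like matrix with entry standard
    deviation ``sd * slope / (N-1)``, whose circular-law support has radius
    ``sqrt(N_alpha) * sd * slope / (N-1)``.
    """
    return np.sqrt(N_alpha) * sd * slope / (N - 1)


def circular_law_check(params: NetworkParams,
                       means: dict[str, float] | None = None,
                       sds: dict[str, float] | None = None,
                       N_values=(10, 50, 200), replicates: int = 3,
                       seed: int = 0, radius_fn=default_cloud_radius,
                       radius_margin: float = 1.3) -> dict:
    """Containment of the split eigenvalue clouds in the predicted discs.

    For each total size ``N`` (keeping the 4:1 excitatory/inhibitory ratio
    of ``params``), samples ``replicates`` weight matrices, computes the
    Jacobian spectrum at the mean-system equilibrium, identifies the
    ``(N_E - 1) + (N_I - 1)`` difference-mode eigenvalues as those nearest
    the unperturbed cluster centers, and reports the fraction inside discs
    of ``radius_margin`` times the predicted radius.  ``radius_fn`` is
    pluggable; the default is :func:`default_cloud_radius`.
    """
    ratio = params.N_E / params.N_I
    report: dict = {"N": [], "containment": [], "radius_E": [], "radius_I": []}
    rng = np.random.default_rng(seed)
    for N in N_values:
        NI = max(2, int(round(N / (1 + ratio))))
        NE = N - NI
        p = params.replace(E=params.E.__class__(
            size=NE, tau=params.E.tau, nu_max=params.E.nu_max,
            Lambda=params.E.Lambda, V_T=params.E.V_T),
            I=params.I.__class__(
            size=NI, tau=params.I.tau, nu_max=params.I.nu_max,
            Lambda=params.I.Lambda, V_T=params.I.V_T))
        m = means or {"EE": p.J_EE, "EI": p.J_EI, "IE": p.J_IE, "II": p.J_II}
        mu_E, mu_I = _mean_equilibrium(p, m)
        sE = float(activation_deriv(mu_E, p.E))
        sI = float(activation_deriv(mu_I, p.I))
        cE = -(1.0 / p.E.tau + m["EE"] / p.M * sE)
        cI = -(1.0 / p.I.tau + m["II"] / p.M * sI)
        sd = {"EE": 0.0, "EI": 0.0, "IE": 0.0, "II": 0.0} | (sds or {})
        rE = radius_fn(NE, p.N, sd["EE"], sE)
        rI = radius_fn(NI, p.N, sd["II"], sI)
        inside = total = 0
        for _ in range(replicates):
            w = sample_heterogeneous_weights(
                p, m, sd, seed=int(rng.integers(2 ** 31 - 1)))
            lam = heterogeneous_spectrum(w, p, mu=(mu_E, mu_I))
            # difference-mode eigenvalues: nearest NE-1 to cE, NI-1 to cI
            dE = np.abs(lam - cE)
            idxE = np.argsort(dE)[:NE - 1]
            rest = np.delete(lam, idxE)
            dI = np.abs(rest - cI)
            idxI = np.argsort(dI)[:NI - 1]
            inside += int(np.sum(dE[idxE] <= radius_margin * max(rE, 1e-12)))
            inside += int(np.sum(dI[idxI] <= radius_margin * max(rI, 1e-12)))
            total += (NE - 1) + (NI - 1)
        report["N"].append(int(N))
        report["containment"].append(inside / total if total else 1.0)
        report["radius_E"].append(float(rE))
        report["radius_I"].append(float(rI))
    return report
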