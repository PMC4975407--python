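r"""Right-hand side, activation function, and structured Jacobian spectra.

The membrane potential of neuron :math:`i` obeys

.. math::

    \dot V_i = -\frac{V_i}{\tau_i}
        + \frac{1}{N-1}\sum_{j \ne i} J_{ij}\,A_j(V_j) + I_i,

with the algebraic sigmoid activation

.. math::

    A(V) = \frac{\nu^{max}}{2}\left[1 +
        \frac{(\Lambda/2)(V - V^T)}{\sqrt{1 + (\Lambda/2)^2 (V - V^T)^2}}\right].

On the homogeneous (primary) equilibrium branch the Jacobian has a fully
degenerate block structure whose eigenvalues are available in closed form:
a pair :math:`\lambda_{0,1} = (Y+Z \pm \sqrt{(Y-Z)^2 + 4X})/2` plus

.. math::

    \lambda_E = -\Big[\frac{1}{\tau_E} + \frac{J_{EE}}{N-1}A_E'(\mu_E)\Big]
    \quad (\times\, N_E - 1), \qquad
    \lambda_I = -\Big[\frac{1}{\tau_I} + \frac{J_{II}}{N-1}A_I'(\mu_I)\Big]
    \quad (\times\, N_I - 1),

where

.. math::

    X = \frac{N_E N_I}{(N-1)^2} J_{EI} J_{IE} A_E'(\mu_E) A_I'(\mu_I),\quad
    Y = -\frac{1}{\tau_E} + \frac{N_E-1}{N-1} J_{EE} A_E'(\mu_E),\quad
    Z = -\frac{1}{\tau_I} + \frac{N_I-1}{N-1} J_{II} A_I'(\mu_I).

The degenerate eigenvalues :math:`\lambda_{E,I}` belong to within-population
difference modes; :math:`\lambda_I = 0` is the branching-point (pitchfork)
condition through which inhibitory symmetry breaking occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .params import NetworkParams, PopulationParams

__all__ = [
    "activation",
    "activation_deriv",
    "inverse_activation",
    "inverse_activation_deriv",
    "rhs",
    "jacobian_full",
    "PrimaryEigenData",
    "eigenvalues_primary",
    "ClusterPartition",
    "eigenvalues_clustered",
    "primary_state",
]


# ---------------------------------------------------------------------------
# activation function
# ---------------------------------------------------------------------------

def activation(V, pop: PopulationParams):
    """Algebraic sigmoid firing rate, strictly increasing from 0 to ``nu_max``."""
    x = (pop.Lambda / 2.0) * (np.asarray(V, dtype=float) - pop.V_T)
    return pop.nu_max / 2.0 * (1.0 + x / np.sqrt(1.0 + x * x))


def activation_deriv(V, pop: PopulationParams):
    """Slope of the activation; maximal value ``nu_max*Lambda/4`` at ``V_T``."""
    x = (pop.Lambda / 2.0) * (np.asarray(V, dtype=float) - pop.V_T)
    return pop.max_slope * (1.0 + x * x) ** -1.5


def inverse_activation(rate, pop: PopulationParams):
    """Unique potential with ``activation(V) = rate``; requires 0 < rate < nu_max."""
    r = np.asarray(rate, dtype=float)
    if np.any(r <= 0.0) or np.any(r >= pop.nu_max):
        raise ValueError("rate must lie strictly inside (0, nu_max)")
    w = 2.0 * r / pop.nu_max - 1.0
    return pop.V_T + (2.0 / pop.Lambda) * w / np.sqrt(1.0 - w * w)


def inverse_activation_deriv(s: float, pop: PopulationParams) -> tuple[float, float]:
    r"""The two potentials at which the activation slope equals ``s``.

    Inverts ``activation_deriv``:

    .. math:: V = V^T \pm \frac{2}{\Lambda}
        \sqrt{\left(\frac{\nu^{max}\Lambda}{4 s}\right)^{2/3} - 1}

    Both returned values (lower, upper) satisfy ``activation_deriv(V) == s``;
    they coincide at ``V_T`` when ``s`` equals the maximum slope.
    """
    if not (0.0 < s <= pop.max_slope):
        raise ValueError(
            f"slope must be in (0, {pop.max_slope}], got {s}"
        )
    d = (2.0 / pop.Lambda) * np.sqrt(max((pop.max_slope / s) ** (2.0 / 3.0) - 1.0, 0.0))
    return pop.V_T - d, pop.V_T + d


# ---------------------------------------------------------------------------
# vector field and Jacobian
# ---------------------------------------------------------------------------

def _activation_all(V: np.ndarray, params: NetworkParams) -> np.ndarray:
    NE = params.N_E
    out = np.empty_like(V)
    out[:NE] = activation(V[:NE], params.E)
    out[NE:] = activation(V[NE:], params.I)
    return out


def _activation_deriv_all(V: np.ndarray, params: NetworkParams) -> np.ndarray:
    NE = params.N_E
    out = np.empty_like(V)
    out[:NE] = activation_deriv(V[:NE], params.E)
    out[NE:] = activation_deriv(V[NE:], params.I)
    return out


def rhs(state: Sequence[float], params: NetworkParams,
        W: np.ndarray | None = None,
        I_ext: np.ndarray | None = None) -> np.ndarray:
    """Time derivative of the membrane potentials.

    Parameters
    ----------
    state : array-like, shape (N,)
        Membrane potentials, excitatory first.
    W : ndarray, optional
        Precomputed weight matrix (``params.weight_matrix()``); passing it
        avoids reallocation in tight integration loops.
    I_ext : ndarray, optional
        External current vector overriding the one in ``params`` (used by
        ramp protocols).
    """
    V = np.asarray(state, dtype=float)
    if V.shape != (params.N,):
        raise ValueError(f"state must have shape ({params.N},), got {V.shape}")
    if W is None:
        W = params.weight_matrix()
    if I_ext is None:
        I_ext = params.input_vector()
    return -V / params.tau_vector() + (W @ _activation_all(V, params)) / params.M + I_ext


def jacobian_full(state: Sequence[float], params: NetworkParams,
                  W: np.ndarray | None = None) -> np.ndarray:
    """Dense Jacobian of :func:`rhs` at an arbitrary state.

    ``J = -diag(1/tau) + W diag(A'(V)) / (N-1)``; at homogeneous states this
    reduces to the two-block primary-branch structure, and at two-cluster
    inhibitory states to the three-block secondary-branch structure.
    """
    V = np.asarray(state, dtype=float)
    if V.shape != (params.N,):
        raise ValueError(f"state must have shape ({params.N},), got {V.shape}")
    if W is None:
        W = params.weight_matrix()
    J = W * (_activation_deriv_all(V, params) / params.M)[None, :]
    J[np.diag_indices_from(J)] -= 1.0 / params.tau_vector()
    return J


def primary_state(mu_E: float, mu_I: float, params: NetworkParams) -> np.ndarray:
    """Replicate population potentials into a full homogeneous state vector."""
    return np.concatenate(
        [np.full(params.N_E, mu_E), np.full(params.N_I, mu_I)]
    )


# ---------------------------------------------------------------------------
# closed-form spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimaryEigenData:
    """Closed-form Jacobian spectrum on the homogeneous branch.

    ``lambda01`` is the mean-mode pair (complex when the discriminant
    ``(Y-Z)^2 + 4X`` is negative); ``lambda_E`` and ``lambda_I`` are the
    degenerate difference-mode eigenvalues with multiplicities ``N_E - 1``
    and ``N_I - 1``.  The discriminant is stored explicitly so that Hopf
    detection is a sign decision on a real number.
    """

    lambda01: tuple[complex, complex]
    lambda_E: float
    lambda_I: float
    mult_E: int
    mult_I: int
    X: float
    Y: float
    Z: float
    discriminant: float

    def multiset(self) -> np.ndarray:
        """All N eigenvalues as a complex array (with multiplicities)."""
        return np.concatenate([
            np.asarray(self.lambda01, dtype=complex),
            np.full(self.mult_E, self.lambda_E, dtype=complex),
            np.full(self.mult_I, self.lambda_I, dtype=complex),
        ])

    @property
    def max_real(self) -> float:
        return float(np.max(self.multiset().real))


def eigenvalues_primary(mu_E: float, mu_I: float,
                        params: NetworkParams) -> PrimaryEigenData:
    """Closed-form eigenvalues of the Jacobian at a homogeneous state."""
    NE, NI, M = params.N_E, params.N_I, params.M
    sE = float(activation_deriv(mu_E, params.E))
    sI = float(activation_deriv(mu_I, params.I))
    X = NE * NI / M**2 * params.J_EI * params.J_IE * sE * sI
    Y = -1.0 / params.E.tau + (NE - 1) / M * params.J_EE * sE
    Z = -1.0 / params.I.tau + (NI - 1) / M * params.J_II * sI
    disc = (Y - Z) ** 2 + 4.0 * X
    sq = np.sqrt(complex(disc))
    lam0 = (Y + Z + sq) / 2.0
    lam1 = (Y + Z - sq) / 2.0
    if disc >= 0.0:
        lam0, lam1 = complex(lam0.real), complex(lam1.real)
    lamE = -(1.0 / params.E.tau + params.J_EE / M * sE)
    lamI = -(1.0 / params.I.tau + params.J_II / M * sI)
    return PrimaryEigenData(
        lambda01=(lam0, lam1), lambda_E=lamE, lambda_I=lamI,
        mult_E=NE - 1, mult_I=NI - 1, X=X, Y=Y, Z=Z, discriminant=disc,
    )


@dataclass(frozen=True)
class ClusterPartition:
    """Partition of the inhibitory population into same-potential clusters.

    ``clusters`` is an ordered list of ``(size, potential)`` pairs whose
    sizes sum to ``N_I``.  A single cluster is the homogeneous (primary)
    configuration; two clusters are the generic symmetry-broken state.
    """

    clusters: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if not self.clusters or any(int(s) < 1 for s, _ in self.clusters):
            raise ValueError("cluster sizes must be positive integers")

    @property
    def n_total(self) -> int:
        return int(sum(s for s, _ in self.clusters))

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(int(s) for s, _ in self.clusters)

    @property
    def potentials(self) -> tuple[float, ...]:
        return tuple(float(v) for _, v in self.clusters)

    def expand(self) -> np.ndarray:
        """Inhibitory potential vector with cluster members contiguous."""
        return np.concatenate([
            np.full(int(s), float(v)) for s, v in self.clusters
        ])


def eigenvalues_clustered(partition: ClusterPartition, mu_E: float,
                          params: NetworkParams) -> np.ndarray:
    """Jacobian eigenvalues at a clustered inhibitory state.

    The within-cluster difference modes contribute, for each inhibitory
    cluster of size ``P`` at potential ``mu``, the eigenvalue
    ``-[1/tau_I + J_II/(N-1) A_I'(mu)]`` with multiplicity ``P - 1``, and the
    excitatory difference modes contribute ``lambda_E`` with multiplicity
    ``N_E - 1``.  The remaining ``1 + n_clusters`` mean-mode eigenvalues come
    from a dense eigensolve of the full Jacobian with the degenerate values
    deflated out.

    Returns the complete complex eigenvalue multiset (length N).
    """
    if partition.n_total != params.N_I:
        raise ValueError(
            f"partition sizes sum to {partition.n_total}, expected {params.N_I}"
        )
    M = params.M
    state = np.concatenate([np.full(params.N_E, mu_E), partition.expand()])
    dense = np.linalg.eigvals(jacobian_full(state, params))

    lamE = -(1.0 / params.E.tau + params.J_EE / M * float(activation_deriv(mu_E, params.E)))
    known: list[float] = [lamE] * (params.N_E - 1)
    for size, mu in partition.clusters:
        lam = -(1.0 / params.I.tau + params.J_II / M * float(activation_deriv(mu, params.I)))
        known.extend([lam] * (int(size) - 1))

    # deflate the analytically known degenerate eigenvalues out of the dense
    # spectrum; what is left are the mean-mode eigenvalues
    remaining = list(dense)
    for lam in known:
        k = int(np.argmin(np.abs(np.asarray(remaining) - lam)))
        remaining.pop(k)
    return np.concatenate([np.asarray(known, dtype=complex),
                           np.asarray(remaining, dtype=complex)])
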