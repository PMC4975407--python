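"""Network parameterization for two-population excitatory/inhibitory rate circuits.

The model is a fully connected network of :math:`N = N_E + N_I` firing-rate
neurons without self-connections.  Neurons within a population share all
parameters, so the network is invariant under within-population index
permutations.  Excitatory neurons occupy indices ``0 .. N_E-1``, inhibitory
neurons ``N_E .. N-1``.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "PopulationParams",
    "NetworkParams",
    "psi",
    "renormalize_weights",
    "table1_params",
    "load_params",
    "save_params",
]


@dataclass(frozen=True)
class PopulationParams:
    """Homogeneous parameters of one neural population.

    Attributes
    ----------
    size : int
        Number of neurons in the population (at least 2).
    tau : float
        Membrane time constant, in model time units.
    nu_max : float
        Maximum firing rate of the sigmoidal activation.
    Lambda : float
        Slope parameter of the activation function.
    V_T : float
        Firing-threshold potential (horizontal shift of the activation).
    """

    size: int
    tau: float = 1.0
    nu_max: float = 1.0
    Lambda: float = 2.0
    V_T: float = 2.0

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError(f"population size must be >= 2, got {self.size}")
        for name in ("tau", "nu_max", "Lambda"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def max_slope(self) -> float:
        """Largest attainable activation slope, ``nu_max * Lambda / 4``."""
        return self.nu_max * self.Lambda / 4.0


@dataclass(frozen=True)
class NetworkParams:
    """Full parameterization of the two-population network.

    Synaptic weights are population-level scalars: ``J_EE, J_IE > 0``
    (excitation), ``J_EI < 0`` and ``J_II <= 0`` (inhibition).  The synaptic
    input of every neuron is normalized by ``M = N - 1``, the number of its
    presynaptic partners in the fully connected topology without
    self-connections.
    """

    E: PopulationParams
    I: PopulationParams
    J_EE: float = 10.0
    J_EI: float = -70.0
    J_IE: float = 70.0
    J_II: float = -10.0
    I_E: float = 0.0
    I_I: float = 0.0

    def __post_init__(self) -> None:
        if self.J_EE <= 0 or self.J_IE <= 0:
            raise ValueError("J_EE and J_IE must be positive (excitatory)")
        if self.J_EI >= 0 or self.J_II > 0:
            raise ValueError("J_EI must be negative and J_II non-positive")

    # -- derived sizes -------------------------------------------------
    @property
    def N_E(self) -> int:
        return self.E.size

    @property
    def N_I(self) -> int:
        return self.I.size

    @property
    def N(self) -> int:
        return self.E.size + self.I.size

    @property
    def M(self) -> int:
        """Synaptic normalization factor ``N - 1``."""
        return self.N - 1

    def with_inputs(self, I_E: float | None = None, I_I: float | None = None) -> "NetworkParams":
        """Return a copy with the external currents replaced."""
        kw = {}
        if I_E is not None:
            kw["I_E"] = float(I_E)
        if I_I is not None:
            kw["I_I"] = float(I_I)
        return dataclasses.replace(self, **kw)

    def replace(self, **kwargs) -> "NetworkParams":
        """Return a copy with arbitrary top-level or weight fields replaced."""
        return dataclasses.replace(self, **kwargs)

    def weight_matrix(self) -> np.ndarray:
        """Dense ``N x N`` synaptic weight matrix (not yet divided by ``N-1``).

        Within-population blocks have zero diagonals (no self-connections).
        """
        NE, NI = self.N_E, self.N_I
        W = np.empty((self.N, self.N))
        W[:NE, :NE] = self.J_EE * (1.0 - np.eye(NE))
        W[:NE, NE:] = self.J_EI
        W[NE:, :NE] = self.J_IE
        W[NE:, NE:] = self.J_II * (1.0 - np.eye(NI))
        return W

    def input_vector(self) -> np.ndarray:
        """Length-``N`` vector of external currents."""
        return np.concatenate(
            [np.full(self.N_E, self.I_E), np.full(self.N_I, self.I_I)]
        )

    def tau_vector(self) -> np.ndarray:
        return np.concatenate(
            [np.full(self.N_E, self.E.tau), np.full(self.N_I, self.I.tau)]
        )


def psi(params: NetworkParams) -> float:
    r"""Inhibition-strength parameter :math:`\psi`.

    .. math:: \psi = \frac{\tau_I\,|J_{II}|\,\nu_I^{max}\,\Lambda_I}{4(N-1)}

    ``psi < 1`` is the weak-inhibition regime, where equilibria are always
    homogeneous within each population; ``psi >= 1`` is the strong-inhibition
    regime, where branching points break the inhibitory permutation symmetry.

    The magnitude of ``J_II`` is used: the regime classification depends only
    on the strength of self-inhibition, not on its (negative) sign.
    """
    p = params.I
    return p.tau * abs(params.J_II) * p.nu_max * p.Lambda / (4.0 * params.M)


def renormalize_weights(params: NetworkParams) -> NetworkParams:
    """Convert to the population-size normalization ``J_ab -> (N-1)/N_b J_ab``.

    This maps the ``1/(N-1)`` synaptic normalization used here onto the
    convention where each weight block is divided by the size of the
    presynaptic population.  The substitution is exactly invertible with
    ``J_ab -> N_b/(N-1) J_ab``.
    """
    M = params.M
    return params.replace(
        J_EE=M / params.N_E * params.J_EE,
        J_IE=M / params.N_E * params.J_IE,
        J_EI=M / params.N_I * params.J_EI,
        J_II=M / params.N_I * params.J_II,
    )


def table1_params(
    J_II: float = -10.0,
    I_E: float = 0.0,
    I_I: float = 0.0,
    N_E: int = 8,
    N_I: int = 2,
) -> NetworkParams:
    """Canonical benchmark parameter set.

    ``N_E = 8``, ``N_I = 2``, ``J_EE = 10``, ``J_EI = -70``, ``J_IE = 70``,
    ``tau = 1``, ``nu_max = 1``, ``Lambda = 2``, ``V_T = 2`` for both
    populations.  ``J_II`` and the external currents are the bifurcation
    parameters and stay free.
    """
    return NetworkParams(
        E=PopulationParams(size=N_E),
        I=PopulationParams(size=N_I),
        J_II=J_II,
        I_E=I_E,
        I_I=I_I,
    )


# ---------------------------------------------------------------------------
# flat key-value config I/O
# ---------------------------------------------------------------------------

_FLAT_KEYS = (
    "N_E", "N_I", "J_EE", "J_EI", "J_IE", "J_II",
    "tau_E", "tau_I", "nu_max_E", "nu_max_I",
    "Lambda_E", "Lambda_I", "V_T_E", "V_T_I", "I_E", "I_I",
)


def params_to_dict(params: NetworkParams) -> dict:
    """Flatten a :class:`NetworkParams` into the canonical key-value form."""
    return {
        "N_E": params.N_E,
        "N_I": params.N_I,
        "J_EE": params.J_EE,
        "J_EI": params.J_EI,
        "J_IE": params.J_IE,
        "J_II": params.J_II,
        "tau_E": params.E.tau,
        "tau_I": params.I.tau,
        "nu_max_E": params.E.nu_max,
        "nu_max_I": params.I.nu_max,
        "Lambda_E": params.E.Lambda,
        "Lambda_I": params.I.Lambda,
        "V_T_E": params.E.V_T,
        "V_T_I": params.I.V_T,
        "I_E": params.I_E,
        "I_I": params.I_I,
    }


def params_from_dict(d: dict) -> NetworkParams:
    missing = [k for k in _FLAT_KEYS if k not in d]
    if missing:
        raise KeyError(f"missing parameter keys: {missing}")
    E = PopulationParams(
        size=int(d["N_E"]), tau=float(d["tau_E"]), nu_max=float(d["nu_max_E"]),
        Lambda=float(d["Lambda_E"]), V_T=float(d["V_T_E"]),
    )
    I = PopulationParams(
        size=int(d["N_I"]), tau=float(d["tau_I"]), nu_max=float(d["nu_max_I"]),
        Lambda=float(d["Lambda_I"]), V_T=float(d["V_T_I"]),
    )
    return NetworkParams(
        E=E, I=I,
        J_EE=float(d["J_EE"]), J_EI=float(d["J_EI"]),
        J_IE=float(d["J_IE"]), J_II=float(d["J_II"]),
        I_E=float(d["I_E"]), I_I=float(d["I_I"]),
    )


def save_params(params: NetworkParams, path: str | Path | io.TextIOBase) -> None:
    """Write a parameter set as a flat YAML key-value file."""
    d = params_to_dict(params)
    if hasattr(path, "write"):
        yaml.safe_dump(d, path, sort_keys=False)
    else:
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def load_params(path: str | Path | io.TextIOBase) -> NetworkParams:
    """Read a parameter set from a flat YAML key-value file."""
    if hasattr(path, "read"):
        d = yaml.safe_load(path)
    else:
        with open(path) as fh:
            d = yaml.safe_load(fh)
    return params_from_dict(d)
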