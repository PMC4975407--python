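r"""Closed-form bifurcation curves and codimension-two points.

All local bifurcations of the homogeneous branch can be parameterized in
closed form by a membrane potential ``v``:

* saddle-node (LP): zero mean-mode eigenvalue, equivalent to ``X = Y Z``;
  the inhibitory slope follows from ``v = mu_E``, the potential from the
  slope inversion, and the currents from the stationarity equations.
* Andronov-Hopf (H): ``Y + Z = 0`` with negative discriminant
  ``(Y-Z)^2 + 4X < 0``.
* Bogdanov-Takens (BT): both conditions at once (double zero eigenvalue),
  reached at the ends of the Hopf parameter interval.
* branching point (BP): ``lambda_I = 0``, i.e. the inhibitory difference
  mode loses stability; exists only for ``psi >= 1`` and yields explicit
  curves ``I_E = F_pm(I_I)``.
* zero-Hopf (ZH): ``lambda_I = 0`` together with a pure-imaginary pair;
  both slope conditions fix the potentials up to sign choices.

On the ``N_I = 2`` secondary (symmetry-broken) branches the LP and H
conditions fix the excitatory slope as rational/quadratic functions of the
two inhibitory slopes; the curves are parameterized by ``v = mu_I0``, with
the partner potential supplied by the inhibitory pair relation.

Every emitted point carries a ``verified`` flag from an independent dense
eigensolve of the full Jacobian at the corresponding equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .equilibria import inhibitory_pair_relation, pair_function
from .model import (
    activation,
    activation_deriv,
    inverse_activation,
    inverse_activation_deriv,
    jacobian_full,
    primary_state,
)
from .params import NetworkParams, psi, renormalize_weights  # noqa: F401 (re-export)

__all__ = [
    "BifurcationCurve",
    "BifurcationPoint",
    "lp_curve_primary",
    "hopf_curve_primary",
    "bt_points_primary",
    "bp_curve",
    "zh_points",
    "lp_curve_secondary",
    "hopf_curve_secondary",
    "detect_cusps_on_curve",
    "codim2_diagram",
    "Codim2Diagram",
    "verify_point",
]

#: dense-eigensolver tolerance for the defining eigenvalue condition
VERIFY_TOL = 1e-6


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class BifurcationCurve:
    """A sampled parametric bifurcation curve in the (I_E, I_I) plane.

    ``v`` holds the curve parameter (a membrane potential), ``I_E``/``I_I``
    the current coordinates, ``states`` the equilibrium potentials
    ``(mu_E, mu_I0, mu_I1)`` at each sample (``mu_I1 == mu_I0`` on the
    primary branch), ``branch`` an integer sign-choice label so that
    separate feasibility segments are never silently bridged, and
    ``verified`` the per-point dense-eigensolver check.
    """

    kind: str
    v: np.ndarray
    I_E: np.ndarray
    I_I: np.ndarray
    states: np.ndarray
    branch: np.ndarray
    verified: np.ndarray
    domain: tuple[float, float] | None = None

    def __len__(self) -> int:
        return len(self.v)

    @property
    def is_empty(self) -> bool:
        return len(self.v) == 0

    def segments(self) -> list[np.ndarray]:
        """Index arrays of the contiguous sign-choice segments."""
        return [np.flatnonzero(self.branch == b) for b in np.unique(self.branch)]


@dataclass(frozen=True)
class BifurcationPoint:
    """An isolated codimension-two point in the (I_E, I_I) plane."""

    kind: str
    I_E: float
    I_I: float
    mu_E: float
    mu_I: tuple[float, ...]
    omega: float | None = None
    verified: bool = False


def _empty_curve(kind: str) -> BifurcationCurve:
    z = np.empty(0)
    return BifurcationCurve(kind=kind, v=z, I_E=z.copy(), I_I=z.copy(),
                            states=np.empty((0, 3)), branch=np.empty(0, dtype=int),
                            verified=np.empty(0, dtype=bool))


# ---------------------------------------------------------------------------
# dense verification
# ---------------------------------------------------------------------------

def _state_from(mu_E: float, mu_I0: float, mu_I1: float,
                params: NetworkParams) -> np.ndarray:
    if abs(mu_I0 - mu_I1) < 1e-12:
        return primary_state(mu_E, mu_I0, params)
    if params.N_I != 2:
        raise ValueError("two-cluster states require N_I = 2")
    return np.concatenate([np.full(params.N_E, mu_E), [mu_I0, mu_I1]])


def verify_point(kind: str, mu_E: float, mu_I0: float, mu_I1: float,
                 params: NetworkParams, tol: float = VERIFY_TOL) -> bool:
    """Check a point's defining eigenvalue condition on the dense Jacobian.

    ``LP``/``BP`` demand an eigenvalue with ``|lambda| < tol``; ``H`` a
    conjugate pair with ``|Re| < tol`` and ``Im != 0``; ``BT`` a double
    (near-)zero eigenvalue; ``ZH`` both a zero and a pure-imaginary pair.
    """
    lam = np.linalg.eigvals(jacobian_full(_state_from(mu_E, mu_I0, mu_I1, params),
                                          params))
    near_zero = np.abs(lam) < tol
    pure_imag = (np.abs(lam.real) < tol) & (np.abs(lam.imag) > tol)
    if kind.startswith("LP") or kind == "BP":
        return bool(near_zero.any())
    if kind.startswith("H"):
        return int(pure_imag.sum()) >= 2
    if kind == "BT":
        # double zero: two eigenvalues within sqrt-tolerance of zero
        return int((np.abs(lam) < np.sqrt(tol)).sum()) >= 2 and bool(
            (np.abs(lam) < 10 * tol).any())
    if kind == "ZH":
        return bool(near_zero.any()) and int(pure_imag.sum()) >= 2
    raise ValueError(f"unknown bifurcation kind {kind!r}")


# ---------------------------------------------------------------------------
# primary-branch curves
# ---------------------------------------------------------------------------

def _currents_primary(mu_E: float, mu_I: float, params: NetworkParams
                      ) -> tuple[float, float]:
    """Currents that make (mu_E, mu_I) a homogeneous equilibrium."""
    M = params.M
    I_E = (mu_E / params.E.tau
           - (params.N_E - 1) / M * params.J_EE * activation(mu_E, params.E)
           - params.N_I / M * params.J_EI * activation(mu_I, params.I))
    I_I = (mu_I / params.I.tau
           - params.N_E / M * params.J_IE * activation(mu_E, params.E)
           - (params.N_I - 1) / M * params.J_II * activation(mu_I, params.I))
    return float(I_E), float(I_I)


def _lp_slope_I(v: float, params: NetworkParams) -> float:
    """Inhibitory slope solving X = Y Z at excitatory potential v."""
    NE, NI, M = params.N_E, params.N_I, params.M
    sE = float(activation_deriv(v, params.E))
    tauE, tauI = params.E.tau, params.I.tau
    num = -1.0 / (tauE * tauI) + (NE - 1) / M * params.J_EE * sE / tauI
    den = (-(NI - 1) / M * params.J_II / tauE
           + ((NE - 1) * (NI - 1) * params.J_EE * params.J_II
              - NE * NI * params.J_EI * params.J_IE) / M**2 * sE)
    return num / den


def _hopf_slope_I(v: float, params: NetworkParams) -> float:
    """Inhibitory slope solving Y + Z = 0 at excitatory potential v."""
    NE, NI, M = params.N_E, params.N_I, params.M
    sE = float(activation_deriv(v, params.E))
    return (M / ((NI - 1) * params.J_II)
            * (1.0 / params.E.tau + 1.0 / params.I.tau
               - (NE - 1) / M * params.J_EE * sE))


def _lp_domain(params: NetworkParams) -> tuple[float, float] | None:
    """Parameter interval (v_a, v_b) on which the LP slope is attainable."""
    g = (params.N_E - 1) / params.M * params.J_EE * params.E.nu_max \
        * params.E.Lambda * params.E.tau / 4.0
    if g <= 1.0:
        return None
    d = (2.0 / params.E.Lambda) * np.sqrt(g ** (2.0 / 3.0) - 1.0)
    return params.E.V_T - d, params.E.V_T + d


def _sample_parametric_primary(kind: str, slope_fn, v_lo: float, v_hi: float,
                               n: int, params: NetworkParams,
                               verify: bool = True) -> BifurcationCurve:
    """Build a primary-branch curve by enumerating both slope-inversion signs."""
    vs, IEs, IIs, states, branch, ok = [], [], [], [], [], []
    grid = np.linspace(v_lo, v_hi, n)
    for sign_idx in (0, 1):  # mu_I below / above threshold
        for v in grid:
            sI = slope_fn(float(v), params)
            if not (0.0 < sI <= params.I.max_slope):
                continue
            mu_I = inverse_activation_deriv(sI, params.I)[sign_idx]
            if kind == "H_primary":
                e = _eig_xyz(float(v), mu_I, params)
                # need a genuinely complex pair with omega bounded away from
                # zero, which excludes the degenerate BT endpoints
                if e[3] >= -(20.0 * VERIFY_TOL) ** 2:
                    continue
            I_E, I_I = _currents_primary(float(v), mu_I, params)
            vs.append(float(v)); IEs.append(I_E); IIs.append(I_I)
            states.append((float(v), mu_I, mu_I))
            branch.append(sign_idx)
            ok.append(verify_point(kind, float(v), mu_I, mu_I,
                                   params.with_inputs(I_E=I_E, I_I=I_I))
                      if verify else True)
    if not vs:
        return _empty_curve(kind)
    return BifurcationCurve(
        kind=kind, v=np.array(vs), I_E=np.array(IEs), I_I=np.array(IIs),
        states=np.array(states), branch=np.array(branch, dtype=int),
        verified=np.array(ok, dtype=bool), domain=(v_lo, v_hi),
    )


def _eig_xyz(mu_E, mu_I, params):
    NE, NI, M = params.N_E, params.N_I, params.M
    sE = float(activation_deriv(mu_E, params.E))
    sI = float(activation_deriv(mu_I, params.I))
    X = NE * NI / M**2 * params.J_EI * params.J_IE * sE * sI
    Y = -1.0 / params.E.tau + (NE - 1) / M * params.J_EE * sE
    Z = -1.0 / params.I.tau + (NI - 1) / M * params.J_II * sI
    return X, Y, Z, (Y - Z) ** 2 + 4 * X


def lp_curve_primary(params: NetworkParams, n: int = 400,
                     verify: bool = True) -> BifurcationCurve:
    """Saddle-node curves of the homogeneous branch.

    Empty when recurrent excitation is too weak to fold the nullclines,
    i.e. when ``(N_E-1)/(N-1) J_EE nu_E Lambda_E tau_E / 4 <= 1``.
    """
    dom = _lp_domain(params)
    if dom is None:
        return _empty_curve("LP_primary")
    v_a, v_b = dom
    eps = 1e-9 * max(1.0, abs(v_b - v_a))
    return _sample_parametric_primary("LP_primary", _lp_slope_I,
                                      v_a + eps, v_b - eps, n, params, verify)


def _hopf_v_endpoints(params: NetworkParams):
    """Outer parameter bounds (v_f, v_e) of the Hopf curve (the BT potentials)."""
    NE, NI, M = params.N_E, params.N_I, params.M
    tauE, tauI = params.E.tau, params.I.tau
    a = ((NE - 1) / M * params.J_EE) ** 2 \
        - NE * NI * (NE - 1) / (M**2 * (NI - 1)) \
        * params.J_EE * params.J_EI * params.J_IE / params.J_II
    b = (-2.0 / tauE * (NE - 1) / M * params.J_EE
         + NE * NI / (M * (NI - 1)) * params.J_EI * params.J_IE / params.J_II
         * (1.0 / tauE + 1.0 / tauI))
    c = 1.0 / tauE**2
    disc = b * b - 4.0 * a * c
    if disc <= 0.0:
        return None
    z = (-b - np.sqrt(disc)) / (2.0 * a)
    g = params.E.nu_max * params.E.Lambda / (4.0 * z)
    if not (z > 0.0 and g > 1.0):
        return None
    d = (2.0 / params.E.Lambda) * np.sqrt(g ** (2.0 / 3.0) - 1.0)
    return params.E.V_T - d, params.E.V_T + d


def hopf_curve_primary(params: NetworkParams, n: int = 400,
                       verify: bool = True) -> BifurcationCurve:
    """Andronov-Hopf curves of the homogeneous branch.

    Samples the full interval between the two BT potentials; points where
    the required inhibitory slope is unattainable or the discriminant is
    non-negative are skipped, which carves out the two feasible windows.
    """
    ends = _hopf_v_endpoints(params)
    if ends is None:
        return _empty_curve("H_primary")
    v_f, v_e = ends
    return _sample_parametric_primary("H_primary", _hopf_slope_I,
                                      v_f, v_e, n, params, verify)


def bt_points_primary(params: NetworkParams,
                      verify: bool = True) -> list[BifurcationPoint]:
    """Bogdanov-Takens points: double zero eigenvalue, ends of the H curve."""
    ends = _hopf_v_endpoints(params)
    if ends is None:
        return []
    out: list[BifurcationPoint] = []
    for v in ends:
        sI = _hopf_slope_I(v, params)
        if not (0.0 < sI <= params.I.max_slope):
            continue
        for mu_I in inverse_activation_deriv(sI, params.I):
            X, Y, Z, disc = _eig_xyz(v, mu_I, params)
            # require the simultaneous LP condition X = YZ (double zero)
            if abs(X - Y * Z) > 1e-6 * max(1.0, abs(X)):
                continue
            I_E, I_I = _currents_primary(v, mu_I, params)
            ok = verify_point("BT", v, mu_I, mu_I,
                              params.with_inputs(I_E=I_E, I_I=I_I)) if verify else True
            out.append(BifurcationPoint(kind="BT", I_E=I_E, I_I=I_I,
                                        mu_E=v, mu_I=(mu_I,), verified=ok))
    return out


def bp_curve(params: NetworkParams, I_I_range: tuple[float, float] = (-40.0, 10.0),
             n: int = 400, verify: bool = True) -> BifurcationCurve:
    r"""Branching-point curves :math:`I_E = F_\pm(I_I)` (``lambda_I = 0``).

    The BP inhibitory potentials are
    :math:`\mu_I = V_I^T \pm \frac{2}{\Lambda_I}\sqrt{\psi^{2/3} - 1}`,
    defined only for :math:`\psi \ge 1`; for each the excitatory potential
    follows from the inhibitory stationarity equation (a monotone activation
    inversion), and ``I_E`` from the excitatory one.
    """
    if psi(params) < 1.0 or params.J_II == 0.0:
        return _empty_curve("BP")
    M = params.M
    d = (2.0 / params.I.Lambda) * np.sqrt(psi(params) ** (2.0 / 3.0) - 1.0)
    mu_I_options = (params.I.V_T - d, params.I.V_T + d)

    vs, IEs, IIs, states, branch, ok = [], [], [], [], [], []
    for sign_idx, mu_I in enumerate(mu_I_options):
        aI = float(activation(mu_I, params.I))
        for I_I in np.linspace(*I_I_range, n):
            # required excitatory rate from the inhibitory equation
            r = M / (params.N_E * params.J_IE) * (
                mu_I / params.I.tau
                - (params.N_I - 1) / M * params.J_II * aI - I_I)
            if not (0.0 < r < params.E.nu_max):
                continue
            mu_E = float(inverse_activation(r, params.E))
            I_E = (mu_E / params.E.tau
                   - (params.N_E - 1) / M * params.J_EE * activation(mu_E, params.E)
                   - params.N_I / M * params.J_EI * aI)
            vs.append(float(I_I)); IEs.append(float(I_E)); IIs.append(float(I_I))
            states.append((mu_E, mu_I, mu_I)); branch.append(sign_idx)
            ok.append(verify_point("BP", mu_E, mu_I, mu_I,
                                   params.with_inputs(I_E=I_E, I_I=I_I))
                      if verify else True)
    if not vs:
        return _empty_curve("BP")
    return BifurcationCurve(
        kind="BP", v=np.array(vs), I_E=np.array(IEs), I_I=np.array(IIs),
        states=np.array(states), branch=np.array(branch, dtype=int),
        verified=np.array(ok, dtype=bool), domain=I_I_range,
    )


def zh_points(params: NetworkParams, verify: bool = True) -> list[BifurcationPoint]:
    r"""Zero-Hopf points: ``lambda_I = 0`` together with a pure-imaginary pair.

    The two slope conditions

    .. math::

        A_E'(\mu_E) = \frac{N-1}{(N_E-1)J_{EE}}
            \Big(\frac{1}{\tau_E} + \frac{N_I}{\tau_I}\Big), \qquad
        A_I'(\mu_I) = \frac{N-1}{\tau_I |J_{II}|}

    each admit two potentials; of the four sign combinations, those with a
    real (non-complex) mean-mode pair are discarded.
    """
    if psi(params) < 1.0:
        return []
    M = params.M
    sE = M / ((params.N_E - 1) * params.J_EE) * (
        1.0 / params.E.tau + params.N_I / params.I.tau)
    sI = M / (params.I.tau * abs(params.J_II))
    if not (0.0 < sE <= params.E.max_slope and 0.0 < sI <= params.I.max_slope):
        return []
    out: list[BifurcationPoint] = []
    for mu_E in inverse_activation_deriv(sE, params.E):
        for mu_I in inverse_activation_deriv(sI, params.I):
            X, Y, Z, disc = _eig_xyz(mu_E, mu_I, params)
            if disc >= 0.0:
                continue
            I_E, I_I = _currents_primary(mu_E, mu_I, params)
            omega = float(np.sqrt(-disc) / 2.0)
            ok = verify_point("ZH", mu_E, mu_I, mu_I,
                              params.with_inputs(I_E=I_E, I_I=I_I)) if verify else True
            out.append(BifurcationPoint(kind="ZH", I_E=I_E, I_I=I_I,
                                        mu_E=mu_E, mu_I=(mu_I,),
                                        omega=omega, verified=ok))
    return out


# ---------------------------------------------------------------------------
# secondary-branch curves (N_I = 2)
# ---------------------------------------------------------------------------

def _secondary_currents(mu_E: float, mu0: float, mu1: float,
                        params: NetworkParams) -> tuple[float, float]:
    M = params.M
    aE = float(activation(mu_E, params.E))
    a0 = float(activation(mu0, params.I))
    a1 = float(activation(mu1, params.I))
    I_E = (mu_E / params.E.tau
           - (params.N_E - 1) / M * params.J_EE * aE
           - params.J_EI / M * (a0 + a1))
    I_I = (mu0 / params.I.tau - params.N_E / M * params.J_IE * aE
           - params.J_II / M * a1)
    return I_E, I_I


def _lp_secondary_slope_E(s0: float, s1: float, params: NetworkParams) -> float:
    """Excitatory slope at which the two-cluster Jacobian is singular."""
    NE, M = params.N_E, params.M
    tauE, tauI = params.E.tau, params.I.tau
    JEE, JEI, JIE, JII = params.J_EE, params.J_EI, params.J_IE, params.J_II
    a = (1.0 / tauI**2 * (NE - 1) / M * JEE
         + 1.0 / tauI * NE / M**2 * JEI * JIE * (s0 + s1)
         + (2.0 * NE * JEI * JIE * JII - (NE - 1) * JEE * JII**2) / M**3 * s0 * s1)
    b = 1.0 / tauE * (1.0 / tauI**2 - (JII / M) ** 2 * s0 * s1)
    if a == 0.0:
        return np.inf
    return b / a


def _hopf_secondary_slopes_E(s0: float, s1: float,
                             params: NetworkParams) -> list[float]:
    """Excitatory slopes giving a pure-imaginary pair on the two-cluster Jacobian."""
    NE, M = params.N_E, params.M
    tauE, tauI = params.E.tau, params.I.tau
    JEE, JEI, JIE, JII = params.J_EE, params.J_EI, params.J_IE, params.J_II
    a = (NE - 1) / M * JEE * (2.0 / tauI * (NE - 1) / M * JEE
                              + NE / M**2 * JEI * JIE * (s0 + s1))
    b = (2.0 * NE / M**3 * JEI * JIE * JII * s0 * s1
         - (1.0 / tauE + 1.0 / tauI)
         * (4.0 / tauI * (NE - 1) / M * JEE + NE / M**2 * JEI * JIE * (s0 + s1)))
    c = 2.0 / tauI * ((1.0 / tauE + 1.0 / tauI) ** 2 - (JII / M) ** 2 * s0 * s1)
    disc = b * b - 4.0 * a * c
    if disc < 0.0 or a == 0.0:
        return []
    sq = np.sqrt(disc)
    return [(-b + sq) / (2.0 * a), (-b - sq) / (2.0 * a)]


def _secondary_v_window(params: NetworkParams, pad: float = 2.0
                        ) -> tuple[float, float] | None:
    """Range of mu_I0 on which off-diagonal pair partners can exist.

    Partners exist where the pair level phi(v) falls inside the fold window
    of the non-monotone phi; the window is bracketed from the turning
    points (the BP potentials) and padded.
    """
    if psi(params) < 1.0:
        return None
    d = (2.0 / params.I.Lambda) * np.sqrt(psi(params) ** (2.0 / 3.0) - 1.0)
    x_lo, x_hi = params.I.V_T - d, params.I.V_T + d
    lv_hi = float(pair_function(x_lo, params))   # local max of phi
    lv_lo = float(pair_function(x_hi, params))   # local min of phi

    def outer(level, bracket_lo, bracket_hi):
        return float(optimize.brentq(
            lambda t: float(pair_function(t, params)) - level,
            bracket_lo, bracket_hi))

    span = 200.0 / params.I.Lambda
    v_min = outer(lv_lo, params.I.V_T - span, x_lo)
    v_max = outer(lv_hi, x_hi, params.I.V_T + span)
    return v_min - pad, v_max + pad


def _sample_secondary(kind: str, slope_enum, params: NetworkParams,
                      n: int, verify: bool) -> BifurcationCurve:
    if params.N_I != 2:
        raise ValueError("secondary-branch curves require N_I = 2")
    window = _secondary_v_window(params)
    if window is None:
        return _empty_curve(kind)
    vs, IEs, IIs, states, branch, ok = [], [], [], [], [], []
    for v in np.linspace(*window, n):
        partners = [m for m in inhibitory_pair_relation(float(v), params)
                    if abs(m - v) > 1e-5]
        s0 = float(activation_deriv(v, params.I))
        for mu1 in partners:
            s1 = float(activation_deriv(mu1, params.I))
            for root_idx, sE in enumerate(slope_enum(s0, s1, params)):
                if not (0.0 < sE <= params.E.max_slope):
                    continue
                for sign_idx, mu_E in enumerate(
                        inverse_activation_deriv(sE, params.E)):
                    I_E, I_I = _secondary_currents(mu_E, float(v), mu1, params)
                    if kind.startswith("H"):
                        # the trace condition is also met by neutral saddles
                        # (a real +/- pair); keep only genuine complex pairs
                        lam = np.linalg.eigvals(jacobian_full(
                            _state_from(mu_E, float(v), mu1, params), params))
                        pure = (np.abs(lam.real) < VERIFY_TOL) \
                            & (np.abs(lam.imag) > 10.0 * VERIFY_TOL)
                        if int(pure.sum()) < 2:
                            continue
                    good = verify_point(
                        kind, mu_E, float(v), mu1,
                        params.with_inputs(I_E=I_E, I_I=I_I)) if verify else True
                    vs.append(float(v)); IEs.append(I_E); IIs.append(I_I)
                    states.append((mu_E, float(v), mu1))
                    branch.append(2 * root_idx + sign_idx)
                    ok.append(good)
    if not vs:
        return _empty_curve(kind)
    return BifurcationCurve(
        kind=kind, v=np.array(vs), I_E=np.array(IEs), I_I=np.array(IIs),
        states=np.array(states), branch=np.array(branch, dtype=int),
        verified=np.array(ok, dtype=bool), domain=window,
    )


def lp_curve_secondary(params: NetworkParams, n: int = 400,
                       verify: bool = True) -> BifurcationCurve:
    """Saddle-node curve on the N_I = 2 symmetry-broken branches."""
    return _sample_secondary(
        "LP_secondary",
        lambda s0, s1, p: [_lp_secondary_slope_E(s0, s1, p)],
        params, n, verify)


def hopf_curve_secondary(params: NetworkParams, n: int = 400,
                         verify: bool = True) -> BifurcationCurve:
    """Hopf curve on the N_I = 2 symmetry-broken branches (both quadratic roots)."""
    return _sample_secondary("H_secondary", _hopf_secondary_slopes_E,
                             params, n, verify)


# ---------------------------------------------------------------------------
# cusp detection and diagram assembly
# ---------------------------------------------------------------------------

def detect_cusps_on_curve(curve: BifurcationCurve,
                          speed_quantile: float = 0.05) -> list[BifurcationPoint]:
    """Estimate cusp points where the curve's tangent passes through zero.

    Works per sign-choice segment: the (I_E, I_I) tangent speed with respect
    to the curve parameter is computed by finite differences; local speed
    minima far below the segment's typical speed, at which the orientation
    of the tangent reverses, are flagged as cusps.
    """
    out: list[BifurcationPoint] = []
    for idx in curve.segments():
        if len(idx) < 7:
            continue
        order = np.argsort(curve.v[idx])
        idx = idx[order]
        v = curve.v[idx]
        P = np.column_stack([curve.I_E[idx], curve.I_I[idx]])
        dv = np.gradient(v)
        T = np.column_stack([np.gradient(P[:, 0]) / dv, np.gradient(P[:, 1]) / dv])
        speed = np.hypot(T[:, 0], T[:, 1])
        typical = np.median(speed)
        for k in range(1, len(idx) - 1):
            if speed[k] > speed[k - 1] or speed[k] > speed[k + 1]:
                continue
            if speed[k] > speed_quantile * typical:
                continue
            # orientation reversal of the tangent across the minimum
            if np.dot(T[k - 1], T[k + 1]) < 0.0:
                out.append(BifurcationPoint(
                    kind="CP", I_E=float(P[k, 0]), I_I=float(P[k, 1]),
                    mu_E=float(curve.states[idx[k], 0]),
                    mu_I=tuple(curve.states[idx[k], 1:]), verified=True))
    return out


@dataclass
class Codim2Diagram:
    """Bundle of all applicable curves and codim-2 points for one J_II."""

    params: NetworkParams
    psi: float
    curves: dict[str, BifurcationCurve]
    points: dict[str, list[BifurcationPoint]]

    def verification_summary(self) -> dict[str, tuple[int, int]]:
        """Per curve kind: (verified points, total points)."""
        out = {}
        for k, c in self.curves.items():
            out[k] = (int(c.verified.sum()), len(c))
        for k, pts in self.points.items():
            out[k] = (sum(p.verified for p in pts), len(pts))
        return out


def codim2_diagram(params: NetworkParams,
                   I_I_range: tuple[float, float] = (-40.0, 10.0),
                   n: int = 400, verify: bool = True) -> Codim2Diagram:
    """Assemble the full codimension-two diagram for the given parameters.

    LP/H/BT of the primary branch are always computed; the BP curve, ZH
    points, and secondary-branch LP/H curves only in the strong-inhibition
    regime (``psi >= 1``), where they exist.
    """
    curves: dict[str, BifurcationCurve] = {
        "LP_primary": lp_curve_primary(params, n, verify),
        "H_primary": hopf_curve_primary(params, n, verify),
    }
    points: dict[str, list[BifurcationPoint]] = {
        "BT": bt_points_primary(params, verify),
    }
    if psi(params) >= 1.0:
        curves["BP"] = bp_curve(params, I_I_range, n, verify)
        curves["LP_secondary"] = lp_curve_secondary(params, n, verify)
        curves["H_secondary"] = hopf_curve_secondary(params, n, verify)
        points["ZH"] = zh_points(params, verify)
    else:
        curves["BP"] = _empty_curve("BP")
        curves["LP_secondary"] = _empty_curve("LP_secondary")
        curves["H_secondary"] = _empty_curve("H_secondary")
        points["ZH"] = []
    points["CP"] = detect_cusps_on_curve(curves["LP_primary"])
    return Codim2Diagram(params=params, psi=psi(params),
                         curves=curves, points=points)
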