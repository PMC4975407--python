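r"""Stationary states on the primary and symmetry-broken branches.

On the primary branch all neurons in a population share one potential and
the equilibrium conditions reduce to two nullcline equations

.. math::

    F(\mu_E, \mu_I) &= -\mu_E/\tau_E + \tfrac{N_E-1}{N-1}J_{EE}A_E(\mu_E)
        + \tfrac{N_I}{N-1}J_{EI}A_I(\mu_I) + I_E = 0\\
    G(\mu_E, \mu_I) &= -\mu_I/\tau_I + \tfrac{N_E}{N-1}J_{IE}A_E(\mu_E)
        + \tfrac{N_I-1}{N-1}J_{II}A_I(\mu_I) + I_I = 0.

Under strong inhibition (:math:`\psi \ge 1`) the inhibitory population can
split; for :math:`N_I = 2` the secondary branches solve a three-equation
system in :math:`(\mu_E, \mu_{I,0}, \mu_{I,1})`.  Any two inhibitory
potentials at equilibrium satisfy the pair relation
:math:`\varphi(\mu_{I,j}) = \varphi(\mu_{I,i})` with
:math:`\varphi(x) = x/\tau_I + \tfrac{J_{II}}{N-1}A_I(x)`, which squares into
a quartic polynomial whose spurious roots are removed by a residual check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .model import (
    ClusterPartition,
    activation,
    activation_deriv,
    eigenvalues_clustered,
    eigenvalues_primary,
    primary_state,
)
from .params import NetworkParams, psi

__all__ = [
    "EquilibriumPoint",
    "QuarticCoefficients",
    "nullcline_F",
    "nullcline_G",
    "solve_primary",
    "pair_function",
    "quartic_coefficients",
    "inhibitory_pair_relation",
    "solve_secondary_ni2",
    "nullclines",
    "nullsurfaces",
    "classify_stability",
    "branch_continuation",
    "BranchDiagram",
]

#: default half-width (in units of 1/Lambda) of the potential search box
#: around the firing threshold; the activation saturates well inside it,
#: so every equilibrium of interest lies in the box
SEARCH_SPAN = 8.0


# ---------------------------------------------------------------------------
# nullcline equations
# ---------------------------------------------------------------------------

def nullcline_F(mu_E, mu_I, params: NetworkParams):
    """Excitatory stationarity residual on the primary branch."""
    M = params.M
    return (-np.asarray(mu_E) / params.E.tau
            + (params.N_E - 1) / M * params.J_EE * activation(mu_E, params.E)
            + params.N_I / M * params.J_EI * activation(mu_I, params.I)
            + params.I_E)


def nullcline_G(mu_E, mu_I, params: NetworkParams):
    """Inhibitory stationarity residual on the primary branch."""
    M = params.M
    return (-np.asarray(mu_I) / params.I.tau
            + params.N_E / M * params.J_IE * activation(mu_E, params.E)
            + (params.N_I - 1) / M * params.J_II * activation(mu_I, params.I)
            + params.I_I)


def _secondary_residual(x: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Residuals of the N_I = 2 symmetry-broken stationarity system."""
    mu_E, mu0, mu1 = x
    M = params.M
    aE = activation(mu_E, params.E)
    a0 = activation(mu0, params.I)
    a1 = activation(mu1, params.I)
    F = (-mu_E / params.E.tau + (params.N_E - 1) / M * params.J_EE * aE
         + params.J_EI / M * (a0 + a1) + params.I_E)
    G = (-mu0 / params.I.tau + params.N_E / M * params.J_IE * aE
         + params.J_II / M * a1 + params.I_I)
    H = (-mu1 / params.I.tau + params.N_E / M * params.J_IE * aE
         + params.J_II / M * a0 + params.I_I)
    return np.array([F, G, H])


# ---------------------------------------------------------------------------
# equilibrium containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquilibriumPoint:
    """A stationary state with its inhibitory cluster structure.

    ``partition`` records the inhibitory potentials as ``(size, value)``
    clusters; a single cluster means the point lies on the primary branch.
    """

    mu_E: float
    partition: ClusterPartition
    residual: float
    eigenvalues: np.ndarray
    stable: bool
    marginal: bool = False

    @property
    def mu_I(self) -> float:
        """Inhibitory potential; only defined for single-cluster points."""
        if len(self.partition.clusters) != 1:
            raise ValueError("mu_I is only defined on the primary branch")
        return self.partition.potentials[0]

    @property
    def mu_I_values(self) -> tuple[float, ...]:
        return self.partition.potentials

    @property
    def max_real_eigenvalue(self) -> float:
        return float(np.max(self.eigenvalues.real))

    def state_vector(self, params: NetworkParams) -> np.ndarray:
        return np.concatenate(
            [np.full(params.N_E, self.mu_E), self.partition.expand()]
        )


def _make_primary_point(mu_E: float, mu_I: float, params: NetworkParams,
                        residual: float, tol: float = 1e-8) -> EquilibriumPoint:
    eig = eigenvalues_primary(mu_E, mu_I, params)
    lam = eig.multiset()
    mx = float(np.max(lam.real))
    return EquilibriumPoint(
        mu_E=float(mu_E),
        partition=ClusterPartition(((params.N_I, float(mu_I)),)),
        residual=float(residual),
        eigenvalues=lam,
        stable=mx < -tol,
        marginal=abs(mx) <= tol,
    )


# ---------------------------------------------------------------------------
# primary-branch solver
# ---------------------------------------------------------------------------

def _search_grid(pop, n: int, span: float) -> np.ndarray:
    return np.linspace(pop.V_T - span / pop.Lambda, pop.V_T + span / pop.Lambda, n)


def solve_primary(params: NetworkParams, n_grid: int = 25,
                  span: float = SEARCH_SPAN, residual_tol: float = 1e-10,
                  dedupe_tol: float = 1e-6) -> list[EquilibriumPoint]:
    """All homogeneous equilibria, found by multi-start damped Newton.

    Initial guesses form an ``n_grid x n_grid`` lattice over
    ``V_T ± span/Lambda`` in each variable; converged roots with residual
    below ``residual_tol`` are deduplicated within ``dedupe_tol``.

    Returns points sorted by ``mu_E``.
    """

    def fun(x):
        return np.array([nullcline_F(x[0], x[1], params),
                         nullcline_G(x[0], x[1], params)])

    roots: list[np.ndarray] = []
    for gE in _search_grid(params.E, n_grid, span):
        for gI in _search_grid(params.I, n_grid, span):
            sol = optimize.root(fun, np.array([gE, gI]), method="hybr",
                                options={"xtol": 1e-13})
            if not sol.success:
                continue
            if np.max(np.abs(fun(sol.x))) > residual_tol:
                continue
            if any(np.max(np.abs(sol.x - r)) < dedupe_tol for r in roots):
                continue
            roots.append(sol.x)

    roots.sort(key=lambda r: r[0])
    return [
        _make_primary_point(r[0], r[1], params,
                            float(np.max(np.abs(fun(r)))))
        for r in roots
    ]


# ---------------------------------------------------------------------------
# inhibitory pair relation (quartic)
# ---------------------------------------------------------------------------

def pair_function(x, params: NetworkParams):
    r""":math:`\varphi(x) = x/\tau_I + \frac{J_{II}}{N-1} A_I(x)`.

    At any equilibrium all inhibitory potentials share one value of
    :math:`\varphi`; for :math:`\psi > 1` the function is non-monotone and
    distinct potentials can coexist.
    """
    return np.asarray(x) / params.I.tau + params.J_II / params.M * activation(x, params.I)


@dataclass(frozen=True)
class QuarticCoefficients:
    """Coefficients of the pair-relation quartic ``a x^4 + ... + e = 0``.

    ``phi_hat`` is the level :math:`\\varphi(\\mu_{I,i})` shifted by the
    activation midpoint ``-J_II nu_max / (2(N-1))``; ``xi_hat`` is
    ``(nu_max Lambda J_II / (4(N-1)))^2``.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    phi_hat: float
    xi_hat: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.e])


def quartic_coefficients(mu_i: float, params: NetworkParams) -> QuarticCoefficients:
    r"""Quartic coefficients for the partner potentials of ``mu_i``.

    Built by squaring the centered pair relation: with
    :math:`u(x) = \hat\varphi - x/\tau_I` and :math:`y(x) = x - V_I^T`,
    partner potentials are real roots of
    :math:`u^2 (1 + \tfrac{\Lambda^2}{4} y^2) - \hat\xi y^2 = 0`.
    """
    pop = params.I
    c_w = params.J_II / params.M
    phi_hat = float(pair_function(mu_i, params)) - c_w * pop.nu_max / 2.0
    xi_hat = (pop.nu_max * pop.Lambda * params.J_II / (4.0 * params.M)) ** 2

    # polynomial arithmetic in descending powers of mu_j
    u = np.array([-1.0 / pop.tau, phi_hat])          # -x/tau + phi_hat
    y = np.array([1.0, -pop.V_T])                    # x - V_T
    u2 = np.polymul(u, u)
    y2 = np.polymul(y, y)
    poly = np.polyadd(
        np.polymul(u2, np.polyadd(np.array([0.0, 0.0, 1.0]),
                                  (pop.Lambda ** 2 / 4.0) * y2)),
        -xi_hat * y2,
    )
    a, b, c, d, e = poly
    return QuarticCoefficients(a=a, b=b, c=c, d=d, e=e,
                               phi_hat=phi_hat, xi_hat=xi_hat)


def inhibitory_pair_relation(mu_i: float, params: NetworkParams,
                             residual_tol: float = 1e-8) -> list[float]:
    """Partner inhibitory potentials compatible with ``mu_i`` at equilibrium.

    Solves the quartic and discards spurious roots (introduced by squaring)
    whose residual in the unsquared pair relation exceeds ``residual_tol``.
    ``mu_i`` itself is always among the retained roots.
    """
    q = quartic_coefficients(mu_i, params)
    roots = np.roots(q.as_array())
    out: list[float] = []
    level = float(pair_function(mu_i, params))
    for r in roots:
        if abs(r.imag) > 1e-8:
            continue
        x = float(r.real)
        # polish against the exact (unsquared) relation
        try:
            x = float(optimize.brentq(
                lambda t: float(pair_function(t, params)) - level,
                x - 1e-4, x + 1e-4))
        except ValueError:
            pass
        if abs(float(pair_function(x, params)) - level) > residual_tol:
            continue
        if any(abs(x - o) < 1e-7 for o in out):
            continue
        out.append(x)
    if not any(abs(o - mu_i) < 1e-6 for o in out):
        out.append(float(mu_i))
    return sorted(out)


# ---------------------------------------------------------------------------
# N_I = 2 secondary branches
# ---------------------------------------------------------------------------

def _make_secondary_point(x: np.ndarray, params: NetworkParams,
                          residual: float, tol: float = 1e-8,
                          cluster_tol: float = 1e-6) -> EquilibriumPoint:
    mu_E, mu0, mu1 = (float(v) for v in x)
    if abs(mu0 - mu1) < cluster_tol:
        return _make_primary_point(mu_E, 0.5 * (mu0 + mu1), params, residual, tol)
    part = ClusterPartition(((1, mu0), (1, mu1)))
    lam = eigenvalues_clustered(part, mu_E, params)
    mx = float(np.max(lam.real))
    return EquilibriumPoint(mu_E=mu_E, partition=part, residual=residual,
                            eigenvalues=lam, stable=mx < -tol,
                            marginal=abs(mx) <= tol)


def solve_secondary_ni2(params: NetworkParams, n_grid: int = 12,
                        span: float = SEARCH_SPAN, residual_tol: float = 1e-10,
                        dedupe_tol: float = 1e-6) -> list[EquilibriumPoint]:
    """All stationary states (homogeneous and broken) for ``N_I = 2``.

    Symmetry-broken solutions come in swap pairs ``(mu_E, a, b)`` /
    ``(mu_E, b, a)``; both members are returned as distinct points.
    """
    if params.N_I != 2:
        raise ValueError("solver requires N_I = 2")

    gridE = _search_grid(params.E, n_grid, span)
    gridI = _search_grid(params.I, n_grid, span)
    roots: list[np.ndarray] = []
    for gE in gridE:
        for g0 in gridI:
            for g1 in gridI:
                if g1 < g0:
                    continue  # recover the swapped partner afterwards
                sol = optimize.root(_secondary_residual, np.array([gE, g0, g1]),
                                    args=(params,), method="hybr",
                                    options={"xtol": 1e-13})
                if not sol.success:
                    continue
                if np.max(np.abs(_secondary_residual(sol.x, params))) > residual_tol:
                    continue
                cand = sol.x if sol.x[1] <= sol.x[2] else sol.x[[0, 2, 1]]
                if any(np.max(np.abs(cand - r)) < dedupe_tol for r in roots):
                    continue
                roots.append(cand)

    points: list[EquilibriumPoint] = []
    for r in sorted(roots, key=lambda v: (v[0], v[1])):
        res = float(np.max(np.abs(_secondary_residual(r, params))))
        points.append(_make_secondary_point(r, params, res))
        if abs(r[1] - r[2]) >= dedupe_tol:
            points.append(_make_secondary_point(r[[0, 2, 1]], params, res))
    return points


# ---------------------------------------------------------------------------
# nullcline / nullsurface sampling
# ---------------------------------------------------------------------------

def _zero_crossings_1d(f, grid: np.ndarray) -> list[float]:
    """Bisection-refined zeros of f along a sampled 1-D grid."""
    try:
        vals = np.asarray(f(grid), dtype=float)
        if vals.shape != grid.shape:
            raise TypeError
    except (TypeError, ValueError):
        vals = np.array([float(f(g)) for g in grid])
    out = []
    for k in range(len(grid) - 1):
        a, b = vals[k], vals[k + 1]
        if a == 0.0:
            out.append(float(grid[k]))
        elif a * b < 0.0:
            out.append(float(optimize.brentq(f, grid[k], grid[k + 1])))
    return out


def nullclines(params: NetworkParams, n: int = 400,
               span: float = SEARCH_SPAN) -> dict[str, np.ndarray]:
    """Sampled zero-level curves of the two nullcline equations.

    Scans grid lines in both directions and refines each sign change by
    bisection.  Returns arrays of (mu_E, mu_I) points under keys ``"F"``
    and ``"G"``.
    """
    gE = _search_grid(params.E, n, span)
    gI = _search_grid(params.I, n, span)
    curves: dict[str, list[tuple[float, float]]] = {"F": [], "G": []}
    for name, fun in (("F", nullcline_F), ("G", nullcline_G)):
        for x in gE:  # scan vertically
            for y in _zero_crossings_1d(lambda t: fun(x, t, params), gI):
                curves[name].append((float(x), y))
        for y in gI:  # scan horizontally
            for x in _zero_crossings_1d(lambda t: fun(t, y, params), gE):
                curves[name].append((x, float(y)))
    return {k: np.array(v).reshape(-1, 2) for k, v in curves.items()}


def potential_bound(params: NetworkParams, margin: float = 2.0) -> float:
    """A box certain to contain every equilibrium membrane potential.

    Since activations lie in (0, nu_max), any stationary potential obeys
    ``|mu| <= tau (sum_b |J_b| nu_b^max + |I|)``; the bound below majorizes
    both populations and adds a margin.
    """
    j_nu = (abs(params.J_EE) + abs(params.J_EI)) * params.E.nu_max \
        + (abs(params.J_IE) + abs(params.J_II)) * params.I.nu_max
    tau = max(params.E.tau, params.I.tau)
    return tau * (j_nu + max(abs(params.I_E), abs(params.I_I))) + margin


def nullsurfaces(params: NetworkParams, n: int = 40,
                 span: float = SEARCH_SPAN) -> dict[str, np.ndarray]:
    """Sampled zero-level surfaces of the three N_I = 2 stationarity equations.

    The two section coordinates run over the activation-sensitive box
    ``V_T ± span/Lambda``; for each section point the zero crossings along
    the remaining axis are scanned over the full equilibrium bound and
    refined by bisection, giving scattered surface samples
    ``(mu_E, mu_I0, mu_I1)`` under keys ``"F"``, ``"G"``, ``"H"``.
    """
    if params.N_I != 2:
        raise ValueError("nullsurfaces require N_I = 2")
    gE = _search_grid(params.E, n, span)
    gI = _search_grid(params.I, n, span)
    B = potential_bound(params)
    out: dict[str, list[tuple[float, float, float]]] = {"F": [], "G": [], "H": []}
    for i, name in enumerate(("F", "G", "H")):
        # solve for the coordinate the equation is stiffest in:
        # F -> mu_E (axis 0), G -> mu_I0 (axis 1), H -> mu_I1 (axis 2)
        axis = i
        grids = [gE, gI, gI]
        scan = np.linspace(-B, B, max(8 * n, 200))
        others = [g for k, g in enumerate(grids) if k != axis]
        for u in others[0]:
            for v in others[1]:
                def f(t):
                    x = [u, v]
                    x.insert(axis, t)
                    return _secondary_residual(np.array(x), params)[i]
                for t in _zero_crossings_1d(f, scan):
                    x = [float(u), float(v)]
                    x.insert(axis, t)
                    out[name].append(tuple(x))
    return {k: np.array(v).reshape(-1, 3) for k, v in out.items()}


# ---------------------------------------------------------------------------
# stability and continuation
# ---------------------------------------------------------------------------

def classify_stability(eq: EquilibriumPoint, params: NetworkParams,
                       tol: float = 1e-8) -> tuple[str, complex]:
    """Label an equilibrium from its eigenvalue multiset.

    Returns ``(label, leading_eigenvalue)`` with label ``"stable"``,
    ``"unstable"`` or ``"marginal"`` (|max real part| below ``tol``).
    """
    lam = eq.eigenvalues
    k = int(np.argmax(lam.real))
    mx = float(lam[k].real)
    if abs(mx) <= tol:
        return "marginal", complex(lam[k])
    return ("stable" if mx < 0 else "unstable"), complex(lam[k])


@dataclass
class BranchDiagram:
    """Codimension-one branch diagram assembled by parameter sweep.

    ``points`` is a pandas-friendly list of dicts with keys ``branch_id,
    I_E, mu_E, mu_I_0, mu_I_1, stability, lambda_max_real``; ``events``
    lists detected sign changes / folds as dicts with keys ``kind``
    (``"LP" | "H" | "BP"``), ``I_E``, and ``branch_id``.
    """

    points: list[dict]
    events: list[dict]

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.points)


def _primary_events_on_segment(sols_prev, sols_next, I_prev, I_next):
    """Pair up consecutive sweep solutions by proximity."""
    pairs = []
    used = set()
    for a in sols_prev:
        best, bd = None, np.inf
        for k, b in enumerate(sols_next):
            if k in used:
                continue
            d = abs(a.mu_E - b.mu_E) + abs(a.mu_I - b.mu_I)
            if d < bd:
                best, bd = k, d
        if best is not None and bd < 1.5:
            used.add(best)
            pairs.append((a, sols_next[best]))
    return pairs


def branch_continuation(params: NetworkParams, I_E_range: tuple[float, float],
                        step: float = 0.05, secondary: bool | None = None,
                        refine_tol: float = 1e-6) -> BranchDiagram:
    """Natural-parameter sweep of the equilibrium branches in ``I_E``.

    At each current the full multi-start solver runs (seeded Newton warm
    starts would miss branch births); solutions are linked between steps by
    proximity.  Sign changes of the mean-mode pair's max real part (LP/H
    candidates) and of the inhibitory difference-mode eigenvalue
    ``lambda_I`` (BP candidates) are refined by bisection in ``I_E``.
    Fold locations (branch terminations) are refined by bisection on
    continued existence of a nearby solution.

    ``secondary=None`` enables the N_I = 2 secondary solver automatically
    when ``psi >= 1``.
    """
    lo, hi = I_E_range
    if hi <= lo:
        raise ValueError("I_E range must be increasing")
    if secondary is None:
        secondary = psi(params) >= 1.0 and params.N_I == 2

    currents = np.arange(lo, hi + step / 2, step)

    def solve_all(I_E):
        p = params.with_inputs(I_E=I_E)
        pts = solve_primary(p, n_grid=15)
        if secondary:
            prim_keys = {(round(q.mu_E, 5), round(q.mu_I, 5)) for q in pts}
            for q in solve_secondary_ni2(p, n_grid=8):
                if len(q.partition.clusters) == 1:
                    if (round(q.mu_E, 5), round(q.mu_I, 5)) in prim_keys:
                        continue
                pts.append(q)
        return pts

    sweep = [solve_all(I) for I in currents]

    points: list[dict] = []
    events: list[dict] = []

    def record(I_E, eq: EquilibriumPoint, branch_id: int):
        vals = eq.mu_I_values
        mu0 = vals[0]
        mu1 = vals[-1] if len(vals) > 1 else vals[0]
        label, lead = classify_stability(eq, params)
        points.append({
            "branch_id": branch_id, "I_E": float(I_E), "mu_E": eq.mu_E,
            "mu_I_0": mu0, "mu_I_1": mu1, "stability": label,
            "lambda_max_real": float(np.max(eq.eigenvalues.real)),
        })

    for i, (I_E, sols) in enumerate(zip(currents, sweep)):
        for j, eq in enumerate(sols):
            record(I_E, eq, j)

    for i in range(len(currents) - 1):
        for a, b in _primary_events_on_segment(
                [s for s in sweep[i] if len(s.partition.clusters) == 1],
                [s for s in sweep[i + 1] if len(s.partition.clusters) == 1],
                currents[i], currents[i + 1]):
            ea = eigenvalues_primary(a.mu_E, a.mu_I, params)
            eb = eigenvalues_primary(b.mu_E, b.mu_I, params)
            # BP candidate: lambda_I sign change
            if ea.lambda_I * eb.lambda_I < 0:
                I_star = _bisect_primary_sign(
                    params, a, currents[i], currents[i + 1],
                    lambda e: e.lambda_I, refine_tol)
                events.append({"kind": "BP", "I_E": I_star, "branch_id": 0})
            # H candidate: complex pair real part crosses zero
            ra = max(z.real for z in ea.lambda01)
            rb = max(z.real for z in eb.lambda01)
            if ea.discriminant < 0 and eb.discriminant < 0 and ra * rb < 0:
                I_star = _bisect_primary_sign(
                    params, a, currents[i], currents[i + 1],
                    lambda e: max(z.real for z in e.lambda01), refine_tol)
                events.append({"kind": "H", "I_E": I_star, "branch_id": 0})

        # LP candidate: change in the number of primary solutions
        na = len([s for s in sweep[i] if len(s.partition.clusters) == 1])
        nb = len([s for s in sweep[i + 1] if len(s.partition.clusters) == 1])
        if na != nb:
            I_star = _bisect_count(params, currents[i], currents[i + 1],
                                   max(na, nb), refine_tol)
            events.append({"kind": "LP", "I_E": I_star, "branch_id": 0})

    return BranchDiagram(points=points, events=events)


def _track_primary(params: NetworkParams, seed: EquilibriumPoint, I_E: float):
    p = params.with_inputs(I_E=I_E)

    def fun(x):
        return np.array([nullcline_F(x[0], x[1], p), nullcline_G(x[0], x[1], p)])

    sol = optimize.root(fun, np.array([seed.mu_E, seed.mu_I]), method="hybr",
                        options={"xtol": 1e-13})
    if not sol.success or np.max(np.abs(fun(sol.x))) > 1e-9:
        return None
    return sol.x


def _bisect_primary_sign(params, seed, lo, hi, key, tol):
    """Refine I_E where an eigenvalue functional crosses zero along a branch."""

    def f(I_E):
        x = _track_primary(params, seed, I_E)
        if x is None:
            raise RuntimeError("branch tracking failed during refinement")
        e = eigenvalues_primary(x[0], x[1], params.with_inputs(I_E=I_E))
        return key(e)

    try:
        f_lo, f_hi = f(lo), f(hi)
        # the crossing may sit (to noise level) on a sweep grid point
        if abs(f_lo) < 1e-9:
            return lo
        if abs(f_hi) < 1e-9:
            return hi
        if f_lo * f_hi > 0:
            return 0.5 * (lo + hi)
        return float(optimize.brentq(f, lo, hi, xtol=tol))
    except RuntimeError:
        return 0.5 * (lo + hi)


def _bisect_count(params, lo, hi, n_high, tol):
    """Bisect I_E where the number of primary solutions changes (fold)."""
    def count(I_E):
        return len(solve_primary(params.with_inputs(I_E=I_E), n_grid=15))

    c_lo = count(lo)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if count(mid) == c_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
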