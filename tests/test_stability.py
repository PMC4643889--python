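"""Jacobians and spectral stability classification."""

import numpy as np
import pytest

import patchgame as pg
from patchgame.equilibria import Equilibrium
from patchgame.stability import (
    analytic_jacobian,
    case1_interior_stable,
    case1_jacobian,
    classify_stability,
    numeric_jacobian,
)


class TestJacobians:
    def test_boundary_entries_match_closed_form(self, scenario, analyzed):
        """At the all-R1 symmetric boundary state the (p,p) entry is
        -(a11 - a21) - c2 n2/n1 and the frequency block decouples from the
        densities (migration balances exactly on the diagonal)."""
        sys = scenario("fig2i")
        eq = next(e for e in analyzed("fig2i") if e.p == 1.0 and e.q == 1.0)
        J = analytic_jacobian(sys, eq)
        A = sys.gameA
        assert J[0, 0] == pytest.approx(-(A.a11 - A.a21) - sys.c2 * eq.n2 / eq.n1)
        assert J[0, 1] == pytest.approx(sys.c2 * eq.n2 / eq.n1)
        assert J[0, 2] == J[0, 3] == 0.0
        assert J[2, 0] == pytest.approx((2 * A.a11 - A.a12 - A.a21) * eq.n1)
        assert J[2, 2] == pytest.approx(-sys.beta1 * eq.n1 - sys.c2 * eq.n2 / eq.n1)
        assert J[2, 3] == pytest.approx(sys.c2)

    def test_decoupled_limit_is_block_diagonal(self):
        sys = pg.TwoPatchSystem(
            pg.Game2x2(1.5, 1.5, 0, 0), pg.Game2x2(5, 1, 0, 0),
            pg.PatchEnv(1.0, 0.01, 0.0), pg.PatchEnv(2.0, 0.01, 0.0),
        )
        n1, n2 = pg.solve_density(sys, 1.0, 1.0)
        J = analytic_jacobian(sys, np.array([1.0, 1.0, n1, n2]))
        assert J[0, 0] == pytest.approx(-(1.5 - 0.0))
        assert J[1, 1] == pytest.approx(-(5.0 - 0.0))
        assert J[2, 2] == pytest.approx(-sys.beta1 * n1)
        assert J[3, 3] == pytest.approx(-sys.beta2 * n2)
        off = J - np.diag(np.diag(J))
        assert np.max(np.abs(off[:2, 2:])) == 0.0
        assert np.max(np.abs(off[2:, :2])) > 0  # payoff rows stay coupled

    def test_analytic_agrees_with_finite_differences_at_equilibria(self, scenario, analyzed):
        for sid in ("fig2e", "fig2i", "fig3a", "fig3g", "fig4"):
            sys = scenario(sid)
            for eq in analyzed(sid):
                Ja = analytic_jacobian(sys, eq)
                Jn = numeric_jacobian(sys, eq)
                scale = max(1.0, np.max(np.abs(Ja)))
                assert np.max(np.abs(Ja - Jn)) < 1e-6 * scale

    def test_analytic_agrees_at_random_interior_states(self, scenario):
        rng = np.random.default_rng(11)
        for sid in ("fig3b", "fig4"):
            sys = scenario(sid)
            for _ in range(5):
                u = np.array([*rng.uniform(0.05, 0.95, 2), *rng.uniform(5, 100, 2)])
                Ja = analytic_jacobian(sys, u)
                Jn = numeric_jacobian(sys, u)
                assert np.max(np.abs(Ja - Jn)) < 1e-6 * max(1.0, np.max(np.abs(Ja)))

    def test_density_block_spectrum_negative_at_boundary_equilibria(self, scenario, analyzed):
        # the 2x2 density sub-block at a symmetric boundary equilibrium is
        # always spectrally stable
        for sid in ("fig2a", "fig3c", "fig4"):
            sys = scenario(sid)
            for eq in analyzed(sid):
                if eq.kind != "symmetric-boundary":
                    continue
                block = analytic_jacobian(sys, eq)[2:, 2:]
                assert np.max(np.real(np.linalg.eigvals(block))) < 0

    def test_patch_swap_symmetry_of_spectrum(self):
        sys = pg.TwoPatchSystem(
            pg.Game2x2(1, 0, 0, 1), pg.Game2x2(1, 0, 0, 1),
            pg.PatchEnv(1.5, 0.01, 0.3), pg.PatchEnv(1.5, 0.01, 0.3),
        )
        n1, n2 = pg.solve_density(sys, 0.2, 0.7)
        e1 = np.linalg.eigvals(analytic_jacobian(sys, np.array([0.2, 0.7, n1, n2])))
        e2 = np.linalg.eigvals(analytic_jacobian(sys, np.array([0.7, 0.2, n2, n1])))
        assert np.allclose(sorted(e1.real), sorted(e2.real), atol=1e-9)


class TestClassification:
    def test_dominance_scenario_boundary_labels(self, analyzed):
        # all-R1 state stable, all-R2 state unstable when R1 dominates both games
        eqset = analyzed("fig2a")
        labels = {(e.p, e.q): e.stability for e in eqset}
        assert labels[(1.0, 1.0)] == "stable"
        assert labels[(0.0, 0.0)] == "unstable"

    def test_shared_interior_ess_gives_stable_symmetric_interior(self, analyzed):
        eq = next(e for e in analyzed("fig3a") if e.kind == "symmetric-interior")
        assert eq.stability == "stable"

    def test_case1_trace_det_conditions_agree_with_spectrum(self, scenario, analyzed):
        checked = 0
        for sid in ("fig2c", "fig2e", "fig2i", "fig2j", "fig2l", "case1-sixeq"):
            sys = scenario(sid)
            for e in analyzed(sid):
                if 0 < e.q < 1 and e.branch is not None:
                    assert case1_interior_stable(sys, e) == (e.stability == "stable")
                    # 2x2 subsystem spectrum consistent with the 4x4 labels
                    tr = np.trace(case1_jacobian(sys, e))
                    if e.stability == "stable":
                        assert tr < 0
                    checked += 1
        assert checked >= 8

    def test_marginal_spectrum_is_reported_not_forced(self, scenario):
        # a payoff tie in patch 1 puts a zero eigenvalue at the all-R1 state
        sys = pg.TwoPatchSystem(
            pg.Game2x2(1, 0, 1, 0), pg.Game2x2(5, 1, 0, 0),
            pg.PatchEnv(1.0, 0.01, 0.0), pg.PatchEnv(2.0, 0.01, 0.0),
        )
        n1, n2 = pg.solve_density(sys, 1.0, 1.0)
        eq = Equilibrium(1.0, 1.0, n1, n2, "symmetric-boundary", 0.0)
        assert classify_stability(sys, eq).label == "marginal"


@pytest.fixture(scope="module")
def regime_systems():
    scens = pg.generate_regime_scenarios(seed=2, c=(0.3, 0.4))
    return {pg.classify_pair(s.sys).label: s.sys for s in scens}


class TestTheorems:
    """Stability statements that hold for every admissible parameter set,
    checked over the randomized regime fixtures with two-way migration."""

    def test_shared_pure_ess_implies_stable_boundary(self, regime_systems):
        for label, sys in regime_systems.items():
            rep_a = pg.classify_game(sys.gameA)
            rep_b = pg.classify_game(sys.gameB)
            eqs = {(e.p, e.q): e for e in pg.symmetric_equilibria(sys)}
            if rep_a.r1_pure_ess and rep_b.r1_pure_ess:
                eq = eqs[(1.0, 1.0)]
                classify_stability(sys, eq)
                assert eq.stability == "stable", label
            if rep_a.r2_pure_ess and rep_b.r2_pure_ess:
                eq = eqs[(0.0, 0.0)]
                classify_stability(sys, eq)
                assert eq.stability == "stable", label

    def test_shared_interior_ess_implies_stable_interior(self):
        # build hawk-dove pairs with matching interior ESS directly
        rng = np.random.default_rng(3)
        for _ in range(5):
            a12, a21 = rng.uniform(0.5, 5.0, 2)
            scale = rng.uniform(0.5, 3.0)
            A = pg.Game2x2(0.0, a12, a21, 0.0)
            B = pg.Game2x2(0.0, scale * a12, scale * a21, 0.0)  # same p*
            sys = pg.TwoPatchSystem(A, B, pg.PatchEnv(1.2, 0.01, 0.3),
                                    pg.PatchEnv(1.5, 0.01, 0.4))
            eq = next(e for e in pg.symmetric_equilibria(sys)
                      if e.kind == "symmetric-interior")
            classify_stability(sys, eq)
            assert eq.stability == "stable"

    def test_migration_can_stabilize_a_non_ess_boundary(self):
        """With a11 slightly below a21 (R1 not an ESS in patch 1) but R1
        dominant in patch 2, some migration rates still make the all-R1
        state attracting."""
        A = pg.Game2x2(1.0, 0.0, 1.02, 0.0)   # a21 - a11 = 0.02, small
        B = pg.Game2x2(3.0, 1.0, 0.0, 0.0)    # R1 ESS
        found = False
        for c in np.linspace(0.05, 0.9, 12):
            sys = pg.TwoPatchSystem(A, B, pg.PatchEnv(1.0, 0.01, c),
                                    pg.PatchEnv(2.0, 0.01, c))
            eq = next(e for e in pg.symmetric_equilibria(sys)
                      if e.p == 1.0 and e.q == 1.0)
            if classify_stability(sys, eq).label == "stable":
                found = True
                break
        assert found
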