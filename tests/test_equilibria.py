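"""Density subsystem, equilibrium enumeration routes, and the reduced-curve
candidate census."""

import numpy as np
import pytest

import patchgame as pg
from patchgame.equilibria import RESIDUAL_TOL, case1_equilibria, curve_intersections
from conftest import FIG2_IDS


def quartic_positive_density_roots(sys, p, q):
    """Independent oracle for the density subsystem with two-way migration:
    substitute the patch-1 balance into the patch-2 balance and read all
    roots of the resulting quartic off its companion matrix."""
    fbar = sys.gameA.mean_payoff(p)
    gbar = sys.gameB.mean_payoff(q)
    a1 = fbar + sys.alpha1 - sys.c1
    a2 = gbar + sys.alpha2 - sys.c2
    b1, b2, c1, c2 = sys.beta1, sys.beta2, sys.c1, sys.c2
    # n2 = (b1 n1^2 - a1 n1) / c2; residual of the patch-2 balance:
    coeffs = [
        -b2 * b1**2 / c2**2,
        2 * b2 * b1 * a1 / c2**2,
        -b2 * a1**2 / c2**2 + a2 * b1 / c2,
        -a2 * a1 / c2 + c1,
        0.0,
    ]
    roots = np.roots(coeffs)
    out = []
    for r in roots:
        if abs(r.imag) > 1e-9 or r.real <= 1e-9:
            continue
        n1 = r.real
        n2 = n1 * (b1 * n1 - a1) / c2
        if n2 > 1e-9:
            out.append((n1, n2))
    return out


class TestSolveDensity:
    def test_decoupled_logistic_closed_form(self):
        sysd = pg.TwoPatchSystem(
            pg.Game2x2(1, 0, 0, 1), pg.Game2x2(2, 0, 0, 1),
            pg.PatchEnv(1.75, 0.05, 0.0), pg.PatchEnv(2.0, 0.01, 0.0),
        )
        n1, n2 = pg.solve_density(sysd, 1.0, 1.0)
        assert n1 == pytest.approx((1.75 + 1.0) / 0.05)   # 55
        assert n2 == pytest.approx((2.0 + 2.0) / 0.01)    # 400... per-patch logistic

    def test_constant_payoff_two_way_case_has_positive_root(self, scenario):
        # density illustration fixtures: unique positive intersection of the
        # two density parabolas, residual certified
        for sid in ("fig1a", "fig1b"):
            sys = scenario(sid)
            n1, n2 = pg.solve_density(sys, 0.5, 0.5)
            assert n1 > 0 and n2 > 0
            u = np.array([0.5, 0.5, n1, n2])
            assert np.max(np.abs(pg.vector_field_frequency(sys, u)[2:])) < 1e-10

    def test_trivial_root_excluded(self, scenario):
        n1, n2 = pg.solve_density(scenario("fig4"), 0.3, 0.7)
        assert min(n1, n2) > 1.0

    TWO_WAY = ["fig1a", "fig1b"] + [f"fig3{c}" for c in "abcdefgh"] + ["fig4"]

    @pytest.mark.parametrize("sid", TWO_WAY)
    def test_uniqueness_on_grid_against_quartic_oracle(self, scenario, sid):
        """On a 21x21 frequency grid the positive root is unique and matches
        the companion-matrix roots of the quartic reduction (the reduction
        applies to the two-way-migration scenarios)."""
        sys = scenario(sid)
        for p in np.linspace(0, 1, 21):
            for q in np.linspace(0, 1, 21):
                oracle = quartic_positive_density_roots(sys, p, q)
                assert len(oracle) == 1
                n1, n2 = pg.solve_density(sys, p, q)
                assert n1 == pytest.approx(oracle[0][0], rel=1e-8)
                assert n2 == pytest.approx(oracle[0][1], rel=1e-8)


class TestSymmetricEquilibria:
    def test_boundary_pair_always_present_with_small_residual(self, scenario):
        for sid in ("fig2a", "fig3c", "fig4"):
            eqs = pg.symmetric_equilibria(scenario(sid))
            coords = {(e.p, e.q) for e in eqs}
            assert {(0.0, 0.0), (1.0, 1.0)} <= coords
            assert all(e.residual < 1e-9 for e in eqs)

    def test_interior_symmetric_only_when_rest_points_coincide(self, scenario):
        # fig4 games: p* = 1/2 != q* = 1/3 -> no symmetric interior
        assert len(pg.symmetric_equilibria(scenario("fig4"))) == 2
        # fig3a games: both hawk-dove with p* = q* = 1/2
        eqs = pg.symmetric_equilibria(scenario("fig3a"))
        assert any(e.kind == "symmetric-interior" and e.p == pytest.approx(0.5)
                   for e in eqs)


class TestCase1:
    def test_wrong_migration_pattern_rejected(self, scenario):
        with pytest.raises(pg.DomainError):
            case1_equilibria(scenario("fig4"))

    @pytest.mark.parametrize(
        "sid, n_interior_q",
        [("fig2a", 0), ("fig2b", 0), ("fig2c", 1), ("fig2e", 1), ("fig2i", 2),
         ("fig2j", 2), ("fig2l", 3), ("case1-sixeq", 4)],
    )
    def test_interior_root_multiplicities(self, analyzed, sid, n_interior_q):
        eqset = analyzed(sid)
        assert sum(0 < e.q < 1 for e in eqset) == n_interior_q

    def test_boundary_q_roots_only_on_matching_boundary_branch(self, analyzed):
        # a q root at 0 or 1 occurs exactly when the patch-1 branch sits at
        # the same boundary, i.e. only the two symmetric boundary states
        for sid in FIG2_IDS:
            for e in analyzed(sid):
                if e.q in (0.0, 1.0):
                    assert e.p == e.q and e.kind == "symmetric-boundary"

    def test_all_branches_option_reveals_unstable_branch_equilibria(self, scenario):
        sys = scenario("fig2i")
        full = case1_equilibria(sys, branches="all")
        default = case1_equilibria(sys)
        assert len(default) == 4
        assert len(full) == 7
        extra = [e for e in full if e.branch == pytest.approx(0.5)]
        assert len(extra) == 3  # equilibria riding the unstable p* branch

    def test_residual_certificates(self, analyzed):
        for sid in FIG2_IDS:
            assert all(e.residual < RESIDUAL_TOL for e in analyzed(sid))


class TestDecoupled:
    def test_three_by_three_product_structure(self, scenario):
        sys = pg.with_migration(scenario("fig4"), 0.0)
        eqset = pg.decoupled_equilibria(sys)
        assert len(eqset) == 9
        ps = sorted({e.p for e in eqset})
        qs = sorted({e.q for e in eqset})
        assert ps == pytest.approx([0.0, 0.5, 1.0])
        assert qs == pytest.approx([0.0, 1 / 3, 1.0])
        # per-patch logistic densities
        for e in eqset:
            assert e.n1 == pytest.approx((sys.alpha1 + sys.gameA.mean_payoff(e.p)) / sys.beta1)


class TestGeneral:
    def test_fig4_positive_census(self, analyzed):
        eqset = analyzed("fig4")
        assert eqset.n_total == 9
        assert eqset.n_interior == 7
        assert all(e.residual < RESIDUAL_TOL for e in eqset)

    def test_no_asymmetric_boundary_equilibria(self, analyzed):
        for sid in ("fig3d", "fig3g", "fig4"):
            for e in analyzed(sid):
                if e.p in (0.0, 1.0) or e.q in (0.0, 1.0):
                    assert e.p == e.q

    def test_sign_identity_at_interior_equilibria(self, scenario, analyzed):
        """Every interior equilibrium with two-way migration satisfies
        D1 D2 p(1-p)q(1-q)(p-p*)(q-q*) = -c1 c2 (p-q)^2."""
        checked = 0
        for sid in ("fig3d", "fig3e", "fig3g", "fig3h", "fig4"):
            sys = scenario(sid)
            pa = pg.classify_game(sys.gameA).interior_candidate
            qa = pg.classify_game(sys.gameB).interior_candidate
            for e in analyzed(sid).interior():
                lhs = (sys.gameA.delta * sys.gameB.delta * e.p * (1 - e.p)
                       * e.q * (1 - e.q) * (e.p - pa) * (e.q - qa))
                rhs = -sys.c1 * sys.c2 * (e.p - e.q) ** 2
                assert lhs == pytest.approx(rhs, abs=1e-9)
                checked += 1
        assert checked >= 10

    def test_exchange_symmetry_for_identical_patches(self):
        sys = pg.TwoPatchSystem(
            pg.Game2x2(1, 0, 0, 1), pg.Game2x2(1, 0, 0, 1),
            pg.PatchEnv(1.5, 0.01, 0.3), pg.PatchEnv(1.5, 0.01, 0.3),
        )
        eqset = pg.general_equilibria(sys)
        states = {(round(e.p, 8), round(e.q, 8), round(e.n1, 4), round(e.n2, 4))
                  for e in eqset}
        swapped = {(q, p, n2, n1) for (p, q, n1, n2) in states}
        assert states == swapped


class TestCurveIntersections:
    def test_fig4_candidate_census_and_positive_subset(self, scenario):
        """The planar reduction has 10 interior intersections at the
        bifurcation-template rates (12 counting the two boundary states);
        only 7 carry positive densities and are genuine equilibria."""
        xs = curve_intersections(scenario("fig4"))
        assert len(xs) == 10
        assert sum(x.positive for x in xs) == 7
        negative = [x for x in xs if not x.positive]
        assert all(min(x.n1, x.n2) <= 0 for x in negative)

    def test_positive_intersections_match_enumerated_interior(self, scenario, analyzed):
        xs = [x for x in curve_intersections(scenario("fig4")) if x.positive]
        interior = analyzed("fig4").interior()
        assert len(xs) == len(interior)
        for x in xs:
            assert any(abs(x.p - e.p) < 1e-6 and abs(x.q - e.q) < 1e-6
                       for e in interior)
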