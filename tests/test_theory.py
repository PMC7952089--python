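import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magicratio.errors import UsageError
from magicratio.theory import (
    AssociationState,
    SpeciesConcentrations,
    TheoryParams,
    association_residuals,
    dimer_fraction,
    dissociation_constant_from_potential,
    effective_valence,
    f_noninteracting,
    f_nonspecific,
    f_specific,
    f_total,
    limiting_f_specific,
    skewed_transition,
    solve_association,
    transition_concentration,
)
from magicratio.units import MM_PER_COUNT_PER_NM3

from conftest import grid_minimize_fs, random_theory_draw


def params(L1=2, L2=2, Kd=1.0, Kb=1.0, vb=0.0, wb=0.0):
    return TheoryParams(L1=L1, L2=L2, Kd=Kd, Kb=Kb, vb_ns=vb, wb_ns=wb)


class TestNonInteracting:
    def test_zero_limit(self):
        assert f_noninteracting(SpeciesConcentrations(0, 0), params()).value == 0.0

    def test_log_argument_one(self):
        p = params(L1=3, L2=2)
        c = SpeciesConcentrations(math.e * 3, math.e * 2)
        assert f_noninteracting(c, p).value == pytest.approx(0.0, abs=1e-12)

    def test_single_species_unit(self):
        p = params(L1=1, L2=1)
        c = SpeciesConcentrations(1.0, 0.0)
        assert f_noninteracting(c, p).value == pytest.approx(-1.0)


class TestSolveAssociation:
    def test_degenerate_zero_species(self):
        st_ = solve_association(SpeciesConcentrations(0.0, 5.0), params())
        assert (st_.cd1, st_.cd2, st_.cb) == (0.0, 0.0, 0.0)

    def test_quadratic_closed_form(self):
        # L1 = L2 = 2, bonds suppressed: Kd rho_d = (1 - rho_d)^2
        p = params(L1=2, L2=2, Kd=1.0, Kb=1e9)
        st_ = solve_association(SpeciesConcentrations(2.0, 2.0), p)
        rho_d = (3.0 - math.sqrt(5.0)) / 2.0
        assert st_.cd1 / 2.0 == pytest.approx(rho_d, rel=1e-7)
        assert st_.cd1 == pytest.approx(st_.cd2)
        assert st_.cd1 == pytest.approx(0.76393, rel=1e-4)

    def test_matches_grid_minimizer(self, rng):
        for _ in range(30):
            c, p = random_theory_draw(rng)
            st_ = solve_association(c, p)
            f_solver = f_specific(c, st_, p).value
            f_grid = grid_minimize_fs(c, p, n=200)
            scale = max(abs(f_grid), 1e-6)
            assert f_solver <= f_grid + 1e-9 * scale
            assert f_grid - f_solver <= 2e-4 * scale

    def test_residuals_below_tolerance(self, rng):
        for _ in range(50):
            c, p = random_theory_draw(rng)
            st_ = solve_association(c, p)
            r7, r8 = association_residuals(c, p, st_)
            if st_.cd1 > 0:
                assert abs(r7) < 1e-8
            assert abs(r8) < 1e-8

    def test_dimer_mass_action_reduction_when_bonds_suppressed(self, rng):
        # Kb huge -> cb ~ 0; solution obeys Kd rho_d = (rho1-rho_d)(rho2-rho_d)
        for _ in range(20):
            c, p = random_theory_draw(rng)
            p = TheoryParams(p.L1, p.L2, p.Kd, 1e12)
            st_ = solve_association(c, p)
            rd = st_.rho_d(p)
            rmax = min(c.rho1(p), c.rho2(p))
            if rd == 0 or rd > rmax * (1 - 1e-6):
                continue  # saturated: residual is cancellation-limited
            lhs = p.Kd * rd
            rhs = (c.rho1(p) - rd) * (c.rho2(p) - rd)
            assert lhs == pytest.approx(rhs, rel=1e-8)

    def test_bond_mass_action_reduction_when_dimers_suppressed(self, rng):
        for _ in range(20):
            c, p = random_theory_draw(rng)
            p = TheoryParams(p.L1, p.L2, 1e15, p.Kb)
            st_ = solve_association(c, p)
            assert st_.cd1 < 1e-10 * max(c.c1, 1.0)
            lhs = p.Kb * st_.cb
            rhs = (c.c1 - st_.cb) * (c.c2 - st_.cb)
            assert lhs == pytest.approx(rhs, rel=1e-8)


class TestFSpecific:
    def test_no_association_is_zero(self):
        # Z_s = 1 when nothing associates
        c = SpeciesConcentrations(3.0, 4.0)
        v = f_specific(c, AssociationState(0, 0, 0), params(L1=4, L2=2))
        assert v.value == pytest.approx(0.0, abs=1e-14)

    def test_all_dimer_equals_dimer_limit(self):
        # equal valence, equal stoichiometry, all-dimer state
        p = params(L1=3, L2=3, Kd=0.01, Kb=1.0)
        c = SpeciesConcentrations(0.3, 0.3)
        rho = c.c1 / 3.0
        full = f_specific(c, AssociationState(c.c1, c.c2, 0.0), p).value
        # rho ln(Kd e / rho)
        assert full == pytest.approx(rho * math.log(p.Kd * math.e / rho), rel=1e-12)
        lim = limiting_f_specific(c, p, "dimer").value
        assert full == pytest.approx(lim, rel=1e-12)

    def test_finite_size_partition_function_oracle(self):
        """Independent oracle: -ln Zs / V from exact lgamma combinatorics
        at large V converges to the Stirling expression."""
        from math import lgamma

        p = params(L1=3, L2=2, Kd=0.37, Kb=1.3)
        c = SpeciesConcentrations(4.0, 3.0)
        st_ = solve_association(c, p)
        rd, cb = st_.cd1 / p.L1, st_.cb

        V = 1e9
        N1, N2 = c.c1 * V, c.c2 * V
        nd = rd * V
        nb = cb * V

        def lnC(n, k):
            return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)

        # vd = vb = 1, eps = -ln K
        ln_zs = (
            lnC(N1 / p.L1, nd)
            + lnC(N2 / p.L2, nd)
            + lgamma(nd + 1)
            + lnC(N1 - p.L1 * nd, nb)
            + lnC(N2 - p.L2 * nd, nb)
            + lgamma(nb + 1)
            + nd * math.log(1.0 / V)
            + nb * math.log(1.0 / V)
            - nd * math.log(p.Kd)
            - nb * math.log(p.Kb)
        )
        oracle = -ln_zs / V
        value = f_specific(c, st_, p).value
        assert value == pytest.approx(oracle, rel=1e-6)

    def test_infeasible_state_rejected(self):
        c = SpeciesConcentrations(1.0, 1.0)
        with pytest.raises(UsageError):
            f_specific(c, AssociationState(2.0, 2.0, 0.0), params())


class TestFNonspecific:
    def test_zero(self):
        assert f_nonspecific(SpeciesConcentrations(0, 0), params()).value == 0.0

    def test_reference_values(self):
        p = params(vb=9e-2, wb=7e-3)
        v = f_nonspecific(SpeciesConcentrations(10.0, 10.0), p).value
        assert v == pytest.approx(4.5 + 7.0 / 6.0, rel=1e-12)

    def test_max_rule(self):
        p = params(vb=0.1, wb=0.01)
        v = f_nonspecific(SpeciesConcentrations(4.0, 2.0), p).value
        assert v == pytest.approx(0.05 * 16 + 0.01 / 6 * 64, rel=1e-12)


class TestFTotal:
    def test_no_association_limit(self):
        p = params(Kd=1e290, Kb=1e290, vb=0.05, wb=0.01)
        c = SpeciesConcentrations(3.0, 5.0)
        expect = f_noninteracting(c, p).value + f_nonspecific(c, p).value
        assert f_total(c, p).value == pytest.approx(expect, rel=1e-9)

    def test_component_additivity(self, rng):
        for _ in range(25):
            c, p = random_theory_draw(rng)
            p = TheoryParams(p.L1, p.L2, p.Kd, p.Kb, 0.03, 0.002)
            st_ = solve_association(c, p)
            total = f_total(c, p).value
            parts = (
                f_noninteracting(c, p).value
                + f_specific(c, st_, p).value
                + f_nonspecific(c, p).value
            )
            assert total == pytest.approx(parts, rel=1e-10, abs=1e-12)

    def test_species_swap_symmetry(self, rng):
        for _ in range(10):
            c, p = random_theory_draw(rng)
            p_sym = TheoryParams(p.L1, p.L1, p.Kd, p.Kb, 0.01, 0.001)
            a = f_total(SpeciesConcentrations(c.c1, c.c2), p_sym).value
            b = f_total(SpeciesConcentrations(c.c2, c.c1), p_sym).value
            assert a == pytest.approx(b, rel=1e-10, abs=1e-12)


class TestLimits:
    def test_dimer_zero_at_kde(self):
        p = params(L1=2, L2=2, Kd=0.7)
        rho = p.Kd * math.e
        c = SpeciesConcentrations(2 * rho, 2 * rho)
        assert limiting_f_specific(c, p, "dimer").value == pytest.approx(0, abs=1e-12)

    def test_independent_zero_at_kbe(self):
        p = params(Kb=0.2)
        cval = p.Kb * math.e
        c = SpeciesConcentrations(cval, cval)
        assert limiting_f_specific(c, p, "independent").value == pytest.approx(
            0, abs=1e-12
        )

    def test_sandwich_in_strong_binding(self):
        """Full Fs within 1% of min(dimer, independent) at strong binding,
        and never above it (the limits are feasible states of the
        minimisation).  Compositions within a factor 2 of the dimer/gel
        crossover c_s are excluded: exactly at the transition the mixed
        optimum genuinely undercuts the limiting envelope by a few
        percent (checked separately with a 3% global bound)."""
        import magicratio.theory as th

        Kb = 3.8e-3
        L = 8
        Kd = th.dimer_kd_from_crossover(L, Kb, 4.0)
        p = TheoryParams(L, L, Kd, Kb)
        c0 = transition_concentration(L, Kd, Kb)
        for ctot in np.geomspace(0.5, 30.0, 30):
            for s in [1.0, 1.2, 1.5, 2.0]:
                c = SpeciesConcentrations(ctot * s / (1 + s), ctot / (1 + s))
                st_ = solve_association(c, p)
                full = f_specific(c, st_, p).value
                lo = min(
                    limiting_f_specific(c, p, "dimer").value,
                    limiting_f_specific(c, p, "independent").value,
                )
                scale = abs(lo)
                assert full <= lo + 1e-9 * scale + 1e-12
                assert full >= lo - 0.03 * scale - 1e-12
                cs = skewed_transition(c0, s)
                if not (0.5 < ctot / cs < 2.0):
                    assert full >= lo - 0.01 * scale - 1e-12


class TestTransitions:
    def test_unit_ratio(self):
        assert transition_concentration(2, 0.5, 1.0) == pytest.approx(math.e)

    def test_defining_identity(self):
        for L, Kd, Kb in [(2, 0.3, 1.0), (4, 1e-6, 0.02), (8, 1e-20, 3.8e-3)]:
            c0 = transition_concentration(L, Kd, Kb)
            p = params(L1=L, L2=L, Kd=Kd, Kb=Kb)
            c = SpeciesConcentrations(c0, c0)
            fd = limiting_f_specific(c, p, "dimer").value
            fi = limiting_f_specific(c, p, "independent").value
            assert fd == pytest.approx(fi, rel=1e-10)

    def test_kb_power_scaling(self):
        base = transition_concentration(3, 0.1, 1.0)
        doubled = transition_concentration(3, 0.1, 2.0)
        assert doubled / base == pytest.approx(2 ** 1.5, rel=1e-12)

    def test_l1_domain_error(self):
        with pytest.raises(UsageError):
            transition_concentration(1, 0.1, 1.0)

    def test_skew_limit_and_quarter(self):
        assert skewed_transition(5.0, 1.0) == pytest.approx(5.0)
        assert skewed_transition(5.0, 2.0) == pytest.approx(1.25)

    def test_skew_monotone_decreasing(self):
        s = np.linspace(1.0, 10.0, 200)
        cs = np.array([skewed_transition(1.0, v) for v in s])
        assert np.all(np.diff(cs) < 0)

    def test_skew_domain(self):
        with pytest.raises(UsageError):
            skewed_transition(1.0, 0.5)


class TestDimerFraction:
    def test_dilution_limit(self):
        p = params(L1=2, L2=2, Kd=1.0, Kb=1e6)
        fr = dimer_fraction(SpeciesConcentrations(1e-6, 1e-6), p)
        assert fr < 1e-3

    def test_strong_binding_below_cs(self):
        Kd, Kb = 1e-12, 1e-2
        p = params(L1=4, L2=4, Kd=Kd, Kb=Kb)
        c0 = transition_concentration(4, Kd, Kb)
        c = SpeciesConcentrations(c0 / 4.0, c0 / 4.0)
        assert dimer_fraction(c, p) > 0.9

    def test_ridge_on_diagonal(self):
        # high-fraction ridge hugs c1 = c2 for equal valences
        Kd, Kb = 1e-12, 1e-2
        p = params(L1=4, L2=4, Kd=Kd, Kb=Kb)
        c0 = transition_concentration(4, Kd, Kb)
        on = dimer_fraction(SpeciesConcentrations(0.8 * c0, 0.8 * c0), p)
        off = dimer_fraction(SpeciesConcentrations(1.28 * c0, 0.32 * c0), p)
        assert on > 0.9
        assert on > off

    def test_zero_total_rejected(self):
        with pytest.raises(UsageError):
            dimer_fraction(SpeciesConcentrations(0, 0), params())


class TestEffectiveValence:
    def test_reference(self):
        v = effective_valence(14, 1.8)
        assert v == pytest.approx(7.78, abs=0.005)
        assert round(v) == 8

    def test_identity(self):
        assert effective_valence(8, 1.0) == 8

    def test_other(self):
        assert effective_valence(8, 1.8) == pytest.approx(4.44, abs=0.005)


class TestDissociationConstant:
    def test_zero_depth_gives_inverse_volume(self):
        kd = dissociation_constant_from_potential(U0=0.0)
        from magicratio.potentials import ATTRACTION_RANGE

        vol = 4.0 / 3.0 * math.pi * ATTRACTION_RANGE**3
        assert kd == pytest.approx(MM_PER_COUNT_PER_NM3 / vol, rel=1e-8)

    def test_anchor_at_u0_9(self):
        assert dissociation_constant_from_potential(U0=9.0) == pytest.approx(
            0.40, abs=0.005
        )

    def test_strictly_decreasing_in_depth(self):
        kds = [dissociation_constant_from_potential(U0=u) for u in range(0, 15, 2)]
        assert all(a > b for a, b in zip(kds, kds[1:]))


@settings(max_examples=30, deadline=None)
@given(
    c1=st.floats(0.0, 20.0),
    c2=st.floats(0.0, 20.0),
    logkd=st.floats(-15, 2),
    logkb=st.floats(-4, 2),
    L1=st.integers(1, 8),
    L2=st.integers(1, 8),
)
def test_property_solver_feasible_and_consistent(c1, c2, logkd, logkb, L1, L2):
    if L1 < L2:
        L1, L2 = L2, L1
    p = TheoryParams(L1, L2, 10.0**logkd, 10.0**logkb)
    c = SpeciesConcentrations(c1, c2)
    st_ = solve_association(c, p)
    st_.validate(c, p)
    assert 0.0 <= st_.cd1 <= c1 + 1e-12
    assert 0.0 <= st_.cb <= min(c1 - st_.cd1, c2 - st_.cd2) + 1e-9
    # free energy at solution never exceeds the no-association value (0)
    assert f_specific(c, st_, p).value <= 1e-12
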