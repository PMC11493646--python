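"""QSS and invariant-manifold reductions: kappa, lifts, invariance, exactness."""

import itertools

import numpy as np
import pytest

from hetkv import (
    ChannelComposition,
    FullMarkovModel,
    InactivatingRates,
    ManifoldReducedModel,
    PlainRates,
    ProtocolSpec,
    QSSReducedModel,
    RateLaw,
    SubunitRates,
    VoltageSegment,
    build_generator,
    enumerate_states,
    invariance_residual,
    manifold_lift,
    manifold_lift_jacobian,
    manifold_open_probability,
    manifold_rhs,
    qss_kappa,
    run_inactivation,
    run_recovery,
    simulate,
)

from conftest import interior_gating_state


def equal_rate_bundle(act=1.0, inact=0.01):
    c = RateLaw.constant
    return SubunitRates(
        plain=PlainRates(c(act), c(act)),
        inactivating=InactivatingRates(c(act), c(act), c(inact), c(inact)),
    )


# ---------------------------------------------------------------------------
# QSS
# ---------------------------------------------------------------------------

class TestQSS:
    def test_homomer_kappa_closed_form(self, ntype_rates):
        comp = ChannelComposition.n_type(4)
        V = -10.0
        ir = ntype_rates.inactivating
        a1, b1 = ir.a1(V), ir.b1(V)
        assert qss_kappa(comp, ntype_rates, V) == pytest.approx(
            (a1 + b1) ** 4 / a1 ** 4, rel=1e-12)

    def test_equal_rates_give_kappa_sixteen(self):
        assert qss_kappa(ChannelComposition.n_type(4), equal_rate_bundle(), 0.0) == \
            pytest.approx(16.0)

    def test_heteromer_kappa_matches_chain_equilibrium_oracle(self):
        """kappa is 1 / (conditional open fraction): compare with the
        stationary distribution of the activation chain with the ball
        transitions removed."""
        rates = equal_rate_bundle()
        comp = ChannelComposition.n_type(2)
        no_ball = SubunitRates(
            plain=rates.plain,
            inactivating=InactivatingRates(rates.inactivating.a1,
                                           rates.inactivating.b1,
                                           RateLaw.constant(0.0),
                                           RateLaw.constant(0.0)))
        model = FullMarkovModel(comp, no_ball)
        with pytest.warns(RuntimeWarning):  # I state disconnected: 2-dim null space
            P = model.stationary(0.0)
        O = P[model.space.conducting_index]
        X = 1.0 - P[model.space.inactive_index]  # mass in the activation chain
        assert qss_kappa(comp, rates, 0.0) == pytest.approx(X / O, rel=1e-6)
        assert qss_kappa(comp, rates, 0.0) == pytest.approx(16.0)

    def test_kappa_at_least_one_everywhere(self, ntype_rates):
        for n in range(5):
            comp = ChannelComposition.n_type(n)
            for V in (-120.0, -60.0, 0.0, 60.0):
                assert qss_kappa(comp, ntype_rates, V) >= 1.0

    def test_pure_recovery_when_ball_binding_removed(self):
        rates = SubunitRates(
            plain=None,
            inactivating=InactivatingRates(RateLaw.constant(1.0), RateLaw.constant(1.0),
                                           RateLaw.constant(0.0), RateLaw.constant(0.5)))
        model = QSSReducedModel(ChannelComposition.n_type(4), rates)
        t = np.linspace(0.0, 10.0, 30)
        X = model.propagate(np.array([0.2]), 0.0, t)[:, 0]
        np.testing.assert_allclose(X, 1.0 - 0.8 * np.exp(-0.5 * t), atol=1e-12)

    def test_stationary_balances_binding_and_unbinding(self, ntype_rates):
        comp = ChannelComposition.n_type(2)
        model = QSSReducedModel(comp, ntype_rates)
        V = 50.0
        ir = ntype_rates.inactivating
        kappa = qss_kappa(comp, ntype_rates, V)
        expected = ir.bI(V) / (ir.bI(V) + 2 * ir.aI(V) / kappa)
        assert model.stationary(V)[0] == pytest.approx(expected, rel=1e-12)

    def test_qss_availability_curve_tracks_full_model(self, ntype_rates):
        comp = ChannelComposition.n_type(2)
        spec = ProtocolSpec(V_steps=(-90.0, -30.0, 0.0, 50.0))
        full = run_inactivation(FullMarkovModel(comp, ntype_rates), spec)
        red = run_inactivation(QSSReducedModel(comp, ntype_rates), spec)
        assert np.abs(full.ratio - red.ratio).max() < 0.05


# ---------------------------------------------------------------------------
# Manifold
# ---------------------------------------------------------------------------

def subunit_configuration_lift(m, p, q, n, h):
    """Oracle: probability of each (i, j, k) by enumerating independent
    subunit configurations (C-type in {closed, open, inactive}, plain in
    {closed, open})."""
    probs = {}
    for conf in itertools.product(*[["c", "o", "i"]] * m, *[["x", "y"]] * p):
        pr = 1.0
        for s in conf[:m]:
            pr *= {"c": 1 - n - h, "o": n, "i": h}[s]
        for s in conf[m:]:
            pr *= {"x": 1 - q, "y": q}[s]
        i = sum(s in ("o", "i") for s in conf[:m])
        j = conf[:m].count("i")
        k = conf[m:].count("y")
        probs[(i, j, k)] = probs.get((i, j, k), 0.0) + pr
    return probs


class TestManifold:
    def test_rhs_vanishes_at_single_subunit_equilibrium(self, ctype_rates):
        comp = ChannelComposition.c_type(2)
        model = ManifoldReducedModel(comp, ctype_rates)
        z = model.stationary(10.0)
        np.testing.assert_allclose(manifold_rhs(z, comp, ctype_rates, 10.0),
                                   0.0, atol=1e-14)

    def test_rhs_matches_three_state_master_equation(self, ctype_rates, rng):
        """dn/dt and dh/dt are the single-subunit closed<->open->inactive
        master equation; dq/dt the two-state plain subunit."""
        comp = ChannelComposition.c_type(2)
        V = -5.0
        ir, pr = ctype_rates.inactivating, ctype_rates.plain
        a1, b1, aI, bI = ir.a1(V), ir.b1(V), ir.aI(V), ir.bI(V)
        for _ in range(10):
            q, n, h = interior_gating_state(rng)
            c = 1.0 - n - h
            oracle = np.array([
                pr.a2(V) * (1 - q) - pr.b2(V) * q,
                a1 * c - b1 * n - aI * n + bI * h,
                aI * n - bI * h,
            ])
            np.testing.assert_allclose(
                manifold_rhs((q, n, h), comp, ctype_rates, V), oracle, atol=1e-14)

    def test_inactivation_frozen_when_rates_zero(self):
        c = RateLaw.constant
        rates = SubunitRates(
            plain=PlainRates(c(1.0), c(1.0)),
            inactivating=InactivatingRates(c(1.2), c(0.6), c(0.0), c(0.0)))
        comp = ChannelComposition.c_type(2)
        dq, dn, dh = manifold_rhs((0.4, 0.3, 0.2), comp, rates, 0.0)
        assert dh == 0.0
        assert dn == pytest.approx(1.2 * (1 - 0.3 - 0.2) - 0.6 * 0.3)

    @pytest.mark.parametrize("m", [1, 2, 3, 4])
    def test_lift_normalized_and_matches_configuration_oracle(self, m, rng):
        comp = ChannelComposition.c_type(m)
        space = enumerate_states(comp)
        for _ in range(5):
            q, n, h = interior_gating_state(rng)
            P = manifold_lift((q, n, h), comp, space)
            assert P.sum() == pytest.approx(1.0, abs=1e-12)
            oracle = subunit_configuration_lift(m, comp.n_plain, q, n, h)
            for pos, (_, i, j, k) in enumerate(space.labels):
                assert P[pos] == pytest.approx(oracle[(i, j, k)], abs=1e-12)

    def test_lift_corner_is_pure_conducting_state(self):
        comp = ChannelComposition.c_type(2)
        space = enumerate_states(comp)
        P = manifold_lift((1.0, 1.0, 0.0), comp, space)
        expected = np.zeros(len(space))
        expected[space.conducting_index] = 1.0
        np.testing.assert_allclose(P, expected, atol=1e-15)

    def test_lift_example_entry_two_two(self):
        comp = ChannelComposition.c_type(2)
        space = enumerate_states(comp)
        q = n = h = 1.0 / 3.0
        P = manifold_lift((q, n, h), comp, space)
        # (i=2, j=1, k=1): 2 n h * C(2,1) q (1-q)
        expected = (2 * n * h) * (2 * q * (1 - q))
        assert P[space.index[("C", 2, 1, 1)]] == pytest.approx(expected, rel=1e-12)

    def test_lift_rejects_states_outside_simplex(self):
        comp = ChannelComposition.c_type(2)
        from hetkv import ReductionError
        with pytest.raises(ReductionError):
            manifold_lift((0.5, 0.8, 0.5), comp)

    def test_jacobian_matches_finite_differences(self, ctype_rates, rng):
        comp = ChannelComposition.c_type(3)
        space = enumerate_states(comp)
        z = interior_gating_state(rng)
        J = manifold_lift_jacobian(z, comp, space)
        eps = 1e-7
        for col in range(3):
            zp, zm = z.copy(), z.copy()
            zp[col] += eps
            zm[col] -= eps
            fd = (manifold_lift(zp, comp, space) - manifold_lift(zm, comp, space)) / (2 * eps)
            np.testing.assert_allclose(J[:, col], fd, atol=1e-6)

    @pytest.mark.parametrize("m", [1, 2, 3, 4])
    def test_invariance_residual_tiny_everywhere(self, m, ctype_rates, rng):
        comp = ChannelComposition.c_type(m)
        for _ in range(10):
            z = interior_gating_state(rng)
            for V in (-90.0, -30.0, 0.0, 30.0, 50.0):
                assert invariance_residual(comp, ctype_rates, V, z) <= 1e-10

    def test_residual_degenerates_to_plain_manifold_without_inactivation(self):
        c = RateLaw.constant
        rates = SubunitRates(
            plain=PlainRates(c(0.9), c(0.3)),
            inactivating=InactivatingRates(c(1.1), c(0.4), c(0.0), c(0.0)))
        comp = ChannelComposition.c_type(2)
        assert invariance_residual(comp, rates, 0.0, (0.4, 0.6, 0.0)) <= 1e-12

    def test_corner_row_expansion_of_the_rate_matrix(self, ctype_rates, rng):
        """The generator row for the all-open-all-inactive corner state of
        the 2:2 channel, applied to the lifted distribution, decomposes as
        -(2 bI + 2 b2) q^2 h^2 + aI 2 q^2 n h + a2 2 q (1-q) h^2."""
        comp = ChannelComposition.c_type(2)
        space = enumerate_states(comp)
        corner = space.index[("C", 2, 2, 2)]
        assert corner == len(space) - 1  # last (18th) row in canonical order
        for V in (-30.0, 20.0):
            R = build_generator(comp, ctype_rates, V, space)
            ir, pr = ctype_rates.inactivating, ctype_rates.plain
            aI, bI = ir.aI(V), ir.bI(V)
            a2, b2 = pr.a2(V), pr.b2(V)
            for _ in range(5):
                q, n, h = interior_gating_state(rng)
                P = manifold_lift((q, n, h), comp, space)
                expansion = (-(2 * bI + 2 * b2) * q ** 2 * h ** 2
                             + aI * (2 * q ** 2 * n * h)
                             + a2 * (2 * q * (1 - q) * h ** 2))
                assert (R @ P)[corner] == pytest.approx(expansion, abs=1e-14)

    def test_open_probability_closed_form_and_lift_agree(self, rng):
        for m in (1, 3, 4):
            comp = ChannelComposition.c_type(m)
            space = enumerate_states(comp)
            z = interior_gating_state(rng)
            O = manifold_open_probability(z, comp)
            assert O == pytest.approx(z[1] ** m * z[0] ** comp.n_plain)
            assert O == pytest.approx(
                manifold_lift(z, comp, space)[space.conducting_index], rel=1e-12)

    def test_reduced_dimension_three_for_heteromers_two_for_homomer(self, ctype_rates):
        dims = [ManifoldReducedModel(ChannelComposition.c_type(m), ctype_rates).dimension
                for m in range(5)]
        assert dims == [1, 3, 3, 3, 2]

    def test_full_trajectory_stays_on_lifted_manifold(self, ctype_rates):
        comp = ChannelComposition.c_type(2)
        red = ManifoldReducedModel(comp, ctype_rates)
        full = FullMarkovModel(comp, ctype_rates)
        segments = [VoltageSegment(0.0, 400.0), VoltageSegment(50.0, 2000.0),
                    VoltageSegment(-90.0, 1500.0)]
        z0 = red.stationary(-90.0)
        tr_full = simulate(full, segments, red.lift(z0), output_dt=10.0)
        tr_red = simulate(red, segments, z0, output_dt=10.0)
        lifted = np.array([red.lift(z) for z in tr_red.states])
        assert np.abs(tr_full.states - lifted).max() < 1e-8

    def test_recovery_curves_identical_between_full_and_reduced(self, ctype_rates):
        comp = ChannelComposition.c_type(3)
        spec = ProtocolSpec(delta_t_grid=(10.0, 100.0, 1000.0))
        full = run_recovery(FullMarkovModel(comp, ctype_rates), spec)
        red = run_recovery(ManifoldReducedModel(comp, ctype_rates), spec)
        np.testing.assert_allclose(full.ratio, red.ratio, atol=1e-9)
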