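"""Clamp-protocol summary curves: peaks, ratios, recovery, tau extraction."""

import numpy as np
import pytest

from hetkv import (
    ChannelComposition,
    FullMarkovModel,
    ProtocolSpec,
    fit_tau,
    run_activation,
    run_all_protocols,
    run_inactivation,
    run_recovery,
)

FAST_SPEC = ProtocolSpec(V_steps=(-90.0, -30.0, 0.0, 50.0))


def test_fit_tau_recovers_exact_single_exponential():
    t = np.linspace(0.0, 40.0, 200)
    tau = fit_tau(t, 1.0 - np.exp(-t / 5.0))
    assert tau == pytest.approx(5.0, rel=1e-6)


def test_fit_tau_degenerate_traces_absent():
    assert fit_tau(np.array([0.0, 1.0]), np.array([0.1, 0.2])) is None
    t = np.linspace(0, 10, 50)
    assert fit_tau(t, np.full_like(t, 0.3)) is None


def test_fit_tau_consistent_between_simulated_and_analytic_trace(plain_rates):
    """The tau extracted from the simulated rising phase equals the tau
    extracted from the analytic Hodgkin-Huxley curve q(t)^4 (independent
    closed-form route), and both sit on the slow-eigenmode timescale."""
    V = 0.0
    a2, b2 = plain_rates.plain.a2(V), plain_rates.plain.b2(V)
    model = FullMarkovModel(ChannelComposition.plain(), plain_rates)
    P0 = np.zeros(5)
    P0[0] = 1.0
    t = np.linspace(0.0, 60.0, 400)
    O_sim = model.open_probability(model.propagate(P0, V, t[1:]))
    O_sim = np.concatenate([[0.0], O_sim])
    q = a2 / (a2 + b2) * (1.0 - np.exp(-(a2 + b2) * t))
    tau_sim = fit_tau(t, O_sim)
    tau_hh = fit_tau(t, q ** 4)
    assert tau_sim == pytest.approx(tau_hh, rel=1e-6)
    slow = 1.0 / (a2 + b2)
    assert slow < tau_sim < 4.0 * slow  # sigmoidal onset inflates tau


def test_plain_channel_activation_peak_is_stationary_value(plain_rates):
    model = FullMarkovModel(ChannelComposition.plain(), plain_rates)
    act = run_activation(model, FAST_SPEC)
    # no inactivation: O(t) rises monotonically to its stationary value
    peak_50 = float(act.loc[act.V_mV == 50.0, "peak_open"].iloc[0])
    assert peak_50 == pytest.approx(model.stationary(50.0)[-1], abs=1e-6)
    # step to the holding potential itself: peak is the resting O
    peak_hold = float(act.loc[act.V_mV == -90.0, "peak_open"].iloc[0])
    assert peak_hold == pytest.approx(model.stationary(-90.0)[-1], abs=1e-9)


def test_ntype_homomer_transient_peak_exceeds_stationary_open(ntype_rates):
    model = FullMarkovModel(ChannelComposition.n_type(4), ntype_rates)
    act = run_activation(model, FAST_SPEC, compute_tau=False)
    peak_50 = float(act.loc[act.V_mV == 50.0, "peak_open"].iloc[0])
    stat_O = model.stationary(50.0)[model.space.conducting_index]
    assert peak_50 > stat_O + 0.05


def test_plain_channel_shows_no_inactivation(plain_rates):
    model = FullMarkovModel(ChannelComposition.plain(), plain_rates)
    inact = run_inactivation(model, FAST_SPEC)
    np.testing.assert_allclose(inact.ratio, 1.0, atol=1e-9)
    rec = run_recovery(model, ProtocolSpec(delta_t_grid=(10.0, 100.0, 1000.0)))
    np.testing.assert_allclose(rec.ratio, 1.0, atol=1e-6)


def test_inactivation_curve_normalization_properties(ntype_rates):
    model = FullMarkovModel(ChannelComposition.n_type(2), ntype_rates)
    inact = run_inactivation(model, ProtocolSpec())
    assert ((inact.ratio >= 0) & (inact.ratio <= 1 + 1e-9)).all()
    # no inactivation accrues while resting at the holding potential
    at_hold = float(inact.loc[inact.V_mV == -90.0, "ratio"].iloc[0])
    assert at_hold == pytest.approx(1.0, abs=1e-6)
    # availability declines at depolarized conditioning voltages
    assert float(inact.ratio.iloc[-1]) < 0.6


def test_literal_per_sweep_normalization_blows_up_at_rest(ntype_rates):
    """The per-sweep P2/P1 quotient exceeds 1 for hyperpolarized P1 where
    the P1 peak is tiny — why the availability normalization is default."""
    model = FullMarkovModel(ChannelComposition.n_type(4), ntype_rates)
    spec = ProtocolSpec(V_steps=(-90.0, 50.0))
    lit = run_inactivation(model, spec, normalization="per_sweep")
    assert float(lit.loc[lit.V_mV == -90.0, "ratio"].iloc[0]) > 10.0


def test_recovery_monotone_and_complete(ntype_rates):
    model = FullMarkovModel(ChannelComposition.n_type(4), ntype_rates)
    spec = ProtocolSpec(delta_t_grid=tuple(np.logspace(1, 4, 12)) + (6e4,))
    rec = run_recovery(model, spec)
    assert (np.diff(rec.ratio) > -1e-12).all()
    assert float(rec.ratio.iloc[-1]) == pytest.approx(1.0, abs=1e-3)


def test_single_inactivating_subunit_confers_inactivation(ntype_rates, ctype_rates):
    spec = ProtocolSpec(V_steps=(-90.0, 50.0))
    plain = FullMarkovModel(ChannelComposition.plain(), ntype_rates)
    base = float(run_inactivation(plain, spec).ratio.iloc[-1])
    for comp, rates in [(ChannelComposition.n_type(1), ntype_rates),
                        (ChannelComposition.c_type(1), ctype_rates)]:
        model = FullMarkovModel(comp, rates)
        ratio = float(run_inactivation(model, spec).ratio.iloc[-1])
        assert ratio < base - 1e-3


def test_tau_defaults_to_homomeric_channels_only(ntype_rates):
    spec = ProtocolSpec(V_steps=(0.0, 50.0))
    het = FullMarkovModel(ChannelComposition.n_type(2), ntype_rates)
    act = run_activation(het, spec)
    assert act.tau_ms.isna().all()
    act_forced = run_activation(het, spec, compute_tau=True)
    assert act_forced.tau_ms.notna().any()
    hom = FullMarkovModel(ChannelComposition.n_type(4), ntype_rates)
    assert run_activation(hom, spec).tau_ms.notna().any()


def test_run_all_protocols_bundles_three_curves(ctype_rates):
    model = FullMarkovModel(ChannelComposition.c_type(4), ctype_rates)
    spec = ProtocolSpec(V_steps=(-90.0, 50.0), delta_t_grid=(10.0, 100.0))
    curves = run_all_protocols(model, spec)
    assert list(curves.activation.columns) == ["V_mV", "peak_open", "tau_ms"]
    assert list(curves.inactivation.columns) == ["V_mV", "ratio"]
    assert list(curves.recovery.columns) == ["delta_t_ms", "ratio"]
    assert len(curves.recovery) == 2
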