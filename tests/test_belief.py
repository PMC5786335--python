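"""Belief propagation and Bayesian filtering, checked against closed forms,
a master-equation oracle and an explicit two-state forward filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from riskforage.belief import (
    Belief,
    BeliefGrid,
    propagate_belief,
    propagate_belief_step,
    snap_to_grid,
    update_habitat_belief,
    update_predator_belief,
)
from riskforage.params import ModelParams
from riskforage.world import EventStreams, WorldState, sample_observation, step_hidden_state

P = ModelParams(gamma_AP=0.1, gamma_PA=0.1)  # fast symmetric predator chain

unit = st.floats(0.0, 1.0)


def master_equation_present(beta0: float, tau: float, g_ap: float, g_pa: float) -> float:
    """P(present at tau) from the 2-state rate-matrix exponential."""
    Q = np.array([[-g_ap, g_ap], [g_pa, -g_pa]])  # states: absent, present
    return float((np.array([1 - beta0, beta0]) @ expm(Q * tau))[1])


@pytest.mark.parametrize("beta0, tau", [(0.0, 1.0), (0.3, 5.0), (1.0, 17.3), (0.5, 0.0)])
def test_propagation_matches_master_equation(beta0, tau):
    b = propagate_belief(Belief(beta0, 0.5), tau, P)
    assert b.beta_P == pytest.approx(
        master_equation_present(beta0, tau, P.gamma_AP, P.gamma_PA), abs=1e-12
    )


def test_propagation_closed_form_value():
    # from certainty of absence, one second of symmetric 0.1 rates
    b = propagate_belief(Belief(0.0, 0.0), 1.0, P)
    assert b.beta_P == pytest.approx(0.5 * (1 - np.exp(-0.2)), abs=1e-12)
    assert b.beta_P == pytest.approx(0.09063, abs=5e-6)


def test_equilibrium_is_fixed_point_and_long_time_limit():
    eq = Belief(P.predator_equilibrium, P.habitat_equilibrium)
    for tau in (0.1, 1.0, 50.0):
        out = propagate_belief(eq, tau, P)
        assert out.beta_P == pytest.approx(eq.beta_P)
        assert out.beta_G == pytest.approx(eq.beta_G)
    # symmetric rates: any start tends to 1/2
    far = propagate_belief(Belief(0.93, 0.02), 1e4, P)
    assert far.beta_P == pytest.approx(0.5, abs=1e-12)
    assert far.beta_G == pytest.approx(0.5, abs=1e-12)


def test_step_composition_approaches_closed_form():
    p = ModelParams(gamma_AP=0.1, gamma_PA=0.1, dt=0.01)
    b = Belief(0.0, 0.2)
    for _ in range(100):  # tau = 1 s in dt = 0.01 steps
        b = propagate_belief_step(b, p)
    exact = propagate_belief(Belief(0.0, 0.2), 1.0, p)
    assert b.beta_P == pytest.approx(exact.beta_P, abs=1e-3)
    assert b.beta_G == pytest.approx(exact.beta_G, abs=1e-3)


def test_zero_rates_make_propagation_identity():
    p = ModelParams(gamma_AP=0.0, gamma_PA=0.0, gamma_GB=0.0, gamma_BG=0.0)
    b = Belief(0.37, 0.81)
    out = propagate_belief_step(b, p)
    assert (out.beta_P, out.beta_G) == (pytest.approx(0.37), pytest.approx(0.81))


def test_negative_tau_rejected():
    with pytest.raises(ValueError):
        propagate_belief(Belief(0.5, 0.5), -1.0, P)


class _Obs:
    def __init__(self, oi=None, od=None):
        self.oi_seen = oi
        self.od_seen = od


def test_indirect_cue_posterior_hand_value():
    # two-hypothesis Bayes: 0.5*0.5 / (0.5*0.5 + 0.1*0.5) = 0.8333...
    post = update_predator_belief(Belief(0.5, 0.5), _Obs(oi=True), P)
    assert post.beta_P == pytest.approx(0.25 / 0.30, abs=1e-12)


def test_joint_direct_and_indirect_posterior_hand_value():
    # od seen, oi not seen: (0.9*0.5*0.5) / (0.9*0.5*0.5 + 0.1*0.9*0.5)
    post = update_predator_belief(Belief(0.5, 0.5), _Obs(oi=False, od=True), P)
    assert post.beta_P == pytest.approx(0.225 / (0.225 + 0.045), abs=1e-12)


def test_uninformative_cue_leaves_belief_unchanged():
    p = ModelParams(lambda_oi_plus=0.3, lambda_oi_minus=0.3)
    for seen in (True, False):
        post = update_predator_belief(Belief(0.42, 0.5), _Obs(oi=seen), p)
        assert post.beta_P == pytest.approx(0.42)


def test_habitat_update_hand_values():
    post = update_habitat_belief(Belief(0.5, 0.5), "rich", P)
    assert post.beta_G == pytest.approx(0.8)
    p_eq = ModelParams(rho_rG=0.4, rho_rB=0.4, rho_pG=0.2, rho_pB=0.2)
    assert update_habitat_belief(Belief(0.5, 0.5), "rich", p_eq).beta_G == pytest.approx(0.5)
    # degenerate priors are invariant under any outcome
    for outcome in ("rich", "poor", "none"):
        assert update_habitat_belief(Belief(0.5, 1.0), outcome, P).beta_G == pytest.approx(1.0)


@settings(max_examples=200, derandomize=True)
@given(beta=unit, tau=st.floats(0.0, 100.0))
def test_propagation_stays_in_unit_interval_and_is_monotone_to_equilibrium(beta, tau):
    out = propagate_belief(Belief(beta, beta), tau, P)
    assert 0.0 <= out.beta_P <= 1.0
    assert abs(out.beta_P - 0.5) <= abs(beta - 0.5) + 1e-12


@settings(max_examples=200, derandomize=True)
@given(beta=st.floats(0.01, 0.99))
def test_cue_evidence_direction(beta):
    # a cue whose + rate exceeds its - rate raises the belief; omission lowers it
    up = update_predator_belief(Belief(beta, 0.5), _Obs(oi=True), P)
    down = update_predator_belief(Belief(beta, 0.5), _Obs(oi=False), P)
    assert up.beta_P > beta
    assert down.beta_P < beta


def test_snap_to_grid_weights():
    g = BeliefGrid(0.01)
    idx, w = snap_to_grid(Belief(0.5, 0.25), g)
    assert w.sum() == pytest.approx(1.0) and len(idx) == 1
    idx, w = snap_to_grid(Belief(0.005, 0.0), g)
    assert np.allclose(sorted(w), [0.5, 0.5])
    rng = np.random.default_rng(7)
    pts = rng.random((10_000, 2))
    idx, w = g.interp_weights(pts[:, 0], pts[:, 1])
    assert np.all(w >= 0)
    assert np.allclose(w.sum(axis=1), 1.0)
    # interpolation of the coordinate functions reproduces the coordinates
    assert np.allclose((g.beta_P[idx] * w).sum(axis=1), pts[:, 0], atol=1e-12)
    assert np.allclose((g.beta_G[idx] * w).sum(axis=1), pts[:, 1], atol=1e-12)


def test_sequential_filter_equals_explicit_forward_filter():
    """Cue-driven belief updates along a simulated assess trajectory agree with
    a brute-force two-state forward (HMM) filter to numerical precision."""
    p = ModelParams(gamma_AP=0.05, gamma_PA=0.08)
    streams = EventStreams(31)
    s = WorldState(location="refuge", predator=False)
    b = Belief(0.3, 0.5)
    # explicit forward filter over states (absent, present)
    f = np.array([0.7, 0.3])
    a01 = 1 - np.exp(-p.gamma_AP * p.dt)
    a10 = 1 - np.exp(-p.gamma_PA * p.dt)
    T = np.array([[1 - a01, a01], [a10, 1 - a10]])
    for t in range(300):
        s = step_hidden_state(s, p.dt, p, streams, t)
        obs = sample_observation("assess", "refuge", s, p, streams, t)
        b = propagate_belief_step(b, p)
        b = update_predator_belief(b, obs, p)
        like = np.array(
            [
                (p.lambda_oi_minus if obs.oi_seen else 1 - p.lambda_oi_minus)
                * (p.lambda_od_minus if obs.od_seen else 1 - p.lambda_od_minus),
                (p.lambda_oi_plus if obs.oi_seen else 1 - p.lambda_oi_plus)
                * (p.lambda_od_plus if obs.od_seen else 1 - p.lambda_od_plus),
            ]
        )
        f = (f @ T) * like
        f /= f.sum()
        assert b.beta_P == pytest.approx(f[1], abs=1e-12)
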