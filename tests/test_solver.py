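"""Value iteration on the belief SMDP, validated against an independently
written dense finite-horizon dynamic program and structural invariants."""

import math

import numpy as np
import pytest

from oracles import brute_force_values, enumerate_outcomes

from riskforage.belief import BeliefGrid
from riskforage.params import ModelParams, ParamError, PATCH, REFUGE, legal_actions
from riskforage.solver import (
    Solution,
    activity_value,
    build_operators,
    build_step_operator,
    policy_regions,
    value_iteration,
)

LOCS = (REFUGE, PATCH)


# ---------------------------------------------------------------------------


def test_branch_probabilities_conserved(full_params, full_grid_ops):
    grid, ops = full_grid_ops
    for (loc, a), op in ops.items():
        total = np.asarray(op.T.sum(axis=1)).ravel() + np.asarray(
            op.T_cap.sum(axis=1)
        ).ravel()
        assert np.allclose(total, 1.0, atol=1e-12), (loc, a)


def test_rest_operator_is_deterministic_drift():
    p = ModelParams()
    g = BeliefGrid(0.1)
    op = build_step_operator(p, g, REFUGE, "rest", keep_branches=True)
    assert len(op.branches) == 1
    assert np.allclose(op.branches[0]["prob"], 1.0)
    assert np.allclose(op.R, 0.0)
    assert op.T_cap.nnz == 0


def test_no_detection_mass_without_predator_arrival():
    # with a zero arrival rate, beta_P = 0 rows carry no capture probability
    p = ModelParams(gamma_AP=0.0)
    g = BeliefGrid(0.5)
    op = build_step_operator(p, g, PATCH, "feed")
    zero_rows = np.nonzero(g.beta_P == 0.0)[0]
    assert np.allclose(op.p_capture[zero_rows], 0.0)
    assert np.allclose(np.asarray(op.T.sum(axis=1)).ravel()[zero_rows], 1.0)


def test_step_operator_matches_independent_enumeration(coarse_params):
    p = coarse_params
    g = BeliefGrid(p.d_beta)
    for loc in LOCS:
        for a in legal_actions(loc):
            op = build_step_operator(p, g, loc, a, keep_branches=True)
            for i in range(g.n_points):
                got = sorted(
                    (br["prob"][i], br["post_P"][i], br["post_G"][i], br["reward"][i])
                    for br in op.branches
                    if br["prob"][i] > 0
                )
                want = sorted(
                    (prob, pp, pg, r)
                    for prob, pp, pg, r, _cap in enumerate_outcomes(
                        p, loc, a, g.beta_P[i], g.beta_G[i]
                    )
                    if prob > 0
                )
                assert len(got) == len(want)
                for gr, wr in zip(got, want):
                    assert gr == pytest.approx(wr, abs=1e-12)


def test_illegal_location_action_pair_rejected():
    p = ModelParams()
    g = BeliefGrid(0.5)
    with pytest.raises(ParamError):
        build_step_operator(p, g, REFUGE, "feed")


def test_value_iteration_matches_brute_force_dp(coarse_params):
    """On the miniature model the converged grid values equal an independently
    implemented dense finite-horizon expansion (discount tail < 1e-9)."""
    p = coarse_params.with_(c_d=0.1)
    sol = value_iteration(p, tol=1e-12)
    horizon = int(np.ceil(np.log(1e-10) / -p.alpha / p.dt))  # disc^H * scale tiny
    V = brute_force_values(p, horizon)
    for loc in LOCS:
        assert np.allclose(sol.V[loc], V[loc], atol=1e-6), loc


def test_interruptible_equals_noninterruptible_when_decisions_free(coarse_params):
    sol_n = value_iteration(coarse_params, interruptible=False, tol=1e-12)
    sol_i = value_iteration(coarse_params, interruptible=True, tol=1e-12)
    for loc in LOCS:
        assert np.allclose(sol_n.V[loc], sol_i.V[loc], atol=1e-8)


def test_interruptible_value_dominates_at_positive_cost(coarse_params):
    p = coarse_params.with_(c_d=0.1, tau_set=(1, 2, 3, 4, 5))
    sol_n = value_iteration(p, interruptible=False, tol=1e-10)
    sol_i = value_iteration(p, interruptible=True, tol=1e-10)
    for loc in LOCS:
        assert np.all(sol_i.V[loc] >= sol_n.V[loc] - 1e-7)


def test_value_non_increasing_in_decision_cost(coarse_params):
    sols = [
        value_iteration(coarse_params.with_(c_d=cd), tol=1e-10)
        for cd in (0.0, 0.1, 0.5)
    ]
    for lo, hi in zip(sols, sols[1:]):
        for loc in LOCS:
            assert np.all(hi.V[loc] <= lo.V[loc] + 1e-7)


def test_uninformative_cues_reduce_policy_to_prior_dynamics():
    # equal emission rates on every channel: observations carry no information,
    # so the value function must be flat along any axis the prior cannot move
    p = ModelParams(
        gamma_AP=0.0, gamma_PA=0.0,  # predator belief frozen at its prior
        lambda_oi_plus=0.1, lambda_oi_minus=0.1,
        lambda_od_plus=0.1, lambda_od_minus=0.1,
        rho_rG=0.5, rho_pG=0.5, rho_rB=0.5, rho_pB=0.5,
        d_beta=0.25, tau_set=(1, 2),
    )
    sol = value_iteration(p, tol=1e-10)
    n = int(round(1 / p.d_beta)) + 1
    V = sol.V[PATCH].reshape(n, n)
    # habitat axis: rich/poor rates equal in both habitats -> value flat in beta_G
    assert np.allclose(V, V[:, :1], atol=1e-6)


def test_policy_extraction_deterministic(coarse_params):
    a = value_iteration(coarse_params, tol=1e-10)
    b = value_iteration(coarse_params, tol=1e-10)
    for loc in LOCS:
        assert np.array_equal(a.policy_action[loc], b.policy_action[loc])
        assert np.array_equal(a.policy_tau[loc], b.policy_tau[loc])


def test_nonconvergence_reported():
    sol = value_iteration(ModelParams(d_beta=0.5), max_iter=3, tol=1e-14)
    assert not sol.converged
    assert sol.iterations == 3 and sol.residual > 1e-14


def test_policy_region_structure_at_zero_cost(sol_cd0_non):
    """Patch: feed at low predator belief, defensive actions at high, assess
    between; refuge transit requires low predator belief."""
    reg = policy_regions(sol_cd0_non)
    patch = reg[reg.location == PATCH]

    def row(action, bg):
        sel = patch[(patch.action == action) & np.isclose(patch.beta_G, bg)]
        assert len(sel) == 1, (action, bg)
        return sel.iloc[0]

    for bg in (0.2, 0.5, 0.8):
        feed, assess, esc = row("feed", bg), row("assess", bg), row("escape", bg)
        assert feed.beta_P_min == 0.0
        assert feed.beta_P_max < assess.beta_P_max <= esc.beta_P_min
        assert assess.beta_P_min <= feed.beta_P_max + 0.01
        assert esc.beta_P_max == 1.0
    refuge = reg[reg.location == REFUGE]
    transit = refuge[refuge.action == "transit"]
    assert (transit.beta_P_max <= 0.35).all()


def test_activity_value_two_step_expansion(full_params, full_grid_ops):
    """Q(feed, tau=2) equals the explicit composition of two one-step backups."""
    grid, ops = full_grid_ops
    rng = np.random.default_rng(0)
    V = {loc: rng.normal(size=grid.n_points) for loc in LOCS}
    op = ops[(PATCH, "feed")]
    disc = math.exp(-full_params.alpha * full_params.dt)
    W = activity_value(op, V, full_params, interruptible=False)
    step1 = op.R + disc * (op.T @ V[PATCH] + op.T_cap @ V[REFUGE])
    step2 = op.R + disc * (op.T @ step1 + op.T_cap @ V[REFUGE])
    assert np.allclose(W[1], step1, atol=1e-12)
    assert np.allclose(W[2], step2, atol=1e-12)
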