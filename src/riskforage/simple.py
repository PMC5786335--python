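"""Stripped-down single-location foraging model.

A rat feeds in a habitat which a predator enters with probability ``p_arrive``
per time step and never leaves.  Each decision (cost ``c_d``) commits to an
action — *feed* (+``r_feed``/step, weak indirect predator cue), *assess*
(0 reward, indirect plus reliable direct cue) or *escape* (0 reward,
terminates the trial) — for a duration ``tau``.  While the predator is present
the rat is caught with probability ``p_catch`` per step, collecting ``r_catch``
and terminating.  The objective is the undiscounted expected total reward, so
value iteration runs on the one-dimensional belief grid over ``beta = P(predator
arrived)`` with capture and escape as terminal branches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import scipy.sparse as sp

from .params import SimpleParams
from .world import EventStreams

__all__ = ["SimpleSolution", "SimpleMetrics", "solve_simple", "simulate_simple",
           "escape_boundary"]

_ACTIONS = ("feed", "assess", "escape")  # also the tie-break order
_INTERRUPT_EPS = 1e-6  # must exceed the value-iteration residual


@dataclass
class SimpleSolution:
    params: SimpleParams
    betas: np.ndarray
    interruptible: bool
    V: np.ndarray
    policy_action: np.ndarray
    policy_tau: np.ndarray
    backups: Dict[str, np.ndarray]  # action -> (tau_max+1, n) committed values
    iterations: int
    residual: float
    converged: bool

    def value_at(self, beta: float) -> float:
        return float(np.interp(beta, self.betas, self.V))

    def policy_at(self, beta: float):
        i = int(round(np.clip(beta, 0, 1) / self.params.d_beta))
        return str(self.policy_action[i]), int(self.policy_tau[i])

    def should_interrupt(self, action: str, remaining: int, beta: float) -> bool:
        if not self.interruptible or remaining < 1 or action == "escape":
            return False
        w = float(np.interp(beta, self.betas, self.backups[action][remaining]))
        return self.value_at(beta) > w + _INTERRUPT_EPS


def _interp_matrix(betas: np.ndarray, targets: np.ndarray) -> sp.csr_matrix:
    """Sparse matrix mapping grid values to linear interpolants at ``targets``."""
    n = betas.size
    d = betas[1] - betas[0]
    f = np.clip(targets, 0.0, 1.0) / d
    i0 = np.clip(np.floor(f).astype(np.intp), 0, n - 2)
    t = f - i0
    rows = np.repeat(np.arange(n), 2)
    cols = np.stack([i0, i0 + 1], axis=1).ravel()
    vals = np.stack([1.0 - t, t], axis=1).ravel()
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def _build_simple_ops(sp_: SimpleParams, betas: np.ndarray):
    """Per-action (T, R, p_catch): T rows sum to 1 - p_catch; R includes the
    expected capture penalty."""
    prior = betas + (1.0 - betas) * sp_.p_arrive
    p_cap = prior * sp_.p_catch
    ops = {}
    for action in ("feed", "assess"):
        channels = [(sp_.lambda_oi_plus, sp_.lambda_oi_minus)]
        if action == "assess":
            channels.append((sp_.lambda_od_plus, sp_.lambda_od_minus))
        outcomes = [(1.0, 1.0)]
        for lam_p, lam_m in channels:
            outcomes = [
                (L_p * l, L_a * m)
                for L_p, L_a in outcomes
                for l, m in ((lam_p, lam_m), (1.0 - lam_p, 1.0 - lam_m))
            ]
        T = sp.csr_matrix((betas.size, betas.size))
        for L_p, L_a in outcomes:
            marg = prior * L_p + (1.0 - prior) * L_a
            with np.errstate(invalid="ignore", divide="ignore"):
                post = np.where(marg > 0, prior * L_p / np.where(marg > 0, marg, 1.0), prior)
            M = _interp_matrix(betas, post)
            T = T + sp.diags((1.0 - p_cap) * marg) @ M
        step_reward = sp_.r_feed if action == "feed" else 0.0
        R = (1.0 - p_cap) * step_reward + p_cap * sp_.r_catch
        ops[action] = (T.tocsr(), R, p_cap)
    return ops


def solve_simple(
    sp_: SimpleParams,
    interruptible: bool = False,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    tie_tol: float = 1e-8,
) -> SimpleSolution:
    """Undiscounted value iteration on the 1-D belief grid.

    Escape and capture are terminal (continuation value 0); convergence is in
    sup norm, guaranteed because every in-habitat policy accumulates capture
    probability once the predator has arrived.
    """
    n = int(round(1.0 / sp_.d_beta)) + 1
    betas = np.linspace(0.0, 1.0, n)
    ops = _build_simple_ops(sp_, betas)
    taus = list(sp_.tau_set)
    tau_max = sp_.tau_max
    V = np.zeros(n)
    residual = np.inf
    converged = False
    it = 0

    def backup(V):
        out = {"escape": np.zeros((tau_max + 1, n))}
        for action in ("feed", "assess"):
            T, R, _ = ops[action]
            W = np.empty((tau_max + 1, n))
            W[0] = V
            for k in range(1, tau_max + 1):
                cont = W[k - 1]
                if interruptible and k > 1:
                    cont = np.maximum(cont, V)
                W[k] = R + T @ cont
            out[action] = W
        return out

    for it in range(1, max_iter + 1):
        W = backup(V)
        V_new = np.maximum.reduce(
            [W[a][taus].max(axis=0) for a in _ACTIONS]
        ) - sp_.c_d
        residual = float(np.max(np.abs(V_new - V)))
        V = V_new
        if residual <= tol:
            converged = True
            break

    W = backup(V)
    # duration ties: shortest when non-interruptible (keep flexibility),
    # longest when interruptible (fewest scheduled decisions; interrupt free)
    tau_order = list(reversed(taus)) if interruptible else taus
    entries = [(tau, a) for tau in tau_order for a in _ACTIONS]
    Q = np.stack([W[a][tau] for tau, a in entries])
    best = Q.max(axis=0)
    chosen = np.argmax(Q >= best - tie_tol, axis=0)
    return SimpleSolution(
        params=sp_,
        betas=betas,
        interruptible=interruptible,
        V=V,
        policy_action=np.array([entries[i][1] for i in chosen], dtype="<U8"),
        policy_tau=np.array([entries[i][0] for i in chosen], dtype=np.int64),
        backups=W,
        iterations=it,
        residual=residual,
        converged=converged,
    )


def escape_boundary(sol: SimpleSolution) -> float:
    """Smallest grid belief at which escape is the optimal action (NaN if never)."""
    idx = np.nonzero(sol.policy_action == "escape")[0]
    return float(sol.betas[idx[0]]) if idx.size else float("nan")


@dataclass
class SimpleMetrics:
    mean_total_reward: float
    mean_steps: float
    decisions_per_step: float
    total_rewards: np.ndarray
    n_trials: int


def run_simple_trial(sol: SimpleSolution, trial_seed: int, max_steps: int = 100_000):
    """One trial under common-random-number event streams.

    Returns (total_reward, n_steps, n_decisions).  The decision cost is part of
    the reward stream; an escape step consumes one time step with zero reward.
    """
    sp_ = sol.params
    streams = EventStreams(trial_seed)
    beta = 0.0
    predator = False
    total = 0.0
    t = 0
    n_decisions = 0
    while t < max_steps:
        n_decisions += 1
        total -= sp_.c_d
        action, tau = sol.policy_at(beta)
        if action == "escape":
            t += 1
            return total, t, n_decisions
        remaining = tau
        terminated = False
        while remaining > 0:
            # world: arrival, then possible capture
            if not predator and streams.u("predator", t) < sp_.p_arrive:
                predator = True
            if predator and streams.u("detect", t) < sp_.p_catch:
                total += sp_.r_catch
                t += 1
                terminated = True
                break
            if action == "feed":
                total += sp_.r_feed
            # belief: propagate, then Bayes on this step's cues
            beta = beta + (1.0 - beta) * sp_.p_arrive
            lam = sp_.lambda_oi_plus if predator else sp_.lambda_oi_minus
            oi = streams.u("oi", t) < lam
            L_p, L_a = (
                (sp_.lambda_oi_plus, sp_.lambda_oi_minus)
                if oi
                else (1.0 - sp_.lambda_oi_plus, 1.0 - sp_.lambda_oi_minus)
            )
            if action == "assess":
                lam_d = sp_.lambda_od_plus if predator else sp_.lambda_od_minus
                od = streams.u("od", t) < lam_d
                if od:
                    L_p *= sp_.lambda_od_plus
                    L_a *= sp_.lambda_od_minus
                else:
                    L_p *= 1.0 - sp_.lambda_od_plus
                    L_a *= 1.0 - sp_.lambda_od_minus
            den = beta * L_p + (1.0 - beta) * L_a
            if den > 0.0:
                beta = beta * L_p / den
            t += 1
            remaining -= 1
            if remaining > 0 and sol.should_interrupt(action, remaining, beta):
                break
        if terminated:
            return total, t, n_decisions
    return total, t, n_decisions


def simulate_simple(sol: SimpleSolution, n_trials: int, seed: int) -> SimpleMetrics:
    """Aggregate metrics over ``n_trials`` trials; trial ``i`` uses the seed
    stream ``(seed, i)`` so compared policies face identical worlds."""
    rewards = np.empty(n_trials)
    steps = np.empty(n_trials)
    decisions = np.empty(n_trials)
    for i in range(n_trials):
        trial_seed = np.random.SeedSequence([seed, i]).generate_state(1)[0]
        r, s, d = run_simple_trial(sol, int(trial_seed))
        rewards[i] = r
        steps[i] = s
        decisions[i] = d
    return SimpleMetrics(
        mean_total_reward=float(rewards.mean()),
        mean_steps=float(steps.mean()),
        decisions_per_step=float(decisions.sum() / steps.sum()),
        total_rewards=rewards,
        n_trials=n_trials,
    )
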