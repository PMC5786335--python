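"""Value iteration on the discretized belief semi-Markov decision process.

The agent chooses *activities* — (action, duration) pairs — at decision epochs,
each decision costing ``c_d``.  Between epochs the belief state evolves
stochastically under the chosen action's observation model.  The solver:

1. builds, per (location, action), a :class:`StepOperator` that enumerates
   every joint per-step outcome (detection x cue outcomes x patch-encounter
   outcome) at every belief-grid point, carrying branch probability, posterior
   belief (mapped back to the grid by bilinear interpolation, or nearest
   neighbour), immediate reward, and whether the branch was a capture;
2. runs value iteration ``V(b) = max_{(a,tau)} [-c_d + Q_{a,tau}(b)]`` where
   ``Q`` comes from a backward recursion over the committed steps with per-step
   discount ``exp(-alpha*dt)``; when the policy is interruptible the recursion
   takes ``max(W_k, V)`` at interior commitment times (interrupting is free;
   the triggered re-decision pays ``c_d`` because ``V`` includes it);
3. extracts the optimal activity per grid point with deterministic
   tie-breaking: shortest duration first, then a fixed action order.

Capture by the predator collects the one-off penalty ``r_pred``, truncates the
current activity and relocates the animal to the refuge (with its predator
belief set to certainty); the process then continues — predation is a severe
injury, not the end of the world.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import scipy.sparse as sp

from .belief import BeliefGrid, _propagate_step_arrays
from .params import (
    ACTION_ORDER,
    ModelParams,
    ParamError,
    PATCH,
    REFUGE,
    legal_actions,
)

__all__ = [
    "StepOperator",
    "Solution",
    "build_step_operator",
    "build_operators",
    "activity_value",
    "value_iteration",
    "policy_regions",
]

# Interrupt only on an improvement that clearly exceeds the value-iteration
# residual; otherwise convergence noise would trigger costly re-decisions.
_INTERRUPT_EPS = 1e-6


@dataclass
class StepOperator:
    """Single-step consequences of performing ``action`` at ``location``.

    ``T`` maps a value function on the grid to its expected discounted
    continuation over the non-capture branches (rows sum to ``1 - p_capture``);
    ``T_cap`` carries the capture mass to post-capture refuge beliefs; ``R`` is
    the expected immediate reward including the capture penalty contribution.
    ``branches`` keeps the full enumeration for inspection and testing.
    """

    location: str
    action: str
    end_location: str
    T: sp.csr_matrix
    T_cap: sp.csr_matrix
    R: np.ndarray
    p_capture: np.ndarray
    branches: list = field(default_factory=list, repr=False)


def _enumerate_branches(p: ModelParams, g: BeliefGrid, location: str, action: str):
    """All joint per-step outcomes at every grid point, vectorized over the grid.

    Returns (branches, p_capture): each branch is a dict with keys
    ``prob, post_P, post_G, reward, kind`` (arrays over grid points; ``kind``
    is 'continue' or 'capture').
    """
    dt = p.dt
    bP1, bG1 = _propagate_step_arrays(g.beta_P, g.beta_G, p)

    exposed = location == PATCH or action == "transit"
    if exposed:
        p_cap = bP1 * (1.0 - np.exp(-p.delta_by_action[action] * dt))
    else:
        p_cap = np.zeros(g.n_points)
    p_nocap = 1.0 - p_cap

    branches = []
    if exposed:
        branches.append(
            dict(
                prob=p_cap.copy(),
                post_P=np.ones(g.n_points),
                post_G=bG1.copy(),
                reward=np.full(g.n_points, p.reward_rate(action) * dt + p.r_pred),
                kind="capture",
            )
        )

    # predator-cue channels available this step
    cue_channels = []
    if action != "rest":
        cue_channels.append((p.lambda_oi_plus * dt, p.lambda_oi_minus * dt))
    if action == "assess":
        cue_channels.append((p.lambda_od_plus * dt, p.lambda_od_minus * dt))

    # joint cue outcomes: product over channels of seen/not-seen
    cue_outcomes = [(np.ones(1), np.ones(1))]  # (L_present, L_absent) scalars
    for lam_p, lam_m in cue_channels:
        new = []
        for L_p, L_a in cue_outcomes:
            new.append((L_p * lam_p, L_a * lam_m))
            new.append((L_p * (1.0 - lam_p), L_a * (1.0 - lam_m)))
        cue_outcomes = new

    # feed-encounter outcomes: (L_good, L_bad, reward per step)
    if action == "feed":
        enc_outcomes = [
            (p.rho_rG * dt, p.rho_rB * dt, p.r_feed_rich * dt),
            (p.rho_pG * dt, p.rho_pB * dt, p.r_feed_poor * dt),
            (1.0 - (p.rho_rG + p.rho_pG) * dt, 1.0 - (p.rho_rB + p.rho_pB) * dt, 0.0),
        ]
        enc_outcomes = [(g_, b_, r_) for g_, b_, r_ in enc_outcomes
                        if g_ > 0.0 or b_ > 0.0]
    else:
        enc_outcomes = [(1.0, 1.0, p.reward_rate(action) * dt)]

    for L_p, L_a in cue_outcomes:
        m_pred = bP1 * L_p + (1.0 - bP1) * L_a  # marginal cue probability
        with np.errstate(invalid="ignore", divide="ignore"):
            post_P = np.where(m_pred > 0, bP1 * L_p / np.where(m_pred > 0, m_pred, 1.0), bP1)
        for E_g, E_b, reward in enc_outcomes:
            m_enc = bG1 * E_g + (1.0 - bG1) * E_b
            with np.errstate(invalid="ignore", divide="ignore"):
                post_G = np.where(m_enc > 0, bG1 * E_g / np.where(m_enc > 0, m_enc, 1.0), bG1)
            prob = p_nocap * m_pred * m_enc
            branches.append(
                dict(
                    prob=prob,
                    post_P=post_P,
                    post_G=post_G,
                    reward=np.full(g.n_points, reward),
                    kind="continue",
                )
            )
    return branches, p_cap


def build_step_operator(
    p: ModelParams,
    g: BeliefGrid,
    location: str,
    action: str,
    grid_mode: str = "bilinear",
    keep_branches: bool = False,
) -> StepOperator:
    """Assemble the sparse per-step operator for one (location, action)."""
    if action not in legal_actions(location):
        raise ParamError(f"action {action!r} illegal in location {location!r}")
    branches, p_cap = _enumerate_branches(p, g, location, action)

    n = g.n_points
    rows_c, cols_c, vals_c = [], [], []
    rows_k, cols_k, vals_k = [], [], []
    R = np.zeros(n)
    row_idx = np.arange(n)
    for br in branches:
        R += br["prob"] * br["reward"]
        idx, w = g.interp_weights(br["post_P"], br["post_G"], mode=grid_mode)
        pw = br["prob"][:, None] * w
        dest_rows, dest_cols, dest_vals = (
            np.repeat(row_idx, idx.shape[1]),
            idx.ravel(),
            pw.ravel(),
        )
        keep = dest_vals != 0.0
        if br["kind"] == "capture":
            rows_k.append(dest_rows[keep])
            cols_k.append(dest_cols[keep])
            vals_k.append(dest_vals[keep])
        else:
            rows_c.append(dest_rows[keep])
            cols_c.append(dest_cols[keep])
            vals_c.append(dest_vals[keep])

    def _csr(rows, cols, vals):
        if not rows:
            return sp.csr_matrix((n, n))
        return sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )

    if location == REFUGE:
        end = PATCH if action == "transit" else REFUGE
    else:
        end = REFUGE if (action == "escape" and p.escape_effective) else PATCH
    return StepOperator(
        location=location,
        action=action,
        end_location=end,
        T=_csr(rows_c, cols_c, vals_c),
        T_cap=_csr(rows_k, cols_k, vals_k),
        R=R,
        p_capture=p_cap,
        branches=branches if keep_branches else [],
    )


def build_operators(p: ModelParams, g: BeliefGrid, grid_mode: str = "bilinear"):
    """Step operators for every legal (location, action)."""
    return {
        (loc, a): build_step_operator(p, g, loc, a, grid_mode=grid_mode)
        for loc in (REFUGE, PATCH)
        for a in legal_actions(loc)
    }


def activity_value(
    op: StepOperator,
    V: Dict[str, np.ndarray],
    p: ModelParams,
    interruptible: bool,
) -> np.ndarray:
    """Committed values ``W[k]`` of the activity with ``k`` steps remaining.

    Backward recursion from ``W[0] = V[end location]``:
    ``W[k] = R + disc * (T @ cont + T_cap @ V[refuge])`` with
    ``cont = max(W[k-1], V[here])`` at interior times when interruptible
    (interruption is free; the re-decision cost is inside ``V``).
    Returns an array of shape ``(tau_max + 1, n_points)``; ``Q(a, tau)`` is
    ``W[tau]``, and ``W[k]`` for ``0 < k < tau`` is the raw continuation value
    against which the interrupt condition compares ``V``.
    """
    disc = float(np.exp(-p.alpha * p.dt))
    n = op.R.size
    W = np.empty((p.tau_max + 1, n))
    W[0] = V[op.end_location]
    V_here = V[op.location]
    V_ref = V[REFUGE]
    cap = op.T_cap @ V_ref
    for k in range(1, p.tau_max + 1):
        cont = W[k - 1]
        if interruptible and k > 1:
            cont = np.maximum(cont, V_here)
        W[k] = op.R + disc * (op.T @ cont + cap)
    return W


@dataclass
class Solution:
    """Solved policy and value function on the belief grid.

    ``policy_action[loc]``/``policy_tau[loc]`` give the optimal activity per
    grid point; ``V[loc]`` the value at a decision epoch (decision cost
    included).  ``backups[loc][action]`` holds the committed-value tables
    ``W[k]`` used for the interrupt condition and threshold extraction.
    """

    params: ModelParams
    grid: BeliefGrid
    interruptible: bool
    V: Dict[str, np.ndarray]
    policy_action: Dict[str, np.ndarray]
    policy_tau: Dict[str, np.ndarray]
    backups: Dict[str, Dict[str, np.ndarray]]
    iterations: int
    residual: float
    converged: bool
    tol: float
    grid_mode: str

    @property
    def c_d(self) -> float:
        return self.params.c_d

    def policy_at(self, location: str, beta_P: float, beta_G: float):
        """(action, tau) at the nearest grid point."""
        g = self.grid
        iP = int(round(np.clip(beta_P, 0, 1) / g.d_beta))
        iG = int(round(np.clip(beta_G, 0, 1) / g.d_beta))
        i = iP * g.n_G + iG
        return str(self.policy_action[location][i]), int(self.policy_tau[location][i])

    def value_at(self, location: str, beta_P: float, beta_G: float) -> float:
        return float(self.grid.interpolate(self.V[location], beta_P, beta_G,
                                           mode=self.grid_mode))

    def continuation_at(self, location: str, action: str, remaining: int,
                        beta_P: float, beta_G: float) -> float:
        W = self.backups[location][action]
        return float(self.grid.interpolate(W[remaining], beta_P, beta_G,
                                           mode=self.grid_mode))

    def should_interrupt(self, location: str, action: str, remaining: int,
                         beta_P: float, beta_G: float) -> bool:
        """Exact interrupt test: re-deciding now beats the committed remainder."""
        if not self.interruptible or remaining < 1:
            return False
        v = self.value_at(location, beta_P, beta_G)
        w = self.continuation_at(location, action, remaining, beta_P, beta_G)
        return v > w + _INTERRUPT_EPS


def _entry_order(p: ModelParams, location: str, prefer_longer: bool):
    """Canonical (tau, action) enumeration implementing the tie-break order.

    Ties between durations resolve toward the shortest commitment for
    non-interruptible policies (flexibility is free) and toward the longest
    for interruptible ones (longer provisional commitments schedule fewer
    decisions and interruption is free); the action order then breaks any
    remaining ties.
    """
    acts = [a for a in ACTION_ORDER if a in legal_actions(location)]
    taus = reversed(p.tau_set) if prefer_longer else p.tau_set
    return [(tau, a) for tau in taus for a in acts]


def value_iteration(
    p: ModelParams,
    interruptible: bool = False,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    grid: Optional[BeliefGrid] = None,
    operators=None,
    grid_mode: str = "bilinear",
    v0: Optional[Dict[str, np.ndarray]] = None,
    tie_tol: float = 1e-6,
) -> Solution:
    """Solve the belief-state SMDP to sup-norm tolerance ``tol``.

    ``v0`` warm-starts the value function (e.g. from a neighbouring decision
    cost); ``operators`` may be shared across solves with identical dynamics.
    """
    if grid is None:
        grid = BeliefGrid(p.d_beta)
    if operators is None:
        operators = build_operators(p, grid, grid_mode=grid_mode)
    locs = (REFUGE, PATCH)
    V = (
        {loc: v0[loc].copy() for loc in locs}
        if v0 is not None
        else {loc: np.zeros(grid.n_points) for loc in locs}
    )
    taus = list(p.tau_set)
    residual = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        backups = {
            loc: {
                a: activity_value(operators[(loc, a)], V, p, interruptible)
                for a in legal_actions(loc)
            }
            for loc in locs
        }
        V_new = {}
        for loc in locs:
            best = None
            for a in legal_actions(loc):
                q = backups[loc][a][taus].max(axis=0)
                best = q if best is None else np.maximum(best, q)
            V_new[loc] = best - p.c_d
        residual = max(float(np.max(np.abs(V_new[loc] - V[loc]))) for loc in locs)
        V = V_new
        if residual <= tol:
            converged = True
            break

    # final backups from the converged V, used for extraction and simulation
    backups = {
        loc: {
            a: activity_value(operators[(loc, a)], V, p, interruptible)
            for a in legal_actions(loc)
        }
        for loc in locs
    }
    policy_action, policy_tau = {}, {}
    for loc in locs:
        entries = _entry_order(p, loc, prefer_longer=interruptible)
        Q = np.stack([backups[loc][a][tau] for tau, a in entries])
        best = Q.max(axis=0)
        chosen = np.argmax(Q >= best - tie_tol, axis=0)
        policy_tau[loc] = np.array([entries[i][0] for i in chosen], dtype=np.int64)
        policy_action[loc] = np.array([entries[i][1] for i in chosen], dtype="<U8")

    return Solution(
        params=p,
        grid=grid,
        interruptible=interruptible,
        V=V,
        policy_action=policy_action,
        policy_tau=policy_tau,
        backups=backups,
        iterations=it,
        residual=residual,
        converged=converged,
        tol=tol,
        grid_mode=grid_mode,
    )


def policy_regions(sol: Solution):
    """Summarize each action's occupied belief region per location.

    Returns a pandas DataFrame with one row per (location, action, beta_G
    column) giving the lowest and highest ``beta_P`` grid values at which the
    action is selected, and per-location occupancy counts.
    """
    import pandas as pd

    g = sol.grid
    rows = []
    for loc, acts in sol.policy_action.items():
        A = acts.reshape(g.n_P, g.n_G)
        for action in dict.fromkeys(A.ravel().tolist()):
            for iG, bG in enumerate(g.values):
                col = A[:, iG] == action
                if not col.any():
                    continue
                iPs = np.nonzero(col)[0]
                rows.append(
                    dict(
                        location=loc,
                        action=action,
                        beta_G=float(bG),
                        beta_P_min=float(g.values[iPs.min()]),
                        beta_P_max=float(g.values[iPs.max()]),
                        n_points=int(col.sum()),
                    )
                )
    return pd.DataFrame(rows)
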