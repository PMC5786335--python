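"""Matched-trial simulation harness and behavioural metrics.

Trials run a solved policy in the generative world under a *protocol*: a
scripted schedule of predator presence (the habitat keeps its free telegraph
dynamics).  The canonical protocol is a 6-minute period with the predator
absent (2 min), present (2 min), then absent again (2 min).  Policy
comparisons use common random numbers — per-trial, per-channel, step-indexed
uniform streams — so two policies simulated at the same trial seed face an
identical world and identical cue/detection/encounter draws, eliminating
between-policy sampling noise.

Each trial starts in the refuge with the predator absent, the habitat drawn
from its stationary distribution, and beliefs at the environment's stationary
values.  The total reward per trial includes the decision costs paid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .belief import Belief, propagate_belief_step, update_habitat_belief, update_predator_belief
from .params import ModelParams, PATCH, REFUGE
from .solver import Solution, build_operators, value_iteration
from .world import EventStreams, WorldState, sample_observation, step_hidden_state

__all__ = ["Protocol", "TrialTrace", "Metrics", "run_trial",
           "compare_interruptibility", "behaviour_summary", "matched_metrics"]

#: Interrupt rules are callables (location, action, remaining, belief) -> bool;
#: ``None`` means the solution's exact value-based condition (if interruptible).
InterruptRule = Optional[Callable[[str, str, int, Belief], bool]]


@dataclass(frozen=True)
class Protocol:
    """Scripted predator schedule: segments of (duration seconds, present?)."""

    segments: Tuple[Tuple[float, bool], ...] = ((120.0, False), (120.0, True), (120.0, False))

    def __post_init__(self) -> None:
        if any(d <= 0 for d, _ in self.segments):
            raise ValueError("segment durations must be positive")

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.segments)

    def presence_schedule(self, dt: float) -> np.ndarray:
        """Boolean array of scripted predator presence per step."""
        out = []
        for dur, present in self.segments:
            out.extend([present] * int(round(dur / dt)))
        return np.array(out, dtype=bool)


@dataclass
class TrialTrace:
    """Per-step records of one trial plus its scalar aggregates."""

    frame: pd.DataFrame
    total_reward: float
    n_decisions: int
    n_steps: int
    decision_times: List[float] = field(default_factory=list)

    @property
    def decisions_per_step(self) -> float:
        return self.n_decisions / self.n_steps

    def activity_proportions(self) -> pd.Series:
        return self.frame["action"].value_counts(normalize=True)

    def location_proportions(self) -> pd.Series:
        return self.frame["location"].value_counts(normalize=True)

    def bout_lengths(self) -> pd.DataFrame:
        """Bouts: maximal runs of consecutive steps with the same action."""
        a = self.frame["action"].to_numpy()
        change = np.r_[True, a[1:] != a[:-1]]
        starts = np.flatnonzero(change)
        lengths = np.diff(np.r_[starts, a.size])
        return pd.DataFrame({"action": a[starts], "length": lengths})


def run_trial(
    sol: Solution,
    proto: Protocol,
    trial_seed: int,
    interrupt_rule: InterruptRule = None,
    record: bool = True,
) -> TrialTrace:
    """Execute the policy through one protocol trial.

    At each decision epoch the animal pays ``c_d`` and commits to the
    activity prescribed at the nearest grid point; beliefs are filtered from
    the sampled observations each step; commitments end on schedule, on
    capture, or — for interruptible policies — when the interrupt condition
    fires (the exact value comparison, or a supplied ``interrupt_rule`` such
    as a fitted threshold box).
    """
    p = sol.params
    dt = p.dt
    schedule = proto.presence_schedule(dt)
    n_steps = schedule.size
    streams = EventStreams(trial_seed)

    habitat_good = streams.u("policy", 0) < p.habitat_equilibrium
    s = WorldState(location=REFUGE, predator=False, habitat_good=habitat_good)
    loc = REFUGE
    b = Belief(p.predator_equilibrium, p.habitat_equilibrium)

    total = 0.0
    n_decisions = 0
    decision_times: List[float] = []
    rows = []
    need_decision = True
    action, remaining = "rest", 0

    for t in range(n_steps):
        if need_decision:
            n_decisions += 1
            total -= p.c_d
            decision_times.append(t * dt)
            action, remaining = sol.policy_at(loc, b.beta_P, b.beta_G)
            need_decision = False
        loc_at_step = loc
        s = step_hidden_state(s, dt, p, streams, t, forced_predator=bool(schedule[t]))
        obs = sample_observation(action, loc, s, p, streams, t)
        if obs.detected:
            reward = p.reward_rate(action) * dt + p.r_pred
            b = propagate_belief_step(b, p)
            b = Belief(1.0, b.beta_G)
            loc = REFUGE
            remaining = 0
            need_decision = True
        else:
            if action == "feed":
                reward = {"rich": p.r_feed_rich, "poor": p.r_feed_poor, "none": 0.0}[
                    obs.feed_outcome
                ] * dt
            else:
                reward = p.reward_rate(action) * dt
            b = propagate_belief_step(b, p)
            b = update_predator_belief(b, obs, p)
            if action == "feed":
                b = update_habitat_belief(b, obs.feed_outcome, p)
            remaining -= 1
            if remaining == 0:
                if action == "transit":
                    loc = PATCH
                elif action == "escape" and p.escape_effective:
                    loc = REFUGE
                need_decision = True
            elif interrupt_rule is not None:
                if interrupt_rule(loc, action, remaining, b):
                    need_decision = True
            elif sol.should_interrupt(loc, action, remaining, b.beta_P, b.beta_G):
                need_decision = True
        total += reward
        if record:
            rows.append(
                (t * dt, loc_at_step, s.predator, s.habitat_good, action, remaining,
                 obs.oi_seen, obs.od_seen, obs.feed_outcome, obs.detected, reward,
                 b.beta_P, b.beta_G)
            )

    frame = pd.DataFrame(
        rows,
        columns=["time", "location", "predator", "habitat", "action", "tau_remaining",
                 "oi", "od", "feed_outcome", "detected", "reward",
                 "beta_P", "beta_G"],
    ) if record else pd.DataFrame()
    return TrialTrace(frame=frame, total_reward=total, n_decisions=n_decisions,
                      n_steps=n_steps, decision_times=decision_times)


@dataclass
class Metrics:
    """Aggregates over a batch of trials of one policy."""

    mean_reward: float
    sem_reward: float
    decisions_per_step: float
    prop_rest: float
    prop_patch: float
    rewards: np.ndarray

    @staticmethod
    def from_trials(traces: Sequence[TrialTrace]) -> "Metrics":
        rewards = np.array([tr.total_reward for tr in traces])
        steps = sum(tr.n_steps for tr in traces)
        decisions = sum(tr.n_decisions for tr in traces)
        rest = patch = total = 0
        for tr in traces:
            if len(tr.frame):
                total += len(tr.frame)
                rest += int((tr.frame["action"] == "rest").sum())
                patch += int((tr.frame["location"] == PATCH).sum())
        return Metrics(
            mean_reward=float(rewards.mean()),
            sem_reward=float(rewards.std(ddof=1) / np.sqrt(rewards.size)) if rewards.size > 1 else 0.0,
            decisions_per_step=decisions / steps,
            prop_rest=rest / total if total else float("nan"),
            prop_patch=patch / total if total else float("nan"),
            rewards=rewards,
        )


def _trial_seed(seed: int, i: int) -> int:
    return int(np.random.SeedSequence([seed, i]).generate_state(1)[0])


def matched_metrics(
    sol: Solution,
    proto: Protocol,
    n_trials: int,
    seed: int,
    interrupt_rule: InterruptRule = None,
    record: bool = True,
) -> Metrics:
    """Run ``n_trials`` trials; trial ``i`` always uses the stream (seed, i)."""
    traces = [
        run_trial(sol, proto, _trial_seed(seed, i), interrupt_rule=interrupt_rule,
                  record=record)
        for i in range(n_trials)
    ]
    return Metrics.from_trials(traces)


def compare_interruptibility(
    p: ModelParams,
    c_d_grid: Sequence[float],
    proto: Protocol,
    n_trials: int = 200,
    seed: int = 0,
    tol: float = 1e-8,
    operators=None,
    grid=None,
    progress: Optional[Callable[[str], None]] = None,
) -> pd.DataFrame:
    """Reward-ratio sweep over decision costs.

    For each ``c_d`` solves the non-interruptible and interruptible policies
    (warm-started along the sweep, sharing step operators) and runs matched
    trials with common random numbers.  Returns one row per ``c_d`` with the
    non-interrupt/interrupt mean-reward ratio, decisions per step, and the
    proportion of time spent resting, for both policies.
    """
    from .belief import BeliefGrid

    if grid is None:
        grid = BeliefGrid(p.d_beta)
    rows = []
    warm = {False: None, True: None}
    for c_d in c_d_grid:
        pc = p.with_(c_d=float(c_d))
        if operators is None:  # shared across the sweep: dynamics don't depend on c_d
            operators = build_operators(pc, grid)
        sols = {}
        for interruptible in (False, True):
            sols[interruptible] = value_iteration(
                pc, interruptible=interruptible, tol=tol, grid=grid,
                operators=operators, v0=warm[interruptible],
            )
            warm[interruptible] = sols[interruptible].V
        m_non = matched_metrics(sols[False], proto, n_trials, seed)
        m_int = matched_metrics(sols[True], proto, n_trials, seed)
        diff = m_non.rewards - m_int.rewards
        sem_diff = float(diff.std(ddof=1) / np.sqrt(diff.size)) if diff.size > 1 else 0.0
        ratio = (
            1.0
            if np.allclose(m_non.rewards, m_int.rewards)
            else m_non.mean_reward / m_int.mean_reward
        )
        rows.append(
            dict(
                c_d=float(c_d),
                ratio=ratio,
                mean_reward_noninterrupt=m_non.mean_reward,
                mean_reward_interrupt=m_int.mean_reward,
                mean_diff=float(diff.mean()),
                sem_diff=sem_diff,
                decisions_per_step_noninterrupt=m_non.decisions_per_step,
                decisions_per_step_interrupt=m_int.decisions_per_step,
                prop_rest_noninterrupt=m_non.prop_rest,
                prop_rest_interrupt=m_int.prop_rest,
            )
        )
        if progress is not None:
            progress(f"c_d={c_d}: ratio={rows[-1]['ratio']:.4f}")
    return pd.DataFrame(rows)


def critical_cost(table: pd.DataFrame, z: float = 2.0) -> float:
    """Smallest swept ``c_d`` from which the reward ratio stays at 1.

    'At 1' means the matched-trial mean reward difference is within ``z``
    standard errors of zero (exactly zero once both policies collapse to
    permanent rest).  Scans from the top of the sweep downward and returns the
    start of the terminal run of equal-performance costs; NaN if the largest
    swept cost still shows an advantage.
    """
    tab = table.sort_values("c_d").reset_index(drop=True)
    equal = (tab["mean_diff"].abs() <= z * tab["sem_diff"].clip(lower=1e-12)) | (
        tab["mean_diff"] == 0.0
    )
    crit = float("nan")
    for i in range(len(tab) - 1, -1, -1):
        if not equal[i]:
            break
        crit = float(tab["c_d"][i])
    return crit


def behaviour_summary(
    sol: Solution,
    condition: str,
    n_runs: int = 100,
    run_length: float = 900.0,
    seed: int = 0,
) -> dict:
    """Occupancy, activity budget and bout statistics under a clamped predator.

    ``condition`` is ``'present'`` or ``'absent'``; the predator is scripted to
    that value for the whole run while the habitat fluctuates freely.
    """
    if condition not in ("present", "absent"):
        raise ValueError("condition must be 'present' or 'absent'")
    proto = Protocol(((run_length, condition == "present"),))
    traces = [
        run_trial(sol, proto, _trial_seed(seed, i)) for i in range(n_runs)
    ]
    act = pd.concat([tr.activity_proportions() for tr in traces], axis=1).fillna(0.0)
    locp = pd.concat([tr.location_proportions() for tr in traces], axis=1).fillna(0.0)
    bouts = pd.concat([tr.bout_lengths() for tr in traces])
    bout_stats = bouts.groupby("action")["length"].agg(["mean", "sem", "count"])
    return dict(
        condition=condition,
        activity_proportions=act.mean(axis=1).to_dict(),
        location_proportions=locp.mean(axis=1).to_dict(),
        bout_stats=bout_stats,
        mean_reward=float(np.mean([tr.total_reward for tr in traces])),
    )
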