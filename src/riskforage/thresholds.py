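"""Interruption thresholds on the predator belief and their linear approximation.

Under an interruptible policy, the belief states at which an ongoing activity
should be abandoned form a boundary in belief space.  For *feed* the
continuation region is a single interval in ``beta_P`` reaching down to 0
(only an upper threshold); for *assess* it is an interior interval (lower and
upper thresholds).  This module extracts those boundaries from a solved
interruptible policy, fits them as linear functions of the habitat belief
``beta_G`` and the decision cost ``c_d``, evaluates the cheap
threshold-triggered interruption policy built from the fits, and sweeps cue
reliabilities.

The threshold convention: an activity is 'continued' at a grid belief if the
committed value with the full ``tau_max`` remaining steps is at least the
value of re-deciding (activities are started at ``tau_max`` in the
interruptible regime).
"""

from __future__ import annotations

from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .belief import Belief, BeliefGrid
from .experiments import InterruptRule, Protocol, matched_metrics
from .params import ModelParams, PATCH, REFUGE, legal_actions
from .solver import Solution, build_operators, value_iteration

__all__ = [
    "extract_thresholds",
    "fit_linear_thresholds",
    "threshold_interrupt_rule",
    "evaluate_approx_policy",
    "sweep_cue_reliability",
]

_EPS = 1e-9


def _continuation_mask(sol: Solution, location: str, action: str) -> np.ndarray:
    """Grid mask where continuing the activity (tau_max remaining) >= re-deciding."""
    W = sol.backups[location][action][sol.params.tau_max]
    return W >= sol.V[location] - _EPS


def extract_thresholds(
    sol: Solution,
    activity: str,
    location: str,
    beta_G_levels: Sequence[float],
    lambda_setting: str = "default",
) -> pd.DataFrame:
    """Interruption thresholds on ``beta_P`` at fixed ``beta_G`` levels.

    Returns one row per level with ``theta_lower``/``theta_upper`` (NaN when
    the continuation region is unbounded on that side, i.e. touches 0 or 1)
    and an ``empty`` flag marking levels at which the activity's initiation
    set (grid points where the policy selects it) is empty.
    """
    if not sol.interruptible:
        raise ValueError("thresholds are defined for interruptible solutions")
    if activity not in legal_actions(location):
        raise ValueError(f"{activity!r} not legal in {location!r}")
    if activity in ("rest", "transit", "escape"):
        raise ValueError(f"{activity!r} has no interruption structure")
    g = sol.grid
    cont = _continuation_mask(sol, location, activity).reshape(g.n_P, g.n_G)
    init = (sol.policy_action[location] == activity).reshape(g.n_P, g.n_G)
    rows = []
    for bG in beta_G_levels:
        iG = int(round(np.clip(bG, 0, 1) / g.d_beta))
        col_cont = cont[:, iG]
        col_init = init[:, iG]
        row = dict(
            activity=activity,
            location=location,
            beta_G=float(g.values[iG]),
            c_d=sol.c_d,
            lambda_setting=lambda_setting,
            theta_lower=float("nan"),
            theta_upper=float("nan"),
            empty=not bool(col_init.any()),
        )
        if col_init.any():
            # the continuation run containing the initiation set
            seed_i = int(np.nonzero(col_init)[0][0])
            lo = seed_i
            while lo > 0 and col_cont[lo - 1]:
                lo -= 1
            hi = seed_i
            while hi < g.n_P - 1 and col_cont[hi + 1]:
                hi += 1
            if lo > 0:
                row["theta_lower"] = float(g.values[lo])
            if hi < g.n_P - 1:
                row["theta_upper"] = float(g.values[hi])
        rows.append(row)
    return pd.DataFrame(rows)


def fit_linear_thresholds(tab: pd.DataFrame) -> pd.DataFrame:
    """Least-squares planes ``theta ~ w0 + w1*beta_G + w2*c_d``.

    One fit per (activity, location, boundary side), over the rows where that
    boundary exists; rows with missing boundaries are excluded, not imputed.
    Returns coefficients with residual summaries.
    """
    fits = []
    for (activity, location), sub in tab.groupby(["activity", "location"]):
        for side in ("lower", "upper"):
            vals = sub[f"theta_{side}"]
            ok = vals.notna() & ~sub["empty"]
            if ok.sum() < 3:
                continue
            X = np.column_stack(
                [np.ones(ok.sum()), sub.loc[ok, "beta_G"], sub.loc[ok, "c_d"]]
            )
            y = vals[ok].to_numpy()
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            fits.append(
                dict(
                    activity=activity,
                    location=location,
                    boundary=side,
                    w0=float(coef[0]),
                    w1_beta_G=float(coef[1]),
                    w2_c_d=float(coef[2]),
                    rmse=float(np.sqrt(np.mean(resid**2))),
                    max_abs_resid=float(np.max(np.abs(resid))),
                    n=int(ok.sum()),
                )
            )
    return pd.DataFrame(fits)


def threshold_interrupt_rule(fit: pd.DataFrame, c_d: float) -> InterruptRule:
    """Interrupt rule from fitted linear thresholds, for the trial harness.

    Feed and assess are interrupted when ``beta_P`` exits the predicted
    threshold box (predictions clipped to [0, 1]); activities without fitted
    boundaries are never interrupted.
    """
    table: Dict[tuple, Dict[str, float]] = {}
    for rec in fit.to_dict("records"):
        table.setdefault((rec["location"], rec["activity"]), {})[rec["boundary"]] = (
            rec["w0"],
            rec["w1_beta_G"],
            rec["w2_c_d"],
        )

    def rule(location: str, action: str, remaining: int, b: Belief) -> bool:
        bounds = table.get((location, action))
        if bounds is None or remaining < 1:
            return False
        if "upper" in bounds:
            w0, w1, w2 = bounds["upper"]
            theta = float(np.clip(w0 + w1 * b.beta_G + w2 * c_d, 0.0, 1.0))
            if b.beta_P > theta + _EPS:
                return True
        if "lower" in bounds:
            w0, w1, w2 = bounds["lower"]
            theta = float(np.clip(w0 + w1 * b.beta_G + w2 * c_d, 0.0, 1.0))
            if b.beta_P < theta - _EPS:
                return True
        return False

    return rule


def evaluate_approx_policy(
    fit: pd.DataFrame,
    sol_non: Solution,
    sol_int: Solution,
    proto: Protocol,
    n_trials: int = 200,
    seed: int = 0,
) -> dict:
    """Matched comparison of exact vs threshold-approximated interruption.

    The approximate policy uses the exact interruptible solution's actions and
    durations but triggers interruption by the fitted linear thresholds.
    Returns mean rewards and non-interrupt/interrupt ratios for both the exact
    and the approximate interruptible policies, on common random numbers.
    """
    rule = threshold_interrupt_rule(fit, sol_int.c_d)
    m_non = matched_metrics(sol_non, proto, n_trials, seed, record=False)
    m_int = matched_metrics(sol_int, proto, n_trials, seed, record=False)
    m_app = matched_metrics(sol_int, proto, n_trials, seed, interrupt_rule=rule,
                            record=False)

    def _ratio(a, b):
        return 1.0 if np.allclose(a.rewards, b.rewards) else a.mean_reward / b.mean_reward

    return dict(
        c_d=sol_int.c_d,
        mean_reward_noninterrupt=m_non.mean_reward,
        mean_reward_exact=m_int.mean_reward,
        mean_reward_approx=m_app.mean_reward,
        ratio_exact=_ratio(m_non, m_int),
        ratio_approx=_ratio(m_non, m_app),
    )


def sweep_cue_reliability(
    p: ModelParams,
    settings: Sequence[tuple],
    c_d_grid: Sequence[float],
    activities: Sequence[tuple] = (("feed", PATCH), ("assess", PATCH), ("assess", REFUGE)),
    beta_G: float = 0.5,
    tol: float = 1e-8,
    progress: Optional[Callable[[str], None]] = None,
) -> pd.DataFrame:
    """Thresholds as a function of cue reliability.

    ``settings`` is a sequence of ``(param_name, value)`` pairs, e.g.
    ``("lambda_oi_plus", 0.25)``; each re-solves the interruptible model per
    decision cost and extracts thresholds at fixed ``beta_G``.
    """
    rows = []
    for name, value in settings:
        pv = p.with_(**{name: value})
        grid = BeliefGrid(pv.d_beta)
        ops = build_operators(pv, grid)
        warm = None
        for c_d in c_d_grid:
            pc = pv.with_(c_d=float(c_d))
            sol = value_iteration(pc, interruptible=True, tol=tol, grid=grid,
                                  operators=ops, v0=warm)
            warm = sol.V
            for activity, location in activities:
                rows.append(
                    extract_thresholds(
                        sol, activity, location, [beta_G],
                        lambda_setting=f"{name}={value}",
                    )
                )
            if progress is not None:
                progress(f"{name}={value} c_d={c_d}")
    return pd.concat(rows, ignore_index=True)
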