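"""Belief propagation and Bayesian updating for the two hidden telegraph processes.

The agent's sufficient statistic is the pair ``(beta_P, beta_G)``: the
posterior probability that a predator is present and that the habitat is good.
Between observations each component relaxes exponentially toward the
stationary probability of its two-state chain (closed form
:func:`propagate_belief`); within a time step the solver and simulator use the
short-step approximation :func:`propagate_belief_step`.  Observations (indirect
cue, direct cue, feed outcome) are folded in by two-hypothesis Bayes rule with
per-step likelihoods ``lambda*dt`` for an emission and ``1 - lambda*dt`` for an
omission; channels that are unavailable for the current action contribute
nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams

__all__ = [
    "Belief",
    "BeliefGrid",
    "propagate_belief",
    "propagate_belief_step",
    "update_predator_belief",
    "update_habitat_belief",
    "snap_to_grid",
]


@dataclass(frozen=True)
class Belief:
    beta_P: float  # probability the predator is present
    beta_G: float  # probability the habitat is good

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta_P <= 1.0 and 0.0 <= self.beta_G <= 1.0):
            raise ValueError(f"belief components must lie in [0, 1]: {self}")


def propagate_belief(b: Belief, tau: float, p: ModelParams) -> Belief:
    """Observation-free belief evolution over a duration ``tau`` (closed form).

    Each component decays exponentially toward its chain's stationary value,
    ``beta(t+tau) = eq + (beta(t) - eq) * exp(-(rate_sum) * tau)``.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    eq_P = p.predator_equilibrium
    eq_G = p.habitat_equilibrium
    bP = eq_P + (b.beta_P - eq_P) * np.exp(-(p.gamma_AP + p.gamma_PA) * tau)
    bG = eq_G + (b.beta_G - eq_G) * np.exp(-(p.gamma_BG + p.gamma_GB) * tau)
    return Belief(float(bP), float(bG))


def propagate_belief_step(b: Belief, p: ModelParams) -> Belief:
    """One-step (``dt``) observation-free prior.

    Short-step approximation: probability mass that was 'present' survives with
    ``exp(-gamma_PA*dt)`` and 'absent' mass arrives with
    ``1 - exp(-gamma_AP*dt)`` (and analogously for habitat quality).
    """
    bP, bG = _propagate_step_arrays(
        np.asarray(b.beta_P), np.asarray(b.beta_G), p
    )
    return Belief(float(bP), float(bG))


def _propagate_step_arrays(bP: np.ndarray, bG: np.ndarray, p: ModelParams):
    """Vectorized one-step prior used by the solver on whole grids."""
    sP = np.exp(-p.gamma_PA * p.dt)
    aP = 1.0 - np.exp(-p.gamma_AP * p.dt)
    sG = np.exp(-p.gamma_GB * p.dt)
    aG = 1.0 - np.exp(-p.gamma_BG * p.dt)
    return bP * sP + (1.0 - bP) * aP, bG * sG + (1.0 - bG) * aG


def _cue_likelihoods(seen: bool, lam_plus: float, lam_minus: float, dt: float):
    """(L_present, L_absent) for one cue channel outcome."""
    if seen:
        return lam_plus * dt, lam_minus * dt
    return 1.0 - lam_plus * dt, 1.0 - lam_minus * dt


def update_predator_belief(prior: Belief, obs, p: ModelParams) -> Belief:
    """Bayes update of ``beta_P`` on the step's cue outcomes.

    ``obs`` carries ternary flags ``oi_seen`` / ``od_seen`` (True, False, or
    None when the channel was unavailable).  Likelihoods multiply across
    available channels; an omission on an available channel is evidence in
    itself (complement likelihoods), while an unavailable channel is ignored.
    """
    L_p = 1.0
    L_a = 1.0
    if obs.oi_seen is not None:
        lp, la = _cue_likelihoods(obs.oi_seen, p.lambda_oi_plus, p.lambda_oi_minus, p.dt)
        L_p *= lp
        L_a *= la
    if obs.od_seen is not None:
        lp, la = _cue_likelihoods(obs.od_seen, p.lambda_od_plus, p.lambda_od_minus, p.dt)
        L_p *= lp
        L_a *= la
    num = L_p * prior.beta_P
    den = num + L_a * (1.0 - prior.beta_P)
    if den <= 0.0:
        return prior
    return Belief(float(num / den), prior.beta_G)


def update_habitat_belief(prior: Belief, feed_outcome: str, p: ModelParams) -> Belief:
    """Bayes update of ``beta_G`` on a feed step's encounter outcome.

    ``feed_outcome`` is ``'rich'``, ``'poor'`` or ``'none'`` (no encounter in
    the step); encounter probabilities are ``rho*dt`` conditioned on habitat.
    """
    dt = p.dt
    if feed_outcome == "rich":
        L_g, L_b = p.rho_rG * dt, p.rho_rB * dt
    elif feed_outcome == "poor":
        L_g, L_b = p.rho_pG * dt, p.rho_pB * dt
    elif feed_outcome == "none":
        L_g = 1.0 - (p.rho_rG + p.rho_pG) * dt
        L_b = 1.0 - (p.rho_rB + p.rho_pB) * dt
    else:
        raise ValueError(f"feed_outcome must be rich/poor/none, got {feed_outcome!r}")
    num = L_g * prior.beta_G
    den = num + L_b * (1.0 - prior.beta_G)
    if den <= 0.0:
        return prior
    return Belief(prior.beta_P, float(num / den))


class BeliefGrid:
    """Regular grid over the belief square [0,1] x [0,1] at resolution ``d_beta``.

    Grid points are indexed in row-major order with ``beta_P`` as the slow axis:
    ``flat = iP * n_G + iG``.
    """

    def __init__(self, d_beta: float = 0.01):
        if not 0 < d_beta <= 0.5:
            raise ValueError("d_beta must be in (0, 0.5]")
        self.d_beta = d_beta
        n = int(round(1.0 / d_beta)) + 1
        self.n_P = n
        self.n_G = n
        self.values = np.linspace(0.0, 1.0, n)
        bP, bG = np.meshgrid(self.values, self.values, indexing="ij")
        self.beta_P = bP.ravel()  # (n_P*n_G,)
        self.beta_G = bG.ravel()

    @property
    def n_points(self) -> int:
        return self.n_P * self.n_G

    def flat_index(self, iP, iG):
        return np.asarray(iP) * self.n_G + np.asarray(iG)

    def interp_weights(self, bP, bG, mode: str = "bilinear"):
        """Map beliefs to grid indices and weights.

        Returns ``(idx, w)`` of shapes ``(m, 4)`` (``(m, 1)`` for nearest):
        convex weights over the surrounding grid points, summing to one.
        """
        bP = np.atleast_1d(np.clip(np.asarray(bP, dtype=float), 0.0, 1.0))
        bG = np.atleast_1d(np.clip(np.asarray(bG, dtype=float), 0.0, 1.0))
        if mode == "nearest":
            iP = np.rint(bP / self.d_beta).astype(np.intp)
            iG = np.rint(bG / self.d_beta).astype(np.intp)
            return self.flat_index(iP, iG)[:, None], np.ones((bP.size, 1))
        if mode != "bilinear":
            raise ValueError(f"unknown grid mode {mode!r}")
        fP = bP / self.d_beta
        fG = bG / self.d_beta
        iP0 = np.clip(np.floor(fP).astype(np.intp), 0, self.n_P - 2)
        iG0 = np.clip(np.floor(fG).astype(np.intp), 0, self.n_G - 2)
        tP = fP - iP0
        tG = fG - iG0
        idx = np.stack(
            [
                self.flat_index(iP0, iG0),
                self.flat_index(iP0, iG0 + 1),
                self.flat_index(iP0 + 1, iG0),
                self.flat_index(iP0 + 1, iG0 + 1),
            ],
            axis=1,
        )
        w = np.stack(
            [
                (1 - tP) * (1 - tG),
                (1 - tP) * tG,
                tP * (1 - tG),
                tP * tG,
            ],
            axis=1,
        )
        return idx, w

    def interpolate(self, values: np.ndarray, bP, bG, mode: str = "bilinear"):
        """Evaluate a grid-valued function at arbitrary beliefs."""
        idx, w = self.interp_weights(bP, bG, mode=mode)
        out = (values[idx] * w).sum(axis=1)
        return out if out.size > 1 else float(out[0])


def snap_to_grid(b: Belief, g: BeliefGrid, mode: str = "bilinear"):
    """Grid coordinates and convex weights representing a belief on the grid."""
    idx, w = g.interp_weights([b.beta_P], [b.beta_G], mode=mode)
    keep = w[0] > 0
    return idx[0][keep], w[0][keep]
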