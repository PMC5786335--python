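"""Generative simulator of the hidden environment.

The environment carries two hidden binary telegraph processes — predator
present/absent (rates ``gamma_AP``/``gamma_PA``) and habitat good/bad
(``gamma_GB``/``gamma_BG``) — plus the animal's observable location.  Per step
of length ``dt`` a hidden state flips with probability ``1 - exp(-rate*dt)``.
Observations depend on the current action: the passive indirect cue ``o_i`` is
available during every activity except rest; the direct cue ``o_d`` only
during assess; rich/poor patch encounters only during feed; and detection by a
present predator occurs at the action's detection rate whenever the animal is
exposed (in the patch, or in transit to it).

Randomness is organised as named per-channel streams of step-indexed uniforms
(:class:`EventStreams`) so that two policies simulated with the same seed face
exactly the same world — the common-random-numbers device used for matched
policy comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .params import ModelParams, ParamError, legal_actions, PATCH, REFUGE

__all__ = ["WorldState", "Observation", "EventStreams", "step_hidden_state",
           "sample_observation", "flip_probability"]

_CHANNELS = ("predator", "habitat", "oi", "od", "detect", "encounter", "policy")


@dataclass(frozen=True)
class WorldState:
    location: str = REFUGE
    predator: bool = False  # True = present
    habitat_good: bool = True
    clock: float = 0.0


@dataclass(frozen=True)
class Observation:
    """What the animal perceives in one step.

    Ternary cue flags are ``True`` (seen), ``False`` (available but not seen)
    or ``None`` (channel unavailable for the current action).
    """

    oi_seen: Optional[bool] = None
    od_seen: Optional[bool] = None
    feed_outcome: str = "unavailable"  # rich | poor | none | unavailable
    detected: bool = False


class EventStreams:
    """Step-indexed uniform random numbers, one independent stream per channel.

    ``u(channel, t)`` is a deterministic function of ``(seed, channel, t)``,
    so simulations consuming different subsets of channels (because policies
    differ) still see identical event outcomes on the channels they share.
    """

    def __init__(self, seed: int, block: int = 512):
        self._block = block
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(len(_CHANNELS))
        self._rngs = {name: np.random.default_rng(c)
                      for name, c in zip(_CHANNELS, children)}
        self._buf: dict[str, np.ndarray] = {
            name: np.empty(0) for name in _CHANNELS
        }

    def u(self, channel: str, t: int) -> float:
        buf = self._buf[channel]
        while t >= buf.size:
            more = self._rngs[channel].random(self._block)
            buf = np.concatenate([buf, more])
            self._buf[channel] = buf
        return float(buf[t])


def flip_probability(rate: float, dt: float) -> float:
    """Per-step probability of a rate-``rate`` event: ``1 - exp(-rate*dt)``."""
    return 1.0 - np.exp(-rate * dt)


def step_hidden_state(
    s: WorldState,
    dt: float,
    p: ModelParams,
    rng,
    t: Optional[int] = None,
    forced_predator: Optional[bool] = None,
) -> WorldState:
    """Advance the hidden telegraph processes by one step of length ``dt``.

    ``rng`` is either a numpy Generator or an :class:`EventStreams` (then ``t``
    must be the step index).  ``forced_predator`` overrides the predator
    dynamics with a scripted value (used by experiment protocols); habitat
    always runs free.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    u_pred, u_hab = _draw(rng, t, "predator"), _draw(rng, t, "habitat")
    if forced_predator is not None:
        predator = forced_predator
    else:
        rate = p.gamma_PA if s.predator else p.gamma_AP
        predator = (not s.predator) if u_pred < flip_probability(rate, dt) else s.predator
    rate_h = p.gamma_GB if s.habitat_good else p.gamma_BG
    habitat = (not s.habitat_good) if u_hab < flip_probability(rate_h, dt) else s.habitat_good
    return replace(s, predator=predator, habitat_good=habitat, clock=s.clock + dt)


def _draw(rng, t, channel: str) -> float:
    if isinstance(rng, EventStreams):
        if t is None:
            raise ValueError("step index t required with EventStreams")
        return rng.u(channel, t)
    return float(rng.random())


def oi_available(action: str) -> bool:
    """The passive cue is available during every activity except rest."""
    return action != "rest"


def is_exposed(location: str, action: str) -> bool:
    """Whether the animal can be detected this step (patch, or en route to it)."""
    return location == PATCH or action == "transit"


def sample_observation(
    action: str,
    location: str,
    s: WorldState,
    p: ModelParams,
    rng,
    t: Optional[int] = None,
) -> Observation:
    """Sample one step's observation given the *current* hidden state.

    Detection is evaluated first (a detected step truncates the activity and
    delivers no cues); cue and encounter channels then draw independently with
    per-step probabilities ``lambda*dt`` / ``rho*dt``.
    """
    if action not in legal_actions(location):
        raise ParamError(f"action {action!r} illegal in location {location!r}")
    dt = p.dt
    if is_exposed(location, action) and s.predator:
        delta = p.delta_by_action[action]
        if _draw(rng, t, "detect") < flip_probability(delta, dt):
            return Observation(detected=True)
    oi = None
    if oi_available(action):
        lam = p.lambda_oi_plus if s.predator else p.lambda_oi_minus
        oi = _draw(rng, t, "oi") < lam * dt
    od = None
    if action == "assess":
        lam = p.lambda_od_plus if s.predator else p.lambda_od_minus
        od = _draw(rng, t, "od") < lam * dt
    feed_outcome = "unavailable"
    if action == "feed":
        if s.habitat_good:
            p_rich, p_poor = p.rho_rG * dt, p.rho_pG * dt
        else:
            p_rich, p_poor = p.rho_rB * dt, p.rho_pB * dt
        u = _draw(rng, t, "encounter")
        if u < p_rich:
            feed_outcome = "rich"
        elif u < p_rich + p_poor:
            feed_outcome = "poor"
        else:
            feed_outcome = "none"
    return Observation(oi_seen=oi, od_seen=od, feed_outcome=feed_outcome)
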