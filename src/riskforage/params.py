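"""Parameter containers for the foraging-under-predation model.

Two parameterizations are provided:

* :class:`ModelParams` — the full two-location model: a telegraph-process
  predator (absent/present, rates ``gamma_AP``/``gamma_PA``), a
  telegraph-process habitat quality (good/bad, rates ``gamma_GB``/``gamma_BG``),
  indirect and direct predator cues emitted at hypothesis-dependent rates,
  rich/poor patch encounters while feeding, action-dependent detection rates,
  reward rates per action, a one-off predation penalty, a per-decision cost
  ``c_d`` and exponential temporal discounting at rate ``alpha``.
* :class:`SimpleParams` — the stripped-down single-location model
  (feed/assess/escape, a predator that arrives and stays, undiscounted,
  terminating on escape or capture).

All continuous-time rates are interpreted per second and are discretized at the
time step ``dt`` by the solver and simulator (per-step flip/detection
probability ``1 - exp(-rate*dt)``, per-step cue-emission probability
``rate*dt``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

__all__ = [
    "ModelParams",
    "SimpleParams",
    "ParamError",
    "validate_params",
    "REFUGE",
    "PATCH",
    "REFUGE_ACTIONS",
    "PATCH_ACTIONS",
    "ACTION_ORDER",
]

REFUGE = "refuge"
PATCH = "patch"

#: Actions legal in each location.
REFUGE_ACTIONS = ("rest", "assess", "transit")
PATCH_ACTIONS = ("feed", "assess", "freeze", "escape")

#: Deterministic tie-break order used by the solver when several actions are
#: value-equivalent at a grid point.
ACTION_ORDER = ("rest", "feed", "assess", "freeze", "transit", "escape")


class ParamError(ValueError):
    """A model-parameter invariant is violated; the message names it."""


@dataclass(frozen=True)
class ModelParams:
    # hidden-state transition rates (per second)
    gamma_AP: float = 0.01
    gamma_PA: float = 0.01
    gamma_GB: float = 0.01
    gamma_BG: float = 0.01
    # cue emission rates (per second): + when predator present, - when absent
    lambda_oi_plus: float = 0.5
    lambda_oi_minus: float = 0.1
    lambda_od_plus: float = 0.9
    lambda_od_minus: float = 0.1
    # patch-encounter rates while feeding (per second)
    rho_rG: float = 0.8
    rho_pG: float = 0.2
    rho_rB: float = 0.2
    rho_pB: float = 0.8
    # reward rates (per second); r_pred is a one-off penalty, not a rate
    r_feed_rich: float = 2.0
    r_feed_poor: float = 1.0
    r_rest: float = 0.0
    r_transit: float = -0.1
    r_assess: float = -0.1
    r_freeze: float = -0.1
    r_escape: float = -1.0
    r_pred: float = -100.0
    # detection rates per action while exposed (per second)
    delta_by_action: Mapping[str, float] = field(
        default_factory=lambda: {
            "feed": 0.05,
            "transit": 0.05,
            "escape": 0.05,
            "assess": 0.02,
            "freeze": 0.01,
            "rest": 0.0,
        }
    )
    # decision cost per decision epoch and discount rate (per second)
    c_d: float = 0.0
    alpha: float = 0.1
    # discretization
    dt: float = 1.0
    d_beta: float = 0.01
    tau_set: Sequence[int] = tuple(range(1, 16))
    # whether escape relocates the animal to the refuge at activity end
    escape_effective: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "tau_set", tuple(self.tau_set))
        object.__setattr__(self, "delta_by_action", dict(self.delta_by_action))
        validate_params(self)

    # -- convenience -------------------------------------------------------
    @property
    def predator_equilibrium(self) -> float:
        """Stationary probability that the predator is present."""
        return self.gamma_AP / (self.gamma_AP + self.gamma_PA)

    @property
    def habitat_equilibrium(self) -> float:
        """Stationary probability that the habitat is good."""
        return self.gamma_BG / (self.gamma_BG + self.gamma_GB)

    @property
    def tau_max(self) -> int:
        return max(self.tau_set)

    def reward_rate(self, action: str) -> float:
        return {
            "rest": self.r_rest,
            "assess": self.r_assess,
            "transit": self.r_transit,
            "feed": 0.0,  # feed reward is encounter-dependent
            "freeze": self.r_freeze,
            "escape": self.r_escape,
        }[action]

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tau_set"] = list(self.tau_set)
        d["delta_by_action"] = dict(self.delta_by_action)
        return d


@dataclass(frozen=True)
class SimpleParams:
    """Single-location terminating model: feed, assess or escape.

    The predator arrives with probability ``p_arrive`` per step and then stays;
    while it is present the animal is caught with probability ``p_catch`` per
    step if it has not escaped.  Feeding pays ``r_feed`` per step; capture pays
    the one-off ``r_catch``; escape and capture terminate the trial.  The
    objective is the undiscounted expected total reward.  Feeding receives the
    indirect predator cue only; assessing receives both the indirect and the
    more reliable direct cue.
    """

    p_arrive: float = 0.01
    p_catch: float = 0.1
    r_feed: float = 1.0
    r_catch: float = -100.0
    c_d: float = 0.0
    # per-step cue probabilities (+ predator present, - absent)
    lambda_oi_plus: float = 0.5
    lambda_oi_minus: float = 0.1
    lambda_od_plus: float = 0.9
    lambda_od_minus: float = 0.1
    d_beta: float = 0.01
    tau_set: Sequence[int] = tuple(range(1, 16))

    def __post_init__(self) -> None:
        object.__setattr__(self, "tau_set", tuple(self.tau_set))
        for name in ("p_arrive", "p_catch", "lambda_oi_plus", "lambda_oi_minus",
                     "lambda_od_plus", "lambda_od_minus"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParamError(f"{name} must be a probability in [0, 1], got {v}")
        if self.c_d < 0:
            raise ParamError("c_d must be >= 0")
        _check_tau_set(self.tau_set)
        if not 0 < self.d_beta <= 0.5:
            raise ParamError("d_beta must be in (0, 0.5]")

    @property
    def tau_max(self) -> int:
        return max(self.tau_set)

    def with_(self, **kwargs) -> "SimpleParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tau_set"] = list(self.tau_set)
        return d


def _check_tau_set(tau_set: Sequence[int]) -> None:
    if len(tau_set) == 0:
        raise ParamError("tau_set must be non-empty")
    if any(t <= 0 for t in tau_set):
        raise ParamError("tau_set entries must be positive")
    if list(tau_set) != sorted(tau_set):
        raise ParamError("tau_set must be sorted ascending")


def validate_params(p: ModelParams) -> ModelParams:
    """Validate a :class:`ModelParams`; returns it unchanged if all invariants hold.

    Raises :class:`ParamError` naming the first violated invariant.
    """
    rate_fields = [
        "gamma_AP", "gamma_PA", "gamma_GB", "gamma_BG",
        "lambda_oi_plus", "lambda_oi_minus", "lambda_od_plus", "lambda_od_minus",
        "rho_rG", "rho_pG", "rho_rB", "rho_pB",
    ]
    for name in rate_fields:
        v = getattr(p, name)
        if v < 0:
            raise ParamError(f"rate {name} must be >= 0, got {v}")
        if v * p.dt > 1.0 + 1e-12:
            raise ParamError(
                f"rate*dt for {name} is {v * p.dt:.3g} > 1; per-step event "
                "probability would be invalid"
            )
    for rho_r, rho_p, hab in ((p.rho_rG, p.rho_pG, "good"), (p.rho_rB, p.rho_pB, "bad")):
        if (rho_r + rho_p) * p.dt > 1.0 + 1e-12:
            raise ParamError(
                f"(rho_r + rho_p)*dt in {hab} habitat exceeds 1; encounter "
                "probabilities would be invalid"
            )
    if p.dt <= 0:
        raise ParamError("dt must be > 0")
    # reward ordering for the net-negative actions
    if not (p.r_escape < p.r_transit <= p.r_assess <= p.r_freeze):
        raise ParamError(
            "reward ordering violated: require r_escape < r_transit <= "
            "r_assess <= r_freeze"
        )
    # detection-rate ordering
    d = p.delta_by_action
    missing = set(ACTION_ORDER) - set(d)
    if missing:
        raise ParamError(f"delta_by_action missing actions: {sorted(missing)}")
    for a, v in d.items():
        if v < 0:
            raise ParamError(f"delta_by_action[{a!r}] must be >= 0")
        if v * p.dt > 1.0 + 1e-12:
            raise ParamError(f"delta_by_action[{a!r}]*dt > 1")
    if not (d["escape"] >= d["transit"] >= d["feed"] > d["assess"] > d["freeze"]):
        raise ParamError(
            "detection ordering violated: require delta_escape >= delta_transit "
            ">= delta_feed > delta_assess > delta_freeze"
        )
    if p.c_d < 0:
        raise ParamError("c_d must be >= 0")
    if not 0.0 <= p.alpha <= 1.0:
        raise ParamError("alpha must be in [0, 1]")
    _check_tau_set(p.tau_set)
    if not 0 < p.d_beta <= 0.5:
        raise ParamError("d_beta must be in (0, 0.5]")
    return p


def legal_actions(location: str) -> tuple[str, ...]:
    """Actions available in a location."""
    if location == REFUGE:
        return REFUGE_ACTIONS
    if location == PATCH:
        return PATCH_ACTIONS
    raise ParamError(f"unknown location {location!r}")
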