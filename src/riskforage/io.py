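"""Configuration loading, solution serialization and packaged defaults.

Configurations are flat YAML files with ``model:`` (ModelParams or
SimpleParams fields), ``solver:``, ``protocol:`` and ``seed:`` sections;
missing model fields fall back to the packaged default parameter fixture.
Solutions are written as inspectable CSV grids (one per location) plus a JSON
metadata sidecar carrying parameters and convergence diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .belief import BeliefGrid
from .experiments import Protocol
from .params import ModelParams, ParamError, SimpleParams, PATCH, REFUGE, legal_actions
from .solver import Solution, activity_value, build_operators

__all__ = ["RunConfig", "load_config", "save_config", "default_config",
           "write_solution", "read_solution", "write_trace"]

_MODEL_KEYS = set(ModelParams.__dataclass_fields__)
_SIMPLE_KEYS = set(SimpleParams.__dataclass_fields__)
_SOLVER_KEYS = {"tol", "max_iter", "grid_mode", "interruptible", "tie_tol"}
_PROTOCOL_KEYS = {"segments", "n_trials"}


@dataclass(frozen=True)
class RunConfig:
    kind: str  # "full" | "simple"
    model: object  # ModelParams | SimpleParams
    tol: float = 1e-8
    max_iter: int = 10_000
    grid_mode: str = "bilinear"
    interruptible: bool = False
    protocol: Protocol = field(default_factory=Protocol)
    n_trials: int = 1000
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return dict(
            kind=self.kind,
            model=self.model.to_dict(),
            solver=dict(tol=self.tol, max_iter=self.max_iter,
                        grid_mode=self.grid_mode, interruptible=self.interruptible),
            protocol=dict(
                segments=[[float(d), bool(pr)] for d, pr in self.protocol.segments],
                n_trials=self.n_trials,
            ),
            seed=self.seed,
        )


def _packaged_defaults(kind: str) -> dict:
    name = "full_default.yaml" if kind == "full" else "simple_default.yaml"
    with resources.files("riskforage.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def _build(raw: dict) -> RunConfig:
    kind = raw.get("kind", "full")
    if kind not in ("full", "simple"):
        raise ParamError(f"kind must be 'full' or 'simple', got {kind!r}")
    defaults = _packaged_defaults(kind)
    model_raw = dict(defaults.get("model", {}))
    model_raw.update(raw.get("model") or {})
    valid_keys = _MODEL_KEYS if kind == "full" else _SIMPLE_KEYS
    unknown = set(model_raw) - valid_keys
    if unknown:
        raise ParamError(f"unknown model keys: {sorted(unknown)}")
    model = (ModelParams if kind == "full" else SimpleParams)(**model_raw)

    solver_raw = dict(defaults.get("solver", {}))
    solver_raw.update(raw.get("solver") or {})
    unknown = set(solver_raw) - _SOLVER_KEYS
    if unknown:
        raise ParamError(f"unknown solver keys: {sorted(unknown)}")
    solver_raw.pop("tie_tol", None)

    proto_raw = dict(defaults.get("protocol", {}))
    proto_raw.update(raw.get("protocol") or {})
    unknown = set(proto_raw) - _PROTOCOL_KEYS
    if unknown:
        raise ParamError(f"unknown protocol keys: {sorted(unknown)}")
    segments = tuple(
        (float(d), bool(pr)) for d, pr in proto_raw.get("segments", Protocol().segments)
    )
    unknown = set(raw) - {"kind", "model", "solver", "protocol", "seed"}
    if unknown:
        raise ParamError(f"unknown config sections: {sorted(unknown)}")
    return RunConfig(
        kind=kind,
        model=model,
        tol=float(solver_raw.get("tol", 1e-8)),
        max_iter=int(solver_raw.get("max_iter", 10_000)),
        grid_mode=str(solver_raw.get("grid_mode", "bilinear")),
        interruptible=bool(solver_raw.get("interruptible", False)),
        protocol=Protocol(segments),
        n_trials=int(proto_raw.get("n_trials", 1000)),
        seed=raw.get("seed"),
    )


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _build(raw)


def default_config(kind: str = "full") -> RunConfig:
    """The packaged default configuration (the standard model parameters)."""
    return _build({"kind": kind})


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# solution serialization


def write_solution(sol: Solution, outdir) -> None:
    """Policy/value grids as CSV per location plus a JSON metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = sol.grid
    for loc in (REFUGE, PATCH):
        df = pd.DataFrame(
            {
                "beta_P": g.beta_P,
                "beta_G": g.beta_G,
                "action": sol.policy_action[loc],
                "tau": sol.policy_tau[loc],
                "value": sol.V[loc],
            }
        )
        # shortest round-tripping decimal representation for exact reload
        df.to_csv(outdir / f"policy_{loc}.csv", index=False,
                  float_format=lambda x: repr(float(x)))
    meta = dict(
        package_version=__version__,
        params=sol.params.to_dict(),
        interruptible=sol.interruptible,
        grid_mode=sol.grid_mode,
        d_beta=g.d_beta,
        tol=sol.tol,
        iterations=sol.iterations,
        residual=sol.residual,
        converged=sol.converged,
    )
    with open(outdir / "solution.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_solution(outdir) -> Solution:
    """Reconstruct a Solution from :func:`write_solution` output.

    The committed-value tables are recomputed from the stored value function
    (one backup pass over the stored ``V``), reproducing the solve's own
    final extraction path.
    """
    outdir = Path(outdir)
    with open(outdir / "solution.json") as fh:
        meta = json.load(fh)
    p = ModelParams(**meta["params"])
    g = BeliefGrid(meta["d_beta"])
    V, policy_action, policy_tau = {}, {}, {}
    for loc in (REFUGE, PATCH):
        df = pd.read_csv(outdir / f"policy_{loc}.csv", float_precision="round_trip")
        if list(df.columns) != ["beta_P", "beta_G", "action", "tau", "value"]:
            raise ParamError(f"unexpected schema in policy_{loc}.csv")
        V[loc] = df["value"].to_numpy()
        policy_action[loc] = df["action"].to_numpy(dtype="<U8")
        policy_tau[loc] = df["tau"].to_numpy(dtype=np.int64)
    ops = build_operators(p, g, grid_mode=meta["grid_mode"])
    backups = {
        loc: {
            a: activity_value(ops[(loc, a)], V, p, meta["interruptible"])
            for a in legal_actions(loc)
        }
        for loc in (REFUGE, PATCH)
    }
    return Solution(
        params=p,
        grid=g,
        interruptible=meta["interruptible"],
        V=V,
        policy_action=policy_action,
        policy_tau=policy_tau,
        backups=backups,
        iterations=meta["iterations"],
        residual=meta["residual"],
        converged=meta["converged"],
        tol=meta["tol"],
        grid_mode=meta["grid_mode"],
    )


def write_trace(trace, path) -> None:
    """Tidy per-step trial record as CSV."""
    trace.frame.to_csv(path, index=False)
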