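"""Configuration files, figure presets and trajectory serialisation.

Run configuration is a YAML mapping using the published parameter names
(``alpha``, ``d``, ``lam``, ``b``, ``kA``, ``uout``, ``s``, ``tau0``, ``k``,
``kC``, ``cac0``, ``a``, ``alpha_K``, ``lam_K``, ``d_K``, ``b1``,
``nu_Ca_st``, ``nu_K_st``, ``rho``, ``vCah``, ``lam_h``, ``d_h``,
``alpha_h``, ...).  Unknown keys are rejected so silent typos cannot change
a simulation.  Omitted keys fall back to the published defaults.

Figure presets bundle the parameter rows of the published parameter table by
figure number (fig2 ... fig14) so each study setting can be re-run with one
name.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clamp import ClampModelParams, ClampProtocol, Mechanism, Trajectory
from .conductances import (
    CA_CONDUCTANCE,
    H_CONDUCTANCE,
    K_CONDUCTANCE,
    T_CONDUCTANCE,
    SigmoidConductanceParams,
)
from .free_membrane import CoupledModelParams, CurrentSchedule
from .gating import CiliumBodyParams, DirectGatingParams, IndirectGatingParams

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "config_from_dict",
    "clamp_params_from_config",
    "coupled_params_from_config",
    "protocol_from_config",
    "schedule_from_config",
    "PRESETS",
    "preset_config",
    "write_trajectory",
    "write_table",
    "read_trajectory",
]

_VERSION = "0.1.0"


class ConfigError(ValueError):
    """Schema violation in a run configuration."""


# parameter-section keys: every published symbol plus simulator knobs
_PARAM_KEYS = {
    # Ca2+ conductance sigmoid
    "alpha", "d", "lam",
    # clamp / flux groups
    "s", "a", "b", "b1", "kA", "uout", "psiK",
    # direct / indirect gating
    "k", "kC", "cac0",
    # K+ conductance sigmoid
    "alpha_K", "d_K", "lam_K",
    # hyperpolarisation-activated family
    "vCah", "alpha_h", "d_h", "lam_h",
    # Ca2+-dependent K+ and cilium-to-body terms
    "vKca", "vCat", "alpha_t", "d_t", "lam_t", "psi_tr", "ut", "nu_t",
    # coupled-system groups
    "rho", "nu_Ca_st", "nu_K_st", "I0",
    # numerics
    "rtol", "atol", "psi_log_uses_ut",
}
_PROTOCOL_KEYS = {"psi0", "psi1", "tau0", "tauK", "duration", "mechanism", "include_K"}
_TOP_KEYS = {"kind", "params", "protocol", "schedule", "variant", "I0", "duration", "seed", "out"}
_SCHEDULE_KEYS = {"baseline", "segments"}


class RunConfig(dict):
    """A validated run configuration (a thin dict with provenance info)."""

    #: keys that were supplied by the user rather than filled from defaults
    user_keys: set

    def __init__(self, data: dict, user_keys: set):
        super().__init__(data)
        self.user_keys = user_keys


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {where}: {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def config_from_dict(data: dict | None) -> RunConfig:
    """Validate a raw mapping into a RunConfig; unknown keys are an error."""
    data = dict(data or {})
    _check_keys(data, _TOP_KEYS, "config")
    params = dict(data.get("params") or {})
    _check_keys(params, _PARAM_KEYS, "params")
    protocol = dict(data.get("protocol") or {})
    _check_keys(protocol, _PROTOCOL_KEYS, "protocol")
    schedule = dict(data.get("schedule") or {})
    _check_keys(schedule, _SCHEDULE_KEYS, "schedule")
    for key, val in params.items():
        if key == "psi_log_uses_ut":
            if not isinstance(val, bool):
                raise ConfigError(f"params.{key} must be boolean, got {val!r}")
        elif not isinstance(val, (int, float)) or isinstance(val, bool):
            raise ConfigError(f"params.{key} must be numeric, got {val!r}")
    user = {f"params.{k}" for k in params} | {f"protocol.{k}" for k in protocol}
    out = {
        "kind": data.get("kind", "clamp"),
        "params": params,
        "protocol": protocol,
        "schedule": schedule,
        "variant": data.get("variant", "base"),
        "I0": data.get("I0", 0.0),
        "duration": data.get("duration"),
        "seed": data.get("seed", 0),
    }
    return RunConfig(out, user)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration file.

    An empty file yields the full default (published) parameter set.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def _sigmoid(params: dict, prefix: str, default: SigmoidConductanceParams) -> SigmoidConductanceParams:
    suffix = f"_{prefix}" if prefix else ""
    return SigmoidConductanceParams(
        alpha=params.get(f"alpha{suffix}", default.alpha),
        d=params.get(f"d{suffix}", default.d),
        lam=params.get(f"lam{suffix}", default.lam),
    )


def clamp_params_from_config(cfg: RunConfig | dict) -> ClampModelParams:
    p = dict(cfg.get("params") or {})
    return ClampModelParams(
        s=p.get("s", 0.5),
        a=p.get("a", 4.0),
        b=p.get("b", 2.0),
        b1=p.get("b1", 1.0),
        kA=p.get("kA", 1.0),
        uout=p.get("uout", 1000.0),
        psiK=p.get("psiK", -0.4),
        direct=DirectGatingParams(k=p.get("k", 2.0)),
        indirect=IndirectGatingParams(kC=p.get("kC", 1.0), cac0=p.get("cac0", 20.0)),
        ca_cond=_sigmoid(p, "", CA_CONDUCTANCE),
        k_cond=_sigmoid(p, "K", K_CONDUCTANCE),
        cb=CiliumBodyParams(
            nu_t=p.get("nu_t", 0.0),
            psi_tr=p.get("psi_tr", 0.0),
            ut=p.get("ut", 0.025),
            cond=_sigmoid(p, "t", T_CONDUCTANCE),
        ),
        rtol=p.get("rtol", 1e-8),
        atol=p.get("atol", 1e-10),
    )


def coupled_params_from_config(cfg: RunConfig | dict) -> CoupledModelParams:
    p = dict(cfg.get("params") or {})
    return CoupledModelParams(
        s=p.get("s", 0.5),
        b=p.get("b", 8.0),
        b1=p.get("b1", 1.0),
        rho=p.get("rho", 10.0),
        kA=p.get("kA", 1.0),
        uout=p.get("uout", 1000.0),
        ut=p.get("ut", 0.025),
        psiK=p.get("psiK", -1.8),
        nuCa_st=p.get("nu_Ca_st", 0.01),
        nuK_st=p.get("nu_K_st", 0.01),
        vCah=p.get("vCah", 0.0),
        vKca=p.get("vKca", 0.0),
        vCat=p.get("vCat", 0.0),
        psi_tr=p.get("psi_tr", 0.0),
        I0=p.get("I0", cfg.get("I0", 0.0)),
        gating=IndirectGatingParams(kC=p.get("kC", 1.0), cac0=p.get("cac0", 20.0)),
        ca_cond=_sigmoid(p, "", CA_CONDUCTANCE),
        k_cond=_sigmoid(p, "K", K_CONDUCTANCE),
        h_cond=_sigmoid(p, "h", H_CONDUCTANCE),
        t_cond=_sigmoid(p, "t", T_CONDUCTANCE),
        psi_log_uses_ut=p.get("psi_log_uses_ut", False),
        rtol=p.get("rtol", 1e-8),
        atol=p.get("atol", 1e-10),
    )


def protocol_from_config(cfg: RunConfig | dict) -> ClampProtocol:
    pr = dict(cfg.get("protocol") or {})
    return ClampProtocol(
        psi0=pr.get("psi0", -1.2),
        psi1=pr.get("psi1", 0.5),
        tau0=pr.get("tau0", 0.02),
        tauK=pr.get("tauK", 0.02),
        duration=pr.get("duration", 30.0),
        mechanism=Mechanism(pr.get("mechanism", "direct")),
        include_K=bool(pr.get("include_K", False)),
    )


def schedule_from_config(cfg: RunConfig | dict) -> CurrentSchedule:
    sc = dict(cfg.get("schedule") or {})
    segments = tuple((float(a), float(b)) for a, b in (sc.get("segments") or []))
    return CurrentSchedule(segments=segments, baseline=float(sc.get("baseline", cfg.get("I0", 0.0))))


# ---------------------------------------------------------------------------
# figure presets: the published parameter rows grouped by figure number

PRESETS: dict[str, dict] = {
    "fig2": {
        "kind": "clamp",
        "params": {"alpha": 4, "d": 0.4, "lam": 0.5, "b": 2, "kA": 1, "uout": 1000, "s": 0.5, "k": 2},
        "protocol": {"psi0": -1.2, "psi1": 0.5, "tau0": 0.02, "mechanism": "direct", "duration": 30},
    },
    "fig3": {
        "kind": "clamp",
        "params": {"alpha": 4, "d": 0.4, "lam": 0.5, "b": 2, "kA": 1, "uout": 1000, "s": 0.5, "k": 2},
        "protocol": {"psi0": -1.2, "psi1": 0.5, "tau0": 0.02, "mechanism": "direct", "duration": 30},
    },
    "fig4": {
        "kind": "curves",
        "params": {"kC": 1, "cac0": 10},
    },
    "fig5": {
        "kind": "clamp",
        "params": {"alpha": 4, "d": 0.4, "lam": 0.5, "b": 2, "kA": 1, "uout": 1000, "a": 4, "kC": 1, "cac0": 10},
        "protocol": {"psi0": -1.2, "psi1": 0.5, "tau0": 0.02, "mechanism": "indirect", "duration": 30},
    },
    "fig6": {
        "kind": "clamp",
        "params": {"alpha": 4, "d": 0.4, "lam": 0.5, "b": 2, "kA": 1, "uout": 1000, "a": 4, "kC": 1, "cac0": 10},
        "protocol": {"psi0": -1.2, "psi1": 0.5, "tau0": 0.02, "mechanism": "indirect", "duration": 30},
    },
    "fig7": {
        "kind": "clamp",
        "params": {"alpha": 4, "d": 0.4, "lam": 0.5, "b": 2, "kA": 1, "uout": 1000, "a": 4, "kC": 1, "cac0": 10},
        "protocol": {"psi0": -1.2, "psi1": 0.5, "tau0": 0.02, "mechanism": "indirect", "duration": 30},
    },
    "fig8": {
        "kind": "curves",
        "params": {"alpha_K": 0.5, "lam_K": 0.005, "d_K": 0.5},
    },
    "fig9": {
        "kind": "clamp",
        "params": {"alpha": 4, "d": 0.4, "lam": 0.5, "b": 2, "b1": 1, "kA": 1, "uout": 1000,
                   "a": 4, "kC": 1, "cac0": 10, "alpha_K": 0.5, "lam_K": 0.005, "d_K": 0.5},
        "protocol": {"psi0": -1.2, "psi1": 0.5, "tau0": 0.02, "tauK": 0.02,
                     "mechanism": "indirect", "include_K": True, "duration": 30},
    },
    "fig10": {
        "kind": "free",
        "variant": "base",
        "params": {"b": 2, "b1": 1, "cac0": 10, "rho": 10, "s": 0.5, "nu_Ca_st": 0.01, "nu_K_st": 0.01},
        "I0": 0.0,
        "duration": 60,
    },
    "fig11": {
        "kind": "free",
        "variant": "base",
        "params": {"b": 8, "cac0": 20, "rho": 10, "s": 0.5, "nu_Ca_st": 0.01, "nu_K_st": 0.01},
        "I0": 0.25,
        "duration": 200,
    },
    "fig12": {
        "kind": "free",
        "variant": "hyper",
        "params": {"b": 8, "cac0": 20, "rho": 10, "s": 0.5, "nu_Ca_st": 0.01, "nu_K_st": 0.01,
                   "vCah": 0.9, "alpha_h": -4, "d_h": 1, "lam_h": 5},
        "I0": 0.25,
        "duration": 200,
    },
    "fig13": {
        "kind": "free",
        "variant": "hyper",
        "params": {"b": 8, "cac0": 20, "rho": 10, "s": 0.5, "nu_Ca_st": 0.01, "nu_K_st": 0.01,
                   "vCah": 0.9, "alpha_h": -4, "d_h": 1, "lam_h": 5},
        "I0": 0.25,
        "duration": 200,
    },
    "fig14": {
        "kind": "curves",
        "params": {"alpha": 4, "d": 0.4, "lam": 0.5, "alpha_K": 0.5, "lam_K": 0.005, "d_K": 0.5,
                   "vCah": 0.9, "alpha_h": -4, "d_h": 1, "lam_h": 5},
    },
}


def preset_config(name: str) -> RunConfig:
    """Validated RunConfig for a named figure preset."""
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return config_from_dict(PRESETS[name])


# ---------------------------------------------------------------------------
# serialisation

_TRAJ_COLUMNS = ["eta", "u", "gate", "i_ca", "i_k", "i_full", "psi"]


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def write_trajectory(trajectory: Trajectory, path: str | Path, config: dict | None = None) -> Path:
    """Write a trajectory as CSV (fixed column order, 12 significant digits).

    A sidecar ``<path>.meta.json`` records the full configuration, its hash
    and the package version, so a result file can always be traced back to
    the exact run that produced it.
    """
    path = Path(path)
    df = trajectory.to_frame()[_TRAJ_COLUMNS]
    _write_csv(df, path)
    meta = {
        "config": config or {},
        "config_sha256": _config_hash(config or {}),
        "tool": "ciliadyn",
        "version": _VERSION,
        "columns": _TRAJ_COLUMNS,
        "rows": int(len(df)),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def write_table(table: pd.DataFrame, path: str | Path, config: dict | None = None) -> Path:
    """Write an analysis table as CSV with the same sidecar convention."""
    path = Path(path)
    _write_csv(table, path)
    meta = {
        "config": config or {},
        "config_sha256": _config_hash(config or {}),
        "tool": "ciliadyn",
        "version": _VERSION,
        "columns": list(table.columns),
        "rows": int(len(table)),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV written by write_trajectory."""
    df = pd.read_csv(path)
    missing = set(_TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"trajectory file {path} lacks columns {sorted(missing)}")
    return Trajectory(**{c: df[c].to_numpy() for c in _TRAJ_COLUMNS})
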