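"""Run configuration, trace serialization, and structured defaults.

Config files are YAML with sections mirroring the library's dataclasses;
unknown keys are an error (with a did-you-mean suggestion), and every run
can write back its fully-resolved config so results are re-runnable.
Traces round-trip through CSV (per-cycle scalars) + JSON (per-edge arrays
and metadata), or a single HDF5 file.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import ModelParams
from .training import DriveProtocol, LearningConfig, TrainingTrace
from .turnover import TurnoverConfig

__all__ = ["RunConfig", "load_config", "save_config", "save_trace", "load_trace"]

TRACE_VERSION = "cytolearn-trace-v1"


@dataclass
class RunConfig:
    """Fully-resolved description of one run."""

    network: dict = field(default_factory=lambda: {"n_side": 8, "jitter": 0.3})
    task: dict = field(default_factory=dict)
    params: ModelParams = field(default_factory=ModelParams)
    protocol: DriveProtocol = field(default_factory=DriveProtocol)
    learning: LearningConfig = field(default_factory=LearningConfig)
    turnover: TurnoverConfig | None = None
    n_cycles: int = 100
    seed: int = 0
    outdir: str = "runs"

    def to_dict(self) -> dict:
        d = {
            "network": dict(self.network),
            "task": dict(self.task),
            "params": {f.name: getattr(self.params, f.name) for f in dc_fields(self.params)},
            "protocol": {f.name: getattr(self.protocol, f.name) for f in dc_fields(self.protocol)},
            "learning": {f.name: getattr(self.learning, f.name) for f in dc_fields(self.learning)},
            "n_cycles": self.n_cycles,
            "seed": self.seed,
            "outdir": self.outdir,
        }
        if self.turnover is not None:
            d["turnover"] = {f.name: getattr(self.turnover, f.name)
                             for f in dc_fields(self.turnover)}
        return d


_SECTION_TYPES = {
    "params": ModelParams,
    "protocol": DriveProtocol,
    "learning": LearningConfig,
    "turnover": TurnoverConfig,
}
_TOP_KEYS = ("network", "task", "params", "protocol", "learning", "turnover",
             "n_cycles", "seed", "outdir")


def _check_keys(given: dict, allowed, context: str) -> None:
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, list(allowed), n=1)
            suffix = f" — did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown key {key!r} in {context}{suffix}")


def config_from_dict(raw: dict) -> RunConfig:
    _check_keys(raw, _TOP_KEYS, "config")
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        if section in raw and raw[section] is not None:
            sub = dict(raw[section])
            allowed = [f.name for f in dc_fields(cls)]
            _check_keys(sub, allowed, f"config section {section!r}")
            kwargs[section] = cls(**sub)
    for key in ("network", "task", "n_cycles", "seed", "outdir"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    return config_from_dict(raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# ----------------------------------------------------------------------
# traces
# ----------------------------------------------------------------------

def save_trace(trace: TrainingTrace, path) -> None:
    """Write a trace to ``<path>.csv`` + ``<path>.json`` (or one ``.h5``)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _save_trace_h5(trace, path)
        return
    base = path.with_suffix("")
    n_t = trace.errors.shape[1] if trace.errors.size else (
        trace.target_strains.shape[1] if trace.target_strains.ndim == 2 else 0)
    cols = {"cycle": np.arange(trace.n_cycles)}
    for i in range(n_t):
        cols[f"error_{i}"] = trace.errors[:, i] if trace.n_cycles else np.array([])
        cols[f"target_strain_{i}"] = (
            trace.target_strains[:, i] if trace.n_cycles else np.array([]))
    cols["sever_events"] = trace.sever_events
    cols["reconnect_events"] = trace.reconnect_events
    pd.DataFrame(cols).to_csv(base.with_suffix(".csv"), index=False)
    meta = {
        "version": TRACE_VERSION,
        "n_targets": int(n_t),
        "dL0": trace.dL0.tolist(),
        "dk": trace.dk.tolist(),
        "counters": trace.counters,
        "seed": int(trace.seed),
        "aborted": bool(trace.aborted),
        "extras": trace.extras,
    }
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh)


def load_trace(path) -> TrainingTrace:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _load_trace_h5(path)
    base = path.with_suffix("")
    with open(base.with_suffix(".json")) as fh:
        meta = json.load(fh)
    if meta.get("version") != TRACE_VERSION:
        raise ValueError(
            f"trace version mismatch: {meta.get('version')!r} != {TRACE_VERSION!r}")
    df = pd.read_csv(base.with_suffix(".csv"))
    n_t = meta["n_targets"]
    n_c = len(df)
    errors = np.column_stack([df[f"error_{i}"] for i in range(n_t)]) if n_c and n_t \
        else np.zeros((n_c, n_t))
    strains = np.column_stack(
        [df[f"target_strain_{i}"] for i in range(n_t)]) if n_c and n_t \
        else np.zeros((n_c, n_t))
    return TrainingTrace(
        errors=errors,
        target_strains=strains,
        dL0=np.array(meta["dL0"]),
        dk=np.array(meta["dk"]),
        sever_events=df["sever_events"].to_numpy() if n_c else np.zeros(0, dtype=int),
        reconnect_events=df["reconnect_events"].to_numpy() if n_c else np.zeros(0, dtype=int),
        counters=meta["counters"],
        seed=meta["seed"],
        aborted=meta["aborted"],
        extras=meta["extras"],
    )


def _save_trace_h5(trace: TrainingTrace, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["version"] = TRACE_VERSION
        f.attrs["seed"] = int(trace.seed)
        f.attrs["aborted"] = bool(trace.aborted)
        f.attrs["counters"] = json.dumps(trace.counters)
        f.attrs["extras"] = json.dumps(trace.extras)
        for name in ("errors", "target_strains", "dL0", "dk",
                     "sever_events", "reconnect_events"):
            f.create_dataset(name, data=getattr(trace, name))


def _load_trace_h5(path) -> TrainingTrace:
    import h5py

    with h5py.File(path, "r") as f:
        if f.attrs["version"] != TRACE_VERSION:
            raise ValueError(f"trace version mismatch in {path}")
        return TrainingTrace(
            errors=f["errors"][()],
            target_strains=f["target_strains"][()],
            dL0=f["dL0"][()],
            dk=f["dk"][()],
            sever_events=f["sever_events"][()],
            reconnect_events=f["reconnect_events"][()],
            counters=json.loads(f.attrs["counters"]),
            seed=int(f.attrs["seed"]),
            aborted=bool(f.attrs["aborted"]),
            extras=json.loads(f.attrs["extras"]),
        )
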