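"""Configuration files, run manifests, and artifact persistence."""

from __future__ import annotations

import dataclasses
import datetime
import json
import pathlib

import h5py
import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError
from .nif_dynamics import NifParams
from .hvc_chain import HvcParams

_SECTIONS = {"nif": NifParams, "hvc": HvcParams}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML/JSON config into validated parameter objects.

    The file may contain ``nif:`` and ``hvc:`` sections plus a top-level
    ``seed``.  Missing fields take the model defaults; unknown sections or
    fields are rejected with the offending name.  An empty file yields all
    defaults.  Returns ``{"nif": NifParams, "hvc": HvcParams, "seed": int}``.
    """
    raw: dict = {}
    if path is not None:
        text = pathlib.Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config root must be a mapping")
    if overrides:
        for key, val in overrides.items():
            sect, _, field = key.partition(".")
            if field:
                raw.setdefault(sect, {})[field] = val
            else:
                raw[key] = val
    out: dict = {"seed": int(raw.pop("seed", 0))}
    for name, cls in _SECTIONS.items():
        section = raw.pop(name, {}) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section) - known
        if unknown:
            raise ConfigurationError(
                f"unknown field(s) in [{name}]: {sorted(unknown)}")
        out[name] = cls(**section)
    if raw:
        raise ConfigurationError(f"unknown config section(s): {sorted(raw)}")
    return out


def save_config(cfg: dict, path) -> None:
    """Round-trippable dump of an effective configuration."""
    doc = {"seed": cfg.get("seed", 0)}
    for name in _SECTIONS:
        params = cfg.get(name)
        if params is not None:
            doc[name] = params.to_dict()
    pathlib.Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclasses.dataclass
class RunManifest:
    """Everything needed to re-run a CLI invocation."""

    command: str
    seed: int
    config: dict
    outputs: list
    version: str = __version__
    timestamp: str = ""

    def write(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["timestamp"] = (doc["timestamp"]
                            or datetime.datetime.now().isoformat(timespec="seconds"))
        pathlib.Path(path).write_text(json.dumps(doc, indent=2, default=str))


def manifest_for(command: str, cfg: dict, outputs: list) -> RunManifest:
    config = {}
    for name in _SECTIONS:
        if name in cfg:
            config[name] = cfg[name].to_dict()
    return RunManifest(command=command, seed=cfg.get("seed", 0),
                       config=config, outputs=[str(o) for o in outputs])


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

def save_nif_run(path, weights, tutor_log=None, sing_log=None,
                 params: NifParams | None = None) -> None:
    """Persist weights (and optionally activity logs) of one NIf run."""
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=weights.W)
        f.create_dataset("W_B", data=weights.W_B)
        f.create_dataset("Sigma", data=weights.Sigma)
        for name, log in (("tutor", tutor_log), ("sing", sing_log)):
            if log is not None:
                g = f.create_group(name)
                g.create_dataset("A", data=log.A, compression="gzip")
                g.create_dataset("syllable",
                                 data=log.presentations.syllable.values)
                g.attrs["present_steps"] = log.present_steps
                g.attrs["silence_steps"] = log.silence_steps
        if params is not None:
            f.attrs["params"] = json.dumps(params.to_dict())


def load_nif_weights(path):
    from .nif_dynamics import NifWeights
    with h5py.File(path, "r") as f:
        return NifWeights(W=f["W"][...], W_B=f["W_B"][...],
                          Sigma=f["Sigma"][...])


def save_hvc_chain(path, chain) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=chain.W)
        f.attrs["params"] = json.dumps(chain.params.to_dict())
        f.attrs["flagged"] = chain.flagged
        f.attrs["provenance"] = json.dumps(chain.provenance, default=str)


def load_hvc_chain(path):
    from .hvc_chain import ChainGraph
    with h5py.File(path, "r") as f:
        params = HvcParams(**json.loads(f.attrs["params"]))
        return ChainGraph(W=f["W"][...], params=params,
                          flagged=bool(f.attrs["flagged"]),
                          provenance=json.loads(f.attrs["provenance"]))
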