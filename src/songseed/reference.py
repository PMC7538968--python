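"""Reference quantitative outcomes of the modeled study, with the package
computations that reproduce them.

Each entry recomputes one headline number from scratch at the study's own
problem sizes and reports it next to the published reference value.
"""

from __future__ import annotations

import numpy as np


def _success_rate(K: int, n_runs: int, base_seed: int) -> dict:
    from .nif_experiments import success_rate_experiment
    df = success_rate_experiment(K, n_runs=n_runs, base_seed=base_seed)
    return {"value": float((df.label == "success").sum() * 100 / n_runs),
            "n": int(n_runs)}


def imitation_success(K: int, seed: int = 0, n_runs: int = 100) -> dict:
    """Successful imitation runs per 100 random initializations."""
    out = _success_rate(K, n_runs, seed)
    out["value"] = out["value"] * n_runs / 100  # count per 100 when n=100
    return {"value": float(out["value"]), "n": n_runs}


def rhythmic_duration(seed: int = 0, n_probes: int = 10) -> dict:
    """Mean evoked duration (ms) after rhythmic training at a 100-ms period."""
    from .hvc_chain import HvcParams, make_schedule, train_hvc, read_syllable_length
    params = HvcParams()
    chain = train_hvc(params, make_schedule("rhythmic", params, seed), seed)
    d = read_syllable_length(chain, n_probes=n_probes, seed=seed)
    return {"value": float(d.mean()), "n": int(n_probes)}


def nonrhythmic_minimum(seed: int = 0, n_runs: int = 20,
                        n_probes: int = 10) -> dict:
    """Lower end (ms) of the pooled duration distribution after
    non-rhythmic training across independent model runs."""
    from .hvc_chain import HvcParams, make_schedule, train_hvc, read_syllable_length
    params = HvcParams()
    pooled = []
    for i in range(n_runs):
        s = seed + i
        chain = train_hvc(params, make_schedule("non_rhythmic", params, s), s)
        pooled.append(read_syllable_length(chain, n_probes=n_probes, seed=s))
    pooled = np.concatenate(pooled)
    return {"value": float(pooled.min()), "n": int(pooled.size)}


REGISTRY = {
    "success-rate-k4": {
        "fn": lambda seed: imitation_success(4, seed),
        "reference": 98.0,
        "units": "successful runs / 100",
    },
    "success-rate-k3": {
        "fn": lambda seed: imitation_success(3, seed),
        "reference": 81.0,
        "units": "successful runs / 100",
    },
    "success-rate-k5": {
        "fn": lambda seed: imitation_success(5, seed),
        "reference": 79.0,
        "units": "successful runs / 100",
    },
    "rhythmic-duration": {
        "fn": rhythmic_duration,
        "reference": 100.0,
        "units": "ms",
    },
    "nonrhythmic-minimum": {
        "fn": nonrhythmic_minimum,
        "reference": 150.0,
        "units": "ms",
    },
}


def reproduce(name: str, seed: int = 0) -> dict:
    """Recompute one registered quantity; returns observed/reference/units."""
    if name not in REGISTRY:
        raise KeyError(
            f"unknown target {name!r}; known: {sorted(REGISTRY)}")
    entry = REGISTRY[name]
    out = entry["fn"](seed)
    out.update(reference=entry["reference"], units=entry["units"],
               name=name)
    return out
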