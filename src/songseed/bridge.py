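"""Convert NIf singing-phase activity into seed drive for the premotor
network and run the combined two-area model.

The sensorimotor network runs on a 1-ms grid with ~100 neurons; the premotor
network runs on a 10-ms grid with ~10 seed neurons.  The bridge downsamples
NIf output by a factor of 10 in time (block mean) and 10 across neurons
(block mean over contiguous groups), then keeps only activity *onsets*
(cells whose value crosses from <=0 to >0 along time), because the premotor
model is driven by onset bursts rather than sustained activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .nif_dynamics import NifParams
from .nif_experiments import ActivityLog, run_imitation
from .hvc_chain import (HvcParams, ChainGraph, probe_once, _hvc_sim,
                        _seed_kernel_rng, init_hvc_weights)


@dataclass
class SeedDrive:
    """Onset-filtered, downsampled drive onto the premotor seed neurons."""

    drive: np.ndarray              # (timesteps, n_channels), nonnegative
    provenance: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.drive.shape[1]


def nif_to_seed_drive(nif_log, time_factor: int = 10,
                      neuron_factor: int = 10,
                      onset_eps: float = 0.08) -> SeedDrive:
    """Downsample a NIf activity log (or raw (T, n) array) and keep onsets.

    Time axis: block mean over ``time_factor`` samples (trailing remainder
    truncated).  Neuron axis: block mean over contiguous groups of
    ``neuron_factor`` neurons.  A cell is then nonzero only where its value
    crosses from below to above ``onset_eps`` along time (the first row
    counts as an onset when above the floor).  The small floor makes the
    crossing robust to tonic background activity that never fully silences
    a downsampled channel.
    """
    A = nif_log.A if isinstance(nif_log, ActivityLog) else np.asarray(nif_log)
    if A.ndim != 2:
        raise ConfigurationError("activity must be a (time, neurons) array")
    T, n = A.shape
    if T < time_factor or n < neuron_factor:
        raise ConfigurationError("activity shorter than one downsampling block")
    T2, n2 = T // time_factor, n // neuron_factor
    trimmed = A[:T2 * time_factor, :n2 * neuron_factor].astype(float)
    down = trimmed.reshape(T2, time_factor, n2, neuron_factor).mean(axis=(1, 3))
    prev = np.vstack([np.zeros((1, n2)), down[:-1]])
    onsets = np.where((down > onset_eps) & (prev <= onset_eps), down, 0.0)
    return SeedDrive(drive=onsets,
                     provenance={"time_factor": time_factor,
                                 "neuron_factor": neuron_factor,
                                 "input_shape": (T, n),
                                 "truncated": (T - T2 * time_factor,
                                               n - n2 * neuron_factor)})


@dataclass
class CombinedResult:
    """Outcome of a full sensorimotor -> premotor training pipeline."""

    nif_outcome: object
    chain: ChainGraph
    subchains: list                  # list of frozenset of non-seed neurons
    overlap: float                   # pairwise overlap of evoked sets
    n_subchains: int
    upstream_ok: bool
    ensemble_channels: list          # per-ensemble active seed channels


def _evoked_set(chain: ChainGraph, seed_mask: np.ndarray, seed: int,
                n_probes: int = 3) -> frozenset:
    """Non-seed neurons evoked by pulsing a subset of seed channels."""
    params = chain.params
    evoked = set()
    for k in range(n_probes):
        _, rec = probe_once(chain, seed + 31 * k, seed_mask=seed_mask,
                            record=True)
        evoked |= set(np.flatnonzero(rec[:, params.n_seed:].any(axis=0))
                      + params.n_seed)
    return frozenset(evoked)


def run_combined(K: int = 2, nif_params: NifParams | None = None,
                 hvc_params: HvcParams | None = None, seed: int = 0,
                 gain: float = 5.0) -> CombinedResult:
    """Full pipeline: NIf tutoring + singing -> bridge -> premotor training
    -> sub-chain extraction.

    The singing-phase seed drive (one onset event per reactivated ensemble)
    is tiled until the premotor network has seen ``hvc_params.n_trials``
    onset events.  Afterwards each ensemble's seed-channel group is probed
    separately; the run splits when the evoked non-seed populations overlap
    by less than 50%.

    A failed upstream (NIf) run is flagged, not silently scored.
    """
    nif_params = nif_params or NifParams()
    hvc_params = hvc_params or HvcParams()
    outcome, (weights, tlog, slog, tasn, sasn) = run_imitation(
        K, seed, nif_params, return_logs=True)
    upstream_ok = outcome.label == "success"

    sd = nif_to_seed_drive(slog)
    n_seed = hvc_params.n_seed
    if sd.drive.shape[1] != n_seed:
        raise ConfigurationError(
            f"bridge produced {sd.drive.shape[1]} channels for {n_seed} seeds")
    # normalize each onset event so its strongest channel receives the full
    # seed drive; the absolute NIf->HVC gain is unconstrained, so each
    # reactivation recruits its leading channels regardless of ensemble size
    drive = sd.drive.copy()
    for t in np.flatnonzero(drive.any(axis=1)):
        peak = drive[t].max()
        drive[t] = np.where(drive[t] >= 0.5 * peak, drive[t], 0.0)
        drive[t] *= hvc_params.seed_drive / peak

    # channels whose onset events are strong enough to fire a seed neuron,
    # per ensemble-scale singing cluster
    steps_per = (nif_params.present_steps + nif_params.silence_steps) // 10
    ens_channels = []
    for cluster in sasn.clusters:
        if len(cluster.founder) < 7:      # flicker, not a syllable ensemble
            continue
        counts = np.zeros(n_seed)
        for pres in cluster.members:
            seg = drive[pres * steps_per:(pres + 1) * steps_per]
            counts += seg.max(axis=0) > hvc_params.threshold
        # a channel belongs to the ensemble when it is recruited on at
        # least half of the ensemble's reactivations
        chan = np.flatnonzero(counts >= 0.5 * len(cluster.members))
        if chan.size == 0 and counts.max() > 0:
            # inconsistent onsets: fall back to the two most recruited
            chan = np.argsort(counts)[-2:]
        ens_channels.append(sorted(int(c) for c in chan))

    # tile the singing drive to the full training length
    ev_t, ev_c = np.nonzero(drive)
    if ev_t.size == 0:
        chain = ChainGraph(W=init_hvc_weights(hvc_params, seed),
                           params=hvc_params, flagged=True,
                           provenance={"note": "no NIf onset events"})
        return CombinedResult(outcome, chain, [], 1.0, 0, upstream_ok,
                              ens_channels)
    period = drive.shape[0]
    events_per_tile = len(np.unique(ev_t))
    n_tiles = int(np.ceil(hvc_params.n_trials / events_per_tile))
    times, drives = [], []
    uniq_t = np.unique(ev_t)
    for tile in range(n_tiles):
        for t in uniq_t:
            row = drive[t]
            times.append(tile * period + int(t))
            drives.append(row)
    ext_steps = np.asarray(times, dtype=np.int64)
    ext_drive = np.asarray(drives)

    W = init_hvc_weights(hvc_params, seed)
    _seed_kernel_rng((seed + 777) % (2**31 - 1))
    total = int(ext_steps[-1]) + hvc_params.iti_min + 1
    dummy = np.empty((0, hvc_params.n_neurons))
    _, runaway = _hvc_sim(
        W, ext_steps, ext_drive, total, n_seed,
        hvc_params.threshold, hvc_params.temperature, hvc_params.inh_gain,
        hvc_params.adapt_gain, hvc_params.adapt_tau_steps,
        hvc_params.noise_sd, hvc_params.p_spont, hvc_params.spont_amp,
        hvc_params.k_wta, hvc_params.eta_ltp, hvc_params.eta_ltd,
        hvc_params.eta_prune, hvc_params.w_max, hvc_params.w_in_budget,
        hvc_params.w_out_budget, hvc_params.w_out_budget_seed,
        1, -1, dummy, 50)
    chain = ChainGraph(W=W, params=hvc_params, flagged=bool(runaway),
                       provenance={"combined": True, "seed": seed, "K": K})

    subchains = []
    for idx, chan in enumerate(ens_channels):
        if not chan:
            continue
        mask = np.zeros(n_seed, dtype=bool)
        mask[list(chan)] = True
        ev = _evoked_set(chain, mask, seed + 13 * (idx + 1))
        subchains.append(ev)

    overlap = 0.0
    if len(subchains) >= 2:
        pair_ov = []
        for a in range(len(subchains)):
            for b in range(a + 1, len(subchains)):
                sa, sb = subchains[a], subchains[b]
                denom = min(len(sa), len(sb))
                pair_ov.append(len(sa & sb) / denom if denom else 1.0)
        overlap = max(pair_ov)
    n_distinct = sum(1 for s in subchains if len(s) > 0)
    if len(subchains) >= 2 and overlap >= 0.5:
        n_distinct = 1
    return CombinedResult(outcome, chain, subchains, overlap, n_distinct,
                          upstream_ok, ens_channels)
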