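"""Chain-growth premotor (HVC) network with stimulation protocols and the
syllable-length readout.

The premotor network is a reconstruction of the classic seed-neuron
chain-growth models of HVC sequence development: binary probabilistic
neurons on a 10-ms grid, with

* recurrent drive through a plastic, nonnegative weight matrix ``W``;
* global inhibition proportional to the previous step's population activity;
* per-neuron spike-frequency adaptation with slow recovery;
* small Gaussian input noise plus a low spontaneous firing probability;
* external pulses that force a group of *seed* neurons to fire.

Plasticity is Hebbian potentiation of pre(t-1) -> post(t) pairs with a
per-synapse cap, a weaker depression of the reverse synapse (temporal
asymmetry), and heterosynaptic competition that rescales each neuron's total
incoming and outgoing weight toward fixed budgets.  Under repeated seed
stimulation the network grows a synaptic chain away from the seeds; the
inter-pulse statistics of the training protocol determine how long the chain
can grow before a new pulse captures the activity front, which is how
stimulus rhythm sets syllable duration.

One timestep equals 10 ms of real time throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import networkx as nx
from numba import njit

from .errors import ConfigurationError

STEP_MS = 10.0


@dataclass
class HvcParams:
    """Parameters of the premotor chain-growth network.

    The published description fixes only the protocol (trial counts,
    inter-trial intervals, pulse structure) and the 10-ms timestep; the
    internal constants below are reconstruction choices, tuned once so that
    a planted feed-forward chain propagates reliably, rhythmic training
    locks the evoked duration to the training period, and non-rhythmic
    training produces long, variable durations.
    """

    n_neurons: int = 100
    n_seed: int = 10
    # protocol
    n_trials: int = 7200
    iti_lambda: float = 50.0       # Poisson mean of inter-trial interval, steps
    iti_min: int = 27              # left truncation of the ITI, steps
    pulses_rhythmic: int = 4
    pulse_period: int = 10         # steps between pulses in a rhythmic trial
    # dynamics
    threshold: float = 0.4
    temperature: float = 0.05      # softness of the spike probability
    p_spont: float = 0.0005       # spontaneous-burst probability (training)
    spont_amp: float = 1.2         # drive bump of a spontaneous burst
    k_wta: int = 3                 # max concurrently bursting non-seed neurons
    inh_gain: float = 0.0          # residual global inhibition per active neuron
    adapt_gain: float = 0.1
    adapt_tau_steps: float = 40.0  # adaptation recovery, steps (400 ms)
    noise_sd: float = 0.05
    seed_drive: float = 2.0        # external drive to seeds on a pulse
    # plasticity
    eta_ltp: float = 0.8
    eta_ltd: float = 0.05          # reverse-pair depression
    eta_prune: float = 0.25        # pre-fires-without-post depression
    w_max: float = 0.8             # per-synapse cap
    w_in_budget: float = 1.6       # max summed incoming weight per neuron
    w_out_budget: float = 1.6      # max summed outgoing weight per neuron
    w_out_budget_seed: float = 1.0  # outgoing budget of seed neurons
    w_init_scale: float = 0.002    # initial weights ~ U(0, scale)
    # readout
    probe_horizon_steps: int = 1000   # 10 s runaway guard
    count_seed_activity: bool = False

    def __post_init__(self):
        if self.n_seed > self.n_neurons:
            raise ConfigurationError("n_seed must be <= n_neurons")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.iti_min < 0 or self.iti_lambda <= 0:
            raise ConfigurationError("invalid inter-trial interval parameters")

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "HvcParams":
        return replace(self, **kw)


@dataclass
class StimulusSchedule:
    """Trial start times plus per-trial pulse offsets, in 10-ms steps."""

    trial_starts: np.ndarray       # (n_trials,) int64
    pulse_offsets: np.ndarray      # (n_pulses_per_trial,) int64
    mode: str = "custom"

    @property
    def n_trials(self) -> int:
        return self.trial_starts.shape[0]

    @property
    def pulse_times(self) -> np.ndarray:
        """All pulse times, sorted, deduplicated."""
        times = (self.trial_starts[:, None] + self.pulse_offsets[None, :]).ravel()
        return np.unique(times)

    @property
    def total_steps(self) -> int:
        return int(self.pulse_times[-1]) + 1


def make_schedule(mode: str, params: HvcParams, seed: int) -> StimulusSchedule:
    """Build the stimulation schedule.

    ``rhythmic``: each trial is ``pulses_rhythmic`` pulses spaced
    ``pulse_period`` steps apart (4 pulses / 10 steps = 100 ms by default).
    ``non_rhythmic``: a single pulse per trial.  Inter-trial intervals are
    Poisson(``iti_lambda``) left-truncated at ``iti_min`` (sampled by
    rejection), measured from the last pulse of one trial to the first pulse
    of the next.
    """
    if mode == "rhythmic":
        offsets = np.arange(params.pulses_rhythmic, dtype=np.int64) * params.pulse_period
    elif mode == "non_rhythmic":
        offsets = np.zeros(1, dtype=np.int64)
    else:
        raise ConfigurationError(f"unknown schedule mode {mode!r}")
    rng = np.random.default_rng(seed)
    itis = np.empty(params.n_trials - 1, dtype=np.int64)
    filled = 0
    while filled < itis.size:
        draw = rng.poisson(params.iti_lambda, size=itis.size - filled)
        keep = draw[draw >= params.iti_min]
        itis[filled:filled + keep.size] = keep
        filled += keep.size
    span = int(offsets[-1])
    starts = np.empty(params.n_trials, dtype=np.int64)
    starts[0] = 1
    for i in range(1, params.n_trials):
        starts[i] = starts[i - 1] + span + itis[i - 1]
    return StimulusSchedule(trial_starts=starts, pulse_offsets=offsets, mode=mode)


def truncated_poisson_mean(lam: float, minimum: int) -> float:
    """Mean of a Poisson(lam) left-truncated (by rejection) at ``minimum``."""
    from scipy import stats
    k = np.arange(minimum, int(lam + 12 * np.sqrt(lam)) + 1)
    p = stats.poisson.pmf(k, lam)
    return float((k * p).sum() / p.sum())


@dataclass
class ChainGraph:
    """A trained premotor network: weights plus derived graph structure."""

    W: np.ndarray
    params: HvcParams
    flagged: bool = False          # runaway activity seen during training
    provenance: dict = field(default_factory=dict)

    def graph(self, edge_threshold: float = 0.2) -> nx.DiGraph:
        """Directed graph of supra-threshold learned connections."""
        g = nx.DiGraph()
        g.add_nodes_from(range(self.params.n_neurons))
        pre, post = np.nonzero(self.W.T > edge_threshold)
        for j, i in zip(pre, post):
            g.add_edge(int(j), int(i), weight=float(self.W[i, j]))
        return g

    def latencies(self, edge_threshold: float = 0.2) -> dict:
        """Per-neuron step latency from the seed population (BFS depth);
        only neurons reachable from seeds appear."""
        g = self.graph(edge_threshold)
        seeds = list(range(self.params.n_seed))
        lat: dict[int, int] = {s: 0 for s in seeds}
        frontier = seeds
        depth = 0
        while frontier:
            depth += 1
            nxt = []
            for u in frontier:
                for v in g.successors(u):
                    if v not in lat:
                        lat[v] = depth
                        nxt.append(v)
            frontier = nxt
        return lat


@njit(cache=False)
def _seed_kernel_rng(seed):
    # numba maintains its own random state, distinct from numpy's
    np.random.seed(seed)


@njit(cache=False)
def _hvc_sim(W, ext_steps, ext_drive, total_steps, n_seed,
             threshold, temperature, inh_gain, adapt_gain, adapt_tau,
             noise_sd, p_spont, spont_amp, k_wta,
             eta_ltp, eta_ltd, eta_prune, w_max, w_in_budget, w_out_budget,
             w_out_budget_seed,
             plastic, record_from, x_record, runaway_limit):
    """Simulate the binary network over ``total_steps``.

    ``ext_steps``/``ext_drive``: sorted event times and per-event drive onto
    each seed neuron (``ext_drive`` has shape (n_events, n_seed)).  When ``plastic`` the Hebbian/competition updates run
    each step.  Activity from step ``record_from`` on is written to
    ``x_record``.  Returns (last step with non-seed activity, runaway flag).
    """
    n = W.shape[0]
    x_prev = np.zeros(n)
    adapt = np.zeros(n)
    last_active = -1
    ev = 0
    n_ev = ext_steps.shape[0]
    runaway = 0
    sat_run = 0
    decay = 1.0 - 1.0 / adapt_tau
    for t in range(total_steps):
        S = x_prev.sum()
        if S > 0.0:
            u = W @ x_prev
        else:
            u = np.zeros(n)
        for i in range(n):
            u[i] += noise_sd * np.random.randn() - inh_gain * S - adapt_gain * adapt[i]
        if ev < n_ev and ext_steps[ev] == t:
            for i in range(n_seed):
                u[i] += ext_drive[ev, i]
            ev += 1
        # spontaneous bursts appear as transient excitatory drive and
        # compete inside the same winner-take-all as synaptic drive
        if p_spont > 0.0:
            for i in range(n_seed, n):
                if np.random.rand() < p_spont:
                    u[i] += spont_amp
        x = np.zeros(n)
        n_act = 0
        for i in range(n):
            z = (u[i] - threshold) / temperature
            if z > 30.0:
                prob = 1.0
            elif z < -30.0:
                prob = 0.0
            else:
                prob = 1.0 / (1.0 + np.exp(-z))
            if np.random.rand() < prob:
                x[i] = 1.0
                n_act += 1
        # fast recurrent inhibition caps concurrent bursting at k_wta:
        # forced seed bursts consume capacity first (a pulse therefore
        # captures the network and silences a running chain), then the most
        # strongly driven non-seed neurons keep the remaining slots
        n_sd = 0
        for i in range(n_seed):
            if x[i] == 1.0:
                n_sd += 1
        slots = k_wta - n_sd
        if slots < 0:
            slots = 0
        n_ns = 0
        for i in range(n_seed, n):
            if x[i] == 1.0:
                n_ns += 1
        if n_ns > slots:
            for _ in range(n_ns - slots):
                worst = -1
                worst_u = 1e18
                for i in range(n_seed, n):
                    if x[i] == 1.0 and u[i] < worst_u:
                        worst_u = u[i]
                        worst = i
                if worst >= 0:
                    x[worst] = 0.0
                    n_act -= 1
        for i in range(n_seed, n):
            if x[i] == 1.0:
                last_active = t
                break
        if n_act >= n - 1:
            sat_run += 1
            if sat_run > runaway_limit:
                runaway = 1
        else:
            sat_run = 0
        # plasticity: potentiate pre(t-1)->post(t), depress the reverse
        # pair, and depress pre->target synapses whose target stayed silent
        # (so a pulse that captures the network prunes the chain at the
        # rhythm boundary)
        if plastic == 1 and S > 0.0:
            for j in range(n):
                if x_prev[j] == 0.0:
                    continue
                for i in range(n):
                    if i == j:
                        continue
                    if x[i] == 1.0:
                        w = W[i, j] + eta_ltp
                        if w > w_max:
                            w = w_max
                        W[i, j] = w
                        w2 = W[j, i] - eta_ltd
                        if w2 < 0.0:
                            w2 = 0.0
                        W[j, i] = w2
                    elif W[i, j] > 0.0 and j >= n_seed:
                        # seed outputs (the afferent training pathway) are
                        # exempt from failure-driven pruning
                        w = W[i, j] - eta_prune
                        if w < 0.0:
                            w = 0.0
                        W[i, j] = w
            # heterosynaptic competition on touched rows/columns:
            # subtractive redistribution of the excess prunes weak synapses
            # while leaving consolidated ones nearly untouched
            for i in range(n):
                if x[i] == 1.0:
                    for _ in range(6):
                        rs = 0.0
                        nz = 0
                        for j in range(n):
                            if W[i, j] > 0.0:
                                rs += W[i, j]
                                nz += 1
                        if rs <= w_in_budget * 1.001 or nz == 0:
                            break
                        sub = (rs - w_in_budget) / nz
                        for j in range(n):
                            if W[i, j] > 0.0:
                                w = W[i, j] - sub
                                W[i, j] = w if w > 0.0 else 0.0
            for j in range(n):
                if x_prev[j] == 1.0:
                    budget = w_out_budget_seed if j < n_seed else w_out_budget
                    for _ in range(6):
                        cs = 0.0
                        nz = 0
                        for i in range(n):
                            if W[i, j] > 0.0:
                                cs += W[i, j]
                                nz += 1
                        if cs <= budget * 1.001 or nz == 0:
                            break
                        sub = (cs - budget) / nz
                        for i in range(n):
                            if W[i, j] > 0.0:
                                w = W[i, j] - sub
                                W[i, j] = w if w > 0.0 else 0.0
        for i in range(n):
            adapt[i] = adapt[i] * decay + x[i]
            x_prev[i] = x[i]
        if record_from >= 0 and t >= record_from:
            for i in range(n):
                x_record[t - record_from, i] = x[i]
        if S == 0.0 and x.sum() == 0.0 and ev >= n_ev and t > 0 and plastic == 0:
            # probe mode: network silent and no more input -> done
            break
    return last_active, runaway


def init_hvc_weights(params: HvcParams, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.0, params.w_init_scale,
                    size=(params.n_neurons, params.n_neurons))
    np.fill_diagonal(W, 0.0)
    return W


def train_hvc(params: HvcParams, schedule: StimulusSchedule, seed: int,
              W0: np.ndarray | None = None) -> ChainGraph:
    """Run the chain-growth network over the full schedule with plasticity on.

    Deterministic given ``seed``.  Runaway activity (near-saturation for an
    extended stretch) flags the returned graph rather than raising.
    """
    W = init_hvc_weights(params, seed) if W0 is None else W0.copy()
    pulse_times = schedule.pulse_times.astype(np.int64)
    drive = np.full((pulse_times.shape[0], params.n_seed), params.seed_drive)
    total = int(pulse_times[-1]) + params.iti_min + 1
    _seed_kernel_rng(seed % (2**31 - 1))
    dummy = np.empty((0, params.n_neurons))
    _, runaway = _hvc_sim(
        W, pulse_times, drive, total, params.n_seed,
        params.threshold, params.temperature, params.inh_gain,
        params.adapt_gain, params.adapt_tau_steps, params.noise_sd,
        params.p_spont, params.spont_amp, params.k_wta,
        params.eta_ltp, params.eta_ltd, params.eta_prune, params.w_max,
        params.w_in_budget, params.w_out_budget,
        params.w_out_budget_seed,
        1, -1, dummy, 50)
    return ChainGraph(W=W, params=params, flagged=bool(runaway),
                      provenance={"mode": schedule.mode, "seed": seed,
                                  "n_trials": schedule.n_trials})


def probe_once(chain: ChainGraph, seed: int,
               seed_mask: np.ndarray | None = None,
               record: bool = False):
    """Stimulate with a single pulse (plasticity off) and measure how long
    non-seed activity persists.

    ``seed_mask`` optionally restricts the pulse to a subset of seed
    neurons (boolean vector of length n_seed).  Returns the duration in ms
    (and the activity raster when ``record``).
    """
    params = chain.params
    W = chain.W.copy()
    pulse = np.zeros(1, dtype=np.int64)
    drive = np.full((1, params.n_seed), params.seed_drive)
    if seed_mask is not None:
        drive[0, ~np.asarray(seed_mask, dtype=bool)] = 0.0
    _seed_kernel_rng(seed % (2**31 - 1))
    horizon = params.probe_horizon_steps
    rec = np.zeros((horizon, params.n_neurons)) if record else np.empty((0, params.n_neurons))
    last, _ = _hvc_sim(
        W, pulse, drive, horizon, params.n_seed,
        params.threshold, params.temperature, params.inh_gain,
        params.adapt_gain, params.adapt_tau_steps, params.noise_sd,
        0.0, params.spont_amp, params.k_wta,
        params.eta_ltp, params.eta_ltd, params.eta_prune, params.w_max,
        params.w_in_budget, params.w_out_budget,
        params.w_out_budget_seed,
        0, 0 if record else -1, rec, 50)
    duration_ms = max(last, 0) * STEP_MS if last >= 0 else 0.0
    if record:
        return duration_ms, rec
    return duration_ms


def read_syllable_length(chain: ChainGraph, n_probes: int = 10,
                         seed: int = 0) -> np.ndarray:
    """The paper-style duration readout: ``n_probes`` single-pulse probes
    with plasticity off; each duration is the last timestep with non-seed
    activity, times 10 ms.  Durations at the probe horizon are reported at
    the horizon (runaway-flagged in the provenance)."""
    out = np.empty(n_probes)
    for p in range(n_probes):
        out[p] = probe_once(chain, seed + 1000 * p + 17)
    return out
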