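"""Core NIf rate network: state, dynamics, input construction, and plasticity.

The model is a recurrent threshold-linear rate network of NIf neurons.  Each
neuron carries a membrane potential ``Y`` and a slow intracellular adaptation
variable ``alpha``.  The dynamics are

    tau_m * dY/dt     = -Y + W_plus @ A + W_minus @ Y_plus + W_B @ B - alpha - Sigma
    tau_adapt * da/dt = eps_adapt * A - alpha

where ``A = min(max(Y, 0), y_cap)`` is the capped threshold-linear activity,
``Y_plus = max(Y, 0)`` the (uncapped) positive part of the potential, ``W``
the plastic recurrent matrix split into its positive and negative parts,
``W_B`` the fixed feed-forward input matrix, ``B`` the current input pattern,
and ``Sigma`` a per-neuron normalization equal to a fixed fraction of the
neuron's mean feed-forward drive across the tutor patterns.  Excitation
saturates with the activity cap while inhibition grows with the raw
potential; this asymmetry lets coherent, strongly driven ensembles suppress
loose coalitions, and is what makes singing-phase reactivation selective.

Two plasticity rules act on ``W`` (diagonal pinned at zero, entries clipped
to ``[-w_cap, +w_cap]``), and only while a pattern is on:

* anti-Hebbian decorrelation, ``dW = -delta_ah * outer(A, A)``, active
  during the first presentation of each tutor syllable;
* a Hopfield-like consolidation rule: ``W_ij`` gains when neurons i and j
  are both active, loses when exactly one is active, and is untouched when
  neither is.  The per-millisecond increment is ``delta_hop * hop_rate``,
  chosen so consolidation saturates near the end of the 20-cycle tutoring
  phase rather than within the first cycle (see docs/methods.md).

Integration is classical fixed-step RK4 on a 1-ms grid with one plasticity
application per step.  After each presentation the network is allowed to
reverberate ``persist_ms`` into the silent gap and is then quenched
(membrane reset, adaptation decaying passively) until the next presentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from numba import njit

from .errors import ConfigurationError, IntegrationError

LEARNING_MODES = {"off": 0, "anti_hebbian": 1, "hopfield": 2}


# ---------------------------------------------------------------------------
# Parameters and containers
# ---------------------------------------------------------------------------

@dataclass
class NifParams:
    """Parameters of the NIf network and tutoring/singing protocol.

    Defaults are the published model values; ``w_init_scale`` (initial
    recurrent weight spread) and ``active_threshold`` (activity level defining
    "active" for the Hopfield rule) are reconstruction choices exposed here.
    """

    n_neurons: int = 100
    n_inputs: int = 100
    tau_m: float = 10.0          # membrane time constant, ms
    tau_adapt: float = 125.0     # adaptation time constant, ms
    eps_adapt: float = 10.0      # adaptation steady-state coefficient
    y_cap: float = 0.5           # membrane-potential ceiling
    delta_ah: float = 0.05       # anti-Hebbian learning rate
    delta_hop: float = 0.01      # Hopfield-like increment
    w_cap: float = 1.0           # recurrent synapse bound
    sparsity: float = 0.8        # fraction of zeroed input elements
    present_ms: int = 30         # pattern-on duration
    silence_ms: int = 70         # gap duration
    cycles_tutor: int = 20
    cycles_sing: int = 20
    sigma_coeff: float = 0.75    # scale of the Sigma normalization
    input_lognorm_sd: float = 0.25  # SD of the underlying normal of W_B
    dt_ms: float = 1.0
    w_init_scale: float = 0.1    # initial recurrent weights ~ U(-scale, +scale)
    active_threshold: float = 0.0  # neuron "active" iff A > this (Hopfield rule)
    uncapped_inhibition: bool = True  # inhibition driven by uncapped Y_plus
    hop_rate: float = 0.25       # fraction of delta_hop applied per 1-ms step
    persist_ms: float = 23.0     # post-presentation reverberation before quench
    sing_jitter: float = 0.15    # SD of the random initial potential per
                                 # singing presentation (noise/initial-condition
                                 # dependence of ensemble reactivation)

    def __post_init__(self):
        if self.n_neurons <= 0 or self.n_inputs <= 0:
            raise ConfigurationError("n_neurons and n_inputs must be positive")
        for name in ("tau_m", "tau_adapt", "dt_ms"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not (0.0 <= self.sparsity < 1.0):
            raise ConfigurationError("sparsity must lie in [0, 1)")
        if self.y_cap <= 0 or self.w_cap <= 0:
            raise ConfigurationError("y_cap and w_cap must be > 0")
        for name in ("present_ms", "silence_ms"):
            if (getattr(self, name) / self.dt_ms) % 1 != 0:
                raise ConfigurationError(f"dt_ms must divide {name}")
        if self.persist_ms < 0 or self.sing_jitter < 0 or self.hop_rate <= 0:
            raise ConfigurationError(
                "persist_ms and sing_jitter must be >= 0, hop_rate > 0")

    @property
    def present_steps(self) -> int:
        return int(round(self.present_ms / self.dt_ms))

    @property
    def silence_steps(self) -> int:
        return int(round(self.silence_ms / self.dt_ms))

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "NifParams":
        return replace(self, **kw)


@dataclass
class NifState:
    """Membrane potentials and adaptation of the network at one time point."""

    Y: np.ndarray
    alpha: np.ndarray
    t_ms: float = 0.0

    def copy(self) -> "NifState":
        return NifState(self.Y.copy(), self.alpha.copy(), self.t_ms)


@dataclass
class NifWeights:
    """Plastic recurrent matrix W plus the fixed input pathway.

    ``W_B`` and ``Sigma`` are fixed for the lifetime of a run; only ``W``
    changes under the learning rules.
    """

    W: np.ndarray
    W_B: np.ndarray
    Sigma: np.ndarray

    def copy(self) -> "NifWeights":
        return NifWeights(self.W.copy(), self.W_B.copy(), self.Sigma.copy())


@dataclass
class InputProgram:
    """Per-syllable input patterns, the shared onset signal, and the schedule.

    ``schedule`` is an ordered list of ``(syllable_index, phase)`` with
    ``syllable_index == -1`` for onset-only (singing) presentations.
    """

    patterns: np.ndarray          # (K, n_inputs)
    onset_signal: np.ndarray      # (n_inputs,)
    schedule: list = field(default_factory=list)

    @property
    def n_syllables(self) -> int:
        return self.patterns.shape[0]


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def init_network(params: NifParams, seed: int) -> tuple[NifWeights, NifState]:
    """Initialize recurrent and input weights plus a zeroed state.

    The recurrent matrix starts as small uniform random values (zero
    diagonal).  Input weights are drawn from a de-meaned log-normal
    distribution: ``exp(N(0, s^2)) - exp(s^2 / 2)`` with
    ``s = input_lognorm_sd``, giving many weak inhibitory entries and a few
    strong excitatory ones (sample mean ~ 0, positive skew).

    ``Sigma`` is zero until attached by :func:`compute_sigma` once the tutor
    patterns exist.
    """
    rng = np.random.default_rng(seed)
    n = params.n_neurons
    W = rng.uniform(-params.w_init_scale, params.w_init_scale, size=(n, n))
    np.fill_diagonal(W, 0.0)
    s = params.input_lognorm_sd
    W_B = np.exp(rng.normal(0.0, s, size=(n, params.n_inputs))) - np.exp(s * s / 2.0)
    state = NifState(Y=np.zeros(n), alpha=np.zeros(n), t_ms=0.0)
    return NifWeights(W=W, W_B=W_B, Sigma=np.zeros(n)), state


def make_sparse_pattern(rng: np.random.Generator, n_inputs: int, sparsity: float) -> np.ndarray:
    """One nonnegative sparse input vector: U(0,1) values with an exact
    fraction of entries forced to zero."""
    vals = rng.uniform(0.0, 1.0, size=n_inputs)
    n_zero = int(round(sparsity * n_inputs))
    zero_idx = rng.choice(n_inputs, size=n_zero, replace=False)
    vals[zero_idx] = 0.0
    return vals


def make_input_program(K: int, params: NifParams, seed: int) -> InputProgram:
    """Draw K syllable patterns plus the shared onset signal and build the
    tutoring + singing presentation schedule.

    Tutoring: ``cycles_tutor`` sequential sweeps over syllables ``0..K-1``.
    Singing: ``cycles_sing`` presentations of the onset signal alone.
    """
    if K < 1:
        raise ConfigurationError("K must be >= 1")
    rng = np.random.default_rng(seed)
    patterns = np.stack([
        make_sparse_pattern(rng, params.n_inputs, params.sparsity) for _ in range(K)
    ])
    # exact collisions are measure-zero; regenerate defensively anyway
    for _ in range(10):
        dup = False
        for i in range(K):
            for j in range(i + 1, K):
                if np.array_equal(patterns[i], patterns[j]):
                    dup = True
                    warnings.warn("duplicate input pattern regenerated")
                    patterns[j] = make_sparse_pattern(rng, params.n_inputs, params.sparsity)
        if not dup:
            break
    onset = make_sparse_pattern(rng, params.n_inputs, params.sparsity)
    schedule = []
    for _ in range(params.cycles_tutor):
        for k in range(K):
            schedule.append((k, "tutor"))
    for _ in range(params.cycles_sing):
        schedule.append((-1, "sing"))
    return InputProgram(patterns=patterns, onset_signal=onset, schedule=schedule)


def compute_sigma(W_B: np.ndarray, patterns: np.ndarray, sigma_coeff: float) -> np.ndarray:
    """Per-neuron normalization: ``sigma_coeff`` times the mean feed-forward
    drive over the tutor patterns, ``Sigma = c * mean_i(W_B @ B_i)``."""
    patterns = np.atleast_2d(patterns)
    if patterns.size == 0:
        raise ConfigurationError("patterns must be nonempty")
    if W_B.shape[1] != patterns.shape[1]:
        raise ConfigurationError(
            f"shape mismatch: W_B has {W_B.shape[1]} inputs, patterns {patterns.shape[1]}")
    return sigma_coeff * (W_B @ patterns.mean(axis=0))


# ---------------------------------------------------------------------------
# Plasticity rules (reference numpy implementations)
# ---------------------------------------------------------------------------

def anti_hebbian_update(W: np.ndarray, Y: np.ndarray, delta_ah: float,
                        w_cap: float = 1.0) -> np.ndarray:
    """In-place anti-Hebbian decorrelation: co-active pairs become mutually
    inhibitory.  Every applied increment is <= 0."""
    Yp = np.maximum(Y, 0.0)
    W -= delta_ah * np.outer(Yp, Yp)
    np.clip(W, -w_cap, w_cap, out=W)
    np.fill_diagonal(W, 0.0)
    return W


def hopfield_update(W: np.ndarray, active_mask: np.ndarray, delta_hop: float,
                    w_cap: float = 1.0) -> np.ndarray:
    """In-place Hopfield-like consolidation.

    For each ordered pair i != j: both active -> +delta_hop; exactly one
    active -> -delta_hop; neither -> unchanged.  The increment matrix is
    symmetric.
    """
    m = active_mask.astype(float)
    # 3*m_i*m_j - m_i - m_j evaluates to +1 / -1 / 0 for both / one / neither
    dW = delta_hop * (3.0 * np.outer(m, m) - m[:, None] - m[None, :])
    W += dW
    np.clip(W, -w_cap, w_cap, out=W)
    np.fill_diagonal(W, 0.0)
    return W


# ---------------------------------------------------------------------------
# Numba kernels (single source of truth for the per-step math)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _deriv(Y, alpha, W, drive, tau_m, tau_a, eps, y_cap, uncapped_inh, dY, dA):
    # A is the capped threshold-linear activity; with uncapped_inh the
    # inhibitory term acts on the *uncapped* positive part of Y, so coherent
    # strongly driven groups inhibit competitors beyond the activity ceiling.
    n = Y.shape[0]
    Yp = np.maximum(Y, 0.0)
    A = np.minimum(Yp, y_cap)
    rec = W @ A
    if uncapped_inh:
        excess = Yp - A
        if excess.max() > 0.0:
            Wm = np.minimum(W, 0.0)
            rec = rec + Wm @ excess
    for i in range(n):
        dY[i] = (-Y[i] + rec[i] + drive[i] - alpha[i]) / tau_m
        dA[i] = (eps * A[i] - alpha[i]) / tau_a


@njit(cache=True)
def _step_kernel(Y, alpha, W, drive, tau_m, tau_a, eps, y_cap, uncapped_inh, dt,
                 mode, delta_ah, delta_hop, w_cap, active_thr):
    """Advance (Y, alpha) by one RK4 step in place; apply plasticity once.

    ``drive`` is the constant external term W_B @ B - Sigma for this step.
    ``mode``: 0 = off, 1 = anti-Hebbian, 2 = Hopfield.
    """
    n = Y.shape[0]
    k1Y = np.empty(n); k1A = np.empty(n)
    k2Y = np.empty(n); k2A = np.empty(n)
    k3Y = np.empty(n); k3A = np.empty(n)
    k4Y = np.empty(n); k4A = np.empty(n)

    _deriv(Y, alpha, W, drive, tau_m, tau_a, eps, y_cap, uncapped_inh, k1Y, k1A)
    Y2 = Y + 0.5 * dt * k1Y
    a2 = alpha + 0.5 * dt * k1A
    _deriv(Y2, a2, W, drive, tau_m, tau_a, eps, y_cap, uncapped_inh, k2Y, k2A)
    Y3 = Y + 0.5 * dt * k2Y
    a3 = alpha + 0.5 * dt * k2A
    _deriv(Y3, a3, W, drive, tau_m, tau_a, eps, y_cap, uncapped_inh, k3Y, k3A)
    Y4 = Y + dt * k3Y
    a4 = alpha + dt * k3A
    _deriv(Y4, a4, W, drive, tau_m, tau_a, eps, y_cap, uncapped_inh, k4Y, k4A)

    ok = True
    for i in range(n):
        yi = Y[i] + dt / 6.0 * (k1Y[i] + 2.0 * k2Y[i] + 2.0 * k3Y[i] + k4Y[i])
        ai = alpha[i] + dt / 6.0 * (k1A[i] + 2.0 * k2A[i] + 2.0 * k3A[i] + k4A[i])
        Y[i] = yi
        alpha[i] = ai
        if not (np.isfinite(yi) and np.isfinite(ai)):
            ok = False

    if mode == 1:
        # decorrelation scales with the capped activity, not the raw potential
        for i in range(n):
            ypi = Y[i] if Y[i] > 0.0 else 0.0
            if ypi > y_cap:
                ypi = y_cap
            if ypi == 0.0:
                continue
            for j in range(n):
                if i == j:
                    continue
                ypj = Y[j] if Y[j] > 0.0 else 0.0
                if ypj > y_cap:
                    ypj = y_cap
                if ypj == 0.0:
                    continue
                w = W[i, j] - delta_ah * ypi * ypj
                if w < -w_cap:
                    w = -w_cap
                W[i, j] = w
    elif mode == 2:
        for i in range(n):
            ai_on = Y[i] > active_thr
            for j in range(n):
                if i == j:
                    continue
                aj_on = Y[j] > active_thr
                if ai_on and aj_on:
                    w = W[i, j] + delta_hop
                    if w > w_cap:
                        w = w_cap
                    W[i, j] = w
                elif ai_on or aj_on:
                    w = W[i, j] - delta_hop
                    if w < -w_cap:
                        w = -w_cap
                    W[i, j] = w
    return ok


@njit(cache=True)
def _run_schedule_kernel(Y, alpha, W, W_B, Sigma, patterns, onset,
                         sched_syll, mode_on, Y0,
                         present_steps, silence_steps, persist_steps,
                         tau_m, tau_a, eps, y_cap, uncapped_inh, dt,
                         delta_ah, delta_hop_eff, w_cap, active_thr,
                         A_out):
    """Run a sequence of presentations, recording activity every step.

    Returns the index of the first non-finite step, or -1 if all finite.
    Each presentation starts from the state row ``Y0[p]`` (zeros, or small
    random values when reactivation is noise-seeded); adaptation carries
    over.  After a presentation the network reverberates ``persist_steps``
    into the silence, is then quenched, and adaptation decays passively for
    the remaining silent steps.  No plasticity acts outside the pattern-on
    window.
    """
    n = Y.shape[0]
    t = 0
    drive_off = -Sigma
    alpha_decay = np.exp(-dt / tau_a)
    for p in range(sched_syll.shape[0]):
        for i in range(n):
            Y[i] = Y0[p, i]
        s = sched_syll[p]
        if s >= 0:
            B = patterns[s]
        else:
            B = onset
        drive_on = W_B @ B - Sigma
        for _ in range(present_steps):
            ok = _step_kernel(Y, alpha, W, drive_on, tau_m, tau_a, eps, y_cap,
                              uncapped_inh, dt, mode_on[p], delta_ah,
                              delta_hop_eff, w_cap, active_thr)
            for i in range(n):
                a = Y[i]
                if a < 0.0:
                    a = 0.0
                elif a > y_cap:
                    a = y_cap
                A_out[t, i] = a
            t += 1
            if not ok:
                return t - 1
        for k in range(silence_steps):
            if k < persist_steps:
                ok = _step_kernel(Y, alpha, W, drive_off, tau_m, tau_a, eps,
                                  y_cap, uncapped_inh, dt, 0, delta_ah,
                                  delta_hop_eff, w_cap, active_thr)
                for i in range(n):
                    a = Y[i]
                    if a < 0.0:
                        a = 0.0
                    elif a > y_cap:
                        a = y_cap
                    A_out[t, i] = a
                t += 1
                if not ok:
                    return t - 1
            else:
                if k == persist_steps:
                    for i in range(n):
                        Y[i] = 0.0
                for i in range(n):
                    alpha[i] *= alpha_decay
                    A_out[t, i] = 0.0
                t += 1
    return -1


# ---------------------------------------------------------------------------
# Public stepping API
# ---------------------------------------------------------------------------

def step_dynamics(state: NifState, weights: NifWeights, input_vector: np.ndarray,
                  params: NifParams, learning_mode: str = "off") -> NifState:
    """Advance the network by one ``dt_ms`` step.

    Returns the new state; when ``learning_mode`` is not ``"off"`` the
    recurrent matrix ``weights.W`` is updated in place (once per step, after
    the integration substep).
    """
    if learning_mode not in LEARNING_MODES:
        raise ConfigurationError(f"unknown learning_mode {learning_mode!r}")
    input_vector = np.asarray(input_vector, dtype=float)
    if input_vector.shape != (params.n_inputs,):
        raise ConfigurationError(
            f"input_vector must have shape ({params.n_inputs},), got {input_vector.shape}")
    if not (np.all(np.isfinite(state.Y)) and np.all(np.isfinite(state.alpha))):
        raise IntegrationError("state is non-finite before stepping", t_ms=state.t_ms)
    new = state.copy()
    drive = weights.W_B @ input_vector - weights.Sigma
    ok = _step_kernel(new.Y, new.alpha, weights.W, drive,
                      params.tau_m, params.tau_adapt, params.eps_adapt,
                      params.y_cap, params.uncapped_inhibition, params.dt_ms,
                      LEARNING_MODES[learning_mode],
                      params.delta_ah, params.delta_hop * params.hop_rate,
                      params.w_cap, params.active_threshold)
    new.t_ms = state.t_ms + params.dt_ms
    if not ok:
        raise IntegrationError(
            f"non-finite state after step at t={new.t_ms} ms", t_ms=new.t_ms)
    return new
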