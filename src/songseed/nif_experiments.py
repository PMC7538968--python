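"""Tutoring/singing protocol runner, ensemble extraction and outcome scoring.

A full imitation run proceeds in two phases.  During *tutoring* the network
sees each syllable pattern (plus the shared onset signal) in sequence for
``cycles_tutor`` sweeps; the first presentation of each syllable uses the
anti-Hebbian decorrelation rule and every later step uses the Hopfield-like
consolidation rule.  During *singing* the onset signal alone is presented
``cycles_sing`` times with plasticity off; adaptation makes the imprinted
ensembles take turns reactivating.

Ensembles are detected from activity logs (per-presentation active sets,
greedily clustered by Jaccard overlap) and runs are scored as success or as
one of the failure modes observed in natural song learning: *deletion* (a
tutored ensemble never reactivates), *improvisation* (a novel ensemble
appears during singing), *duplication* (one tutor syllable imprints two
distinct ensembles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IntegrationError, ScoringError
from .nif_dynamics import (
    InputProgram,
    NifParams,
    NifState,
    NifWeights,
    LEARNING_MODES,
    compute_sigma,
    init_network,
    make_input_program,
    _run_schedule_kernel,
)


# ---------------------------------------------------------------------------
# Activity logs
# ---------------------------------------------------------------------------

@dataclass
class ActivityLog:
    """Network activity over a phase, with per-presentation bookkeeping.

    ``A`` is activity (thresholded membrane potential) at dt resolution;
    ``presentations`` has one row per presentation with columns
    ``pres, syllable, phase, cycle, t_start`` (t_start in ms from log start).
    """

    A: np.ndarray                     # (T, n_neurons) float32
    presentations: pd.DataFrame
    present_steps: int
    silence_steps: int
    dt_ms: float = 1.0

    @property
    def duration_ms(self) -> float:
        return self.A.shape[0] * self.dt_ms

    def presentation_slice(self, pres: int) -> np.ndarray:
        """Activity during the pattern-on window of one presentation."""
        row = self.presentations.iloc[pres]
        t0 = int(round(row.t_start / self.dt_ms))
        return self.A[t0:t0 + self.present_steps]


def _run_phase(weights: NifWeights, state: NifState, program: InputProgram,
               params: NifParams, phase: str,
               rng: np.random.Generator | None = None) -> ActivityLog:
    """Run all presentations of one phase through the compiled kernel."""
    entries = [(i, s) for i, (s, ph) in enumerate(program.schedule) if ph == phase]
    if not entries:
        raise ScoringError(f"program has no {phase!r} presentations")
    sched_syll = np.array([s for _, s in entries], dtype=np.int64)
    K = program.n_syllables
    n_pres = len(entries)
    if phase == "tutor":
        # anti-Hebbian during the 30-ms on-window of each syllable's first
        # presentation (cycle 1); Hopfield during every later on-window.
        # Plasticity acts only while a pattern is on; silences carry none.
        mode_on = np.where(np.arange(n_pres) < K,
                           LEARNING_MODES["anti_hebbian"],
                           LEARNING_MODES["hopfield"]).astype(np.int64)
        Y0 = np.zeros((n_pres, params.n_neurons))
        # tutoring reverberates persist_ms into each gap, then is quenched
        persist_steps = min(int(round(params.persist_ms / params.dt_ms)),
                            params.silence_steps)
    else:
        mode_on = np.zeros(n_pres, dtype=np.int64)
        # which stored ensemble reactivates on a non-specific onset pulse
        # depends on noise / initial conditions: jitter the reset potential
        if rng is None:
            rng = np.random.default_rng(0)
        Y0 = rng.normal(0.0, params.sing_jitter,
                        size=(n_pres, params.n_neurons))             if params.sing_jitter > 0 else np.zeros((n_pres, params.n_neurons))
        persist_steps = params.silence_steps

    steps_per = params.present_steps + params.silence_steps
    A_out = np.zeros((n_pres * steps_per, params.n_neurons), dtype=np.float32)
    bad = _run_schedule_kernel(
        state.Y, state.alpha, weights.W, weights.W_B, weights.Sigma,
        program.patterns, program.onset_signal,
        sched_syll, mode_on, Y0,
        params.present_steps, params.silence_steps, persist_steps,
        params.tau_m, params.tau_adapt, params.eps_adapt,
        params.y_cap, params.uncapped_inhibition, params.dt_ms,
        params.delta_ah, params.delta_hop * params.hop_rate, params.w_cap,
        params.active_threshold, A_out)
    if bad >= 0:
        pres = bad // steps_per
        raise IntegrationError(
            f"non-finite state in {phase} presentation {pres} "
            f"(step {bad % steps_per})", t_ms=bad * params.dt_ms)
    state.t_ms += n_pres * steps_per * params.dt_ms

    pres_table = pd.DataFrame({
        "pres": np.arange(n_pres),
        "syllable": sched_syll,
        "phase": phase,
        "cycle": (np.arange(n_pres) // K + 1) if phase == "tutor"
                 else np.arange(n_pres) + 1,
        "t_start": np.arange(n_pres) * steps_per * params.dt_ms,
    })
    return ActivityLog(A=A_out, presentations=pres_table,
                       present_steps=params.present_steps,
                       silence_steps=params.silence_steps,
                       dt_ms=params.dt_ms)


def run_tutoring(weights: NifWeights, state: NifState, program: InputProgram,
                 params: NifParams) -> tuple[NifWeights, ActivityLog]:
    """Run the tutoring phase with plasticity on; returns the trained weights
    (mutated in place) and the full activity log."""
    log = _run_phase(weights, state, program, params, "tutor")
    return weights, log


def run_singing(weights: NifWeights, state: NifState, program: InputProgram,
                params: NifParams,
                rng: np.random.Generator | None = None) -> ActivityLog:
    """Run the singing phase (onset signal alone, plasticity off).

    ``rng`` seeds the per-presentation initial-condition jitter that decides
    which stored ensemble reactivates first.  ``weights.W`` is bit-identical
    before and after.
    """
    return _run_phase(weights, state, program, params, "sing", rng=rng)


# ---------------------------------------------------------------------------
# Ensemble extraction
# ---------------------------------------------------------------------------

@dataclass
class Ensemble:
    """One detected ensemble: a neuron set plus its member presentations."""

    cluster_id: int
    founder: frozenset
    members: list            # presentation indices (within the source log)
    syllables: list          # syllable labels of member presentations
    phase: str

    @property
    def neurons(self) -> frozenset:
        return self.founder


@dataclass
class EnsembleAssignment:
    """Per-presentation active sets clustered into ensembles."""

    active_sets: list                    # list[frozenset], one per presentation
    clusters: list                       # list[Ensemble]
    pres_cluster: np.ndarray             # cluster id per presentation, -1 if silent
    tutor_map: dict = field(default_factory=dict)   # syllable -> sorted cluster ids
    sing_sequence: list = field(default_factory=list)
    silent: list = field(default_factory=list)      # presentations with no activity

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


def extract_ensembles(log: ActivityLog, activity_frac: float = 0.1,
                      merge_jaccard: float = 0.5,
                      cycles: tuple | None = None,
                      silent_frac: float = 0.1) -> EnsembleAssignment:
    """Detect ensembles from an activity log.

    Per presentation, the active set is the set of neurons whose mean activity
    over the pattern-on window exceeds ``activity_frac`` times the largest
    such mean in that presentation.  Presentations whose peak mean activity
    falls below ``silent_frac`` times the strongest presentation in the log
    are treated as silent (no ensemble activated) rather than yielding noise
    clusters.  Presentations are then greedily clustered in order: a
    presentation joins the best-matching existing cluster when the Jaccard
    overlap with the cluster's founding set is at least ``merge_jaccard``,
    otherwise it founds a new cluster.

    ``cycles`` optionally restricts to an inclusive (first, last) cycle range.
    """
    table = log.presentations
    if cycles is not None:
        keep = (table.cycle >= cycles[0]) & (table.cycle <= cycles[1])
        table = table[keep]
    mean_acts, order = [], []
    for _, row in table.iterrows():
        seg = log.presentation_slice(int(row.pres))
        mean_acts.append(seg.mean(axis=0))
        order.append(int(row.pres))
    peaks = np.array([m.max() for m in mean_acts]) if mean_acts else np.empty(0)
    global_peak = peaks.max() if peaks.size else 0.0
    floor = max(silent_frac * global_peak, 1e-9)
    active_sets = []
    for mean_a, peak in zip(mean_acts, peaks):
        if peak < floor:
            active_sets.append(frozenset())
        else:
            active_sets.append(frozenset(np.flatnonzero(mean_a > activity_frac * peak)))

    clusters: list[Ensemble] = []
    pres_cluster = np.full(len(active_sets), -1, dtype=int)
    silent = []
    phase = table.phase.iloc[0] if len(table) else ""
    for idx, (pres, aset) in enumerate(zip(order, active_sets)):
        syll = int(table.iloc[idx].syllable)
        if not aset:
            silent.append(pres)
            continue
        best, best_j = None, -1.0
        for c in clusters:
            j = jaccard(aset, c.founder)
            if j >= merge_jaccard and j > best_j:
                best, best_j = c, j
        if best is None:
            best = Ensemble(cluster_id=len(clusters), founder=aset,
                            members=[], syllables=[], phase=phase)
            clusters.append(best)
        best.members.append(pres)
        best.syllables.append(syll)
        pres_cluster[idx] = best.cluster_id

    tutor_map: dict[int, list[int]] = {}
    sing_sequence: list[int] = []
    if phase == "tutor":
        for c in clusters:
            for s in set(c.syllables):
                tutor_map.setdefault(s, []).append(c.cluster_id)
        tutor_map = {s: sorted(ids) for s, ids in tutor_map.items()}
    elif phase == "sing":
        sing_sequence = [int(c) for c in pres_cluster if c >= 0]
    return EnsembleAssignment(active_sets=active_sets, clusters=clusters,
                              pres_cluster=pres_cluster, tutor_map=tutor_map,
                              sing_sequence=sing_sequence, silent=silent)


# ---------------------------------------------------------------------------
# Outcome scoring
# ---------------------------------------------------------------------------

@dataclass
class RunOutcome:
    """Label plus raw flags/counts for one tutor+sing run."""

    label: str                      # success / deletion / improvisation / duplication / other
    n_tutor_ensembles: int
    n_sing_ensembles: int
    flags: dict = field(default_factory=dict)
    details: dict = field(default_factory=dict)


def score_run(tutor_assignment: EnsembleAssignment,
              sing_assignment: EnsembleAssignment, K: int,
              match_jaccard: float = 0.5,
              min_ensemble_size: int = 7) -> RunOutcome:
    """Score one run against the tutor song.

    Success requires the correct number of tutoring ensembles (== K), every
    tutoring ensemble matched (Jaccard >= ``match_jaccard``) by at least one
    singing ensemble, no syllable imprinting two distinct tutoring ensembles,
    and no unmatched singing ensemble of syllable scale.  Singing clusters
    smaller than ``min_ensemble_size`` neurons are transient flickers, not
    improvised syllables, and do not count against the run (they are kept in
    ``details``).  Failure labels follow the precedence
    duplication > deletion > improvisation; all raw flags are retained.
    """
    if not tutor_assignment.clusters or not sing_assignment.clusters:
        raise ScoringError("cannot score a run with empty ensemble assignments")

    t_sets = [c.neurons for c in tutor_assignment.clusters]
    s_sets = [c.neurons for c in sing_assignment.clusters]
    t_matched = [any(jaccard(t, s) >= match_jaccard for s in s_sets) for t in t_sets]
    s_matched = [any(jaccard(t, s) >= match_jaccard for t in t_sets) for s in s_sets]

    duplication = any(len(ids) >= 2 for ids in tutor_assignment.tutor_map.values())
    deletion = not all(t_matched)
    unmatched_sizes = [len(s) for s, m in zip(s_sets, s_matched) if not m]
    improvisation = any(sz >= min_ensemble_size for sz in unmatched_sizes)
    correct_count = len(t_sets) == K
    success = (correct_count and not deletion and not improvisation
               and not duplication)

    if success:
        label = "success"
    elif duplication:
        label = "duplication"
    elif deletion:
        label = "deletion"
    elif improvisation:
        label = "improvisation"
    else:
        label = "other"
    return RunOutcome(
        label=label,
        n_tutor_ensembles=len(t_sets),
        n_sing_ensembles=len(s_sets),
        flags={"duplication": duplication, "deletion": deletion,
               "improvisation": improvisation, "correct_count": correct_count},
        details={"tutor_matched": t_matched, "sing_matched": s_matched,
                 "unmatched_sing_sizes": unmatched_sizes,
                 "tutor_map": dict(tutor_assignment.tutor_map),
                 "silent_sing_presentations": list(sing_assignment.silent)},
    )


# ---------------------------------------------------------------------------
# Full runs and sweeps
# ---------------------------------------------------------------------------

def run_imitation(K: int, seed: int, params: NifParams | None = None,
                  activity_frac: float = 0.1, merge_jaccard: float = 0.5,
                  tutor_eval_cycles: tuple | None = None,
                  return_logs: bool = False):
    """One complete tutor + sing simulation, scored.

    The tutoring assignment is extracted from the second half of the tutoring
    cycles (by default), i.e. from the consolidated regime, so that the
    disorganized first cycles do not spawn spurious clusters; duplication
    (a syllable alternating between two ensembles) is still visible there.
    """
    params = params or NifParams()
    program = make_input_program(K, params, seed)
    weights, state = init_network(params, seed)
    weights.Sigma = compute_sigma(weights.W_B, program.patterns, params.sigma_coeff)
    if tutor_eval_cycles is None:
        tutor_eval_cycles = (params.cycles_tutor // 2 + 1, params.cycles_tutor)

    weights, tutor_log = run_tutoring(weights, state, program, params)
    sing_log = run_singing(weights, state, program, params,
                           rng=np.random.default_rng([seed, 1]))

    tutor_asn = extract_ensembles(tutor_log, activity_frac, merge_jaccard,
                                  cycles=tutor_eval_cycles)
    sing_asn = extract_ensembles(sing_log, activity_frac, merge_jaccard)
    outcome = score_run(tutor_asn, sing_asn, K, match_jaccard=merge_jaccard)
    if return_logs:
        return outcome, (weights, tutor_log, sing_log, tutor_asn, sing_asn)
    return outcome


def success_rate_experiment(K: int, n_runs: int = 100, base_seed: int = 0,
                            params: NifParams | None = None,
                            **detector_kw) -> pd.DataFrame:
    """Run ``n_runs`` independent imitation simulations (run i seeded with
    ``base_seed + i``) and tabulate the outcomes.

    Returns one row per run with columns
    ``run, seed, K, label, n_tutor_ens, n_sing_ens`` plus the raw flags.
    Individual run errors are recorded as label ``"error"``, not raised.
    """
    rows = []
    for i in range(n_runs):
        seed = base_seed + i
        try:
            out = run_imitation(K, seed, params, **detector_kw)
            rows.append({"run": i, "seed": seed, "K": K, "label": out.label,
                         "n_tutor_ens": out.n_tutor_ensembles,
                         "n_sing_ens": out.n_sing_ensembles, **out.flags})
        except Exception as exc:   # per-run failures are data, not fatal
            rows.append({"run": i, "seed": seed, "K": K, "label": "error",
                         "n_tutor_ens": 0, "n_sing_ens": 0, "note": str(exc)})
    return pd.DataFrame(rows)


def count_successes(outcomes: pd.DataFrame) -> int:
    return int((outcomes.label == "success").sum())


def cycles_to_criterion(K: int, seed: int, params: NifParams,
                        activity_frac: float = 0.1,
                        merge_jaccard: float = 0.5) -> int:
    """First tutoring cycle c such that every cycle >= c shows exactly K
    ensembles (clustering each cycle's presentations separately).
    Returns -1 when the criterion is never reached."""
    program = make_input_program(K, params, seed)
    weights, state = init_network(params, seed)
    weights.Sigma = compute_sigma(weights.W_B, program.patterns, params.sigma_coeff)
    _, log = run_tutoring(weights, state, program, params)
    counts = []
    for c in range(1, params.cycles_tutor + 1):
        asn = extract_ensembles(log, activity_frac, merge_jaccard, cycles=(c, c))
        counts.append(asn.n_clusters)
    for c0 in range(len(counts)):
        if all(cnt == K for cnt in counts[c0:]):
            return c0 + 1
    return -1


def size_scaling_check(sizes=(100, 500, 1000), K: int = 4, seed: int = 0,
                       params: NifParams | None = None) -> pd.DataFrame:
    """Cycles-to-criterion for several network sizes (inputs scaled with the
    network).  A property check: the learning speed should be of the same
    order across sizes."""
    params = params or NifParams()
    rows = []
    for size in sizes:
        p = params.replace(n_neurons=int(size), n_inputs=int(size))
        rows.append({"size": int(size), "K": K,
                     "cycles_to_criterion": cycles_to_criterion(K, seed, p)})
    return pd.DataFrame(rows)
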