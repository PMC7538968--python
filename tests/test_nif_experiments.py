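"""Tests of the tutoring/singing protocol runner, ensemble detection and
outcome scoring."""

import numpy as np
import pandas as pd
import pytest

from songseed import (NifParams, NifWeights, NifState, InputProgram,
                      init_network, make_input_program, compute_sigma,
                      run_tutoring, run_singing, run_imitation,
                      extract_ensembles, score_run, success_rate_experiment,
                      ScoringError)
from songseed.nif_experiments import (ActivityLog, EnsembleAssignment,
                                      Ensemble, jaccard, cycles_to_criterion)


def _toy_log(active_sets, n_neurons=30, phase="sing", syllables=None):
    """Build an ActivityLog whose presentations activate the given neuron
    sets at a constant level."""
    present, silence = 30, 70
    steps = present + silence
    A = np.zeros((len(active_sets) * steps, n_neurons), dtype=np.float32)
    for p, s in enumerate(active_sets):
        A[p * steps:p * steps + present, sorted(s)] = 0.5
    syll = syllables if syllables is not None else [-1] * len(active_sets)
    tab = pd.DataFrame({
        "pres": np.arange(len(active_sets)),
        "syllable": syll,
        "phase": phase,
        "cycle": np.arange(len(active_sets)) + 1,
        "t_start": np.arange(len(active_sets)) * steps * 1.0,
    })
    return ActivityLog(A=A, presentations=tab, present_steps=present,
                       silence_steps=silence)


# ---------------------------------------------------------------------------
# Protocol runner
# ---------------------------------------------------------------------------

class TestPhases:
    def test_log_length_matches_schedule(self, nif_params):
        prog = make_input_program(4, nif_params, 0)
        weights, state = init_network(nif_params, 0)
        weights.Sigma = compute_sigma(weights.W_B, prog.patterns,
                                      nif_params.sigma_coeff)
        _, log = run_tutoring(weights, state, prog, nif_params)
        assert log.duration_ms == 20 * 4 * (30 + 70)

    def test_zero_learning_rates_leave_weights_unchanged(self):
        p = NifParams(delta_ah=0.0, delta_hop=0.0)
        prog = make_input_program(3, p, 1)
        weights, state = init_network(p, 1)
        weights.Sigma = compute_sigma(weights.W_B, prog.patterns,
                                      p.sigma_coeff)
        before = weights.W.copy()
        run_tutoring(weights, state, prog, p)
        assert np.array_equal(weights.W, before)

    def test_singing_is_plasticity_free(self, nif_params):
        prog = make_input_program(3, nif_params, 2)
        weights, state = init_network(nif_params, 2)
        weights.Sigma = compute_sigma(weights.W_B, prog.patterns,
                                      nif_params.sigma_coeff)
        run_tutoring(weights, state, prog, nif_params)
        before = weights.W.copy()
        run_singing(weights, state, prog, nif_params,
                    rng=np.random.default_rng(0))
        assert np.array_equal(weights.W, before)

    def test_weight_invariants_hold_after_tutoring(self, nif_params):
        prog = make_input_program(4, nif_params, 3)
        weights, state = init_network(nif_params, 3)
        weights.Sigma = compute_sigma(weights.W_B, prog.patterns,
                                      nif_params.sigma_coeff)
        run_tutoring(weights, state, prog, nif_params)
        assert np.all(np.diag(weights.W) == 0)
        assert np.all(np.abs(weights.W) <= nif_params.w_cap + 1e-12)

    def test_planted_attractor_reactivates_on_onset_input(self):
        # hand-built 6-neuron network with one imprinted ensemble {0,1,2}:
        # mutually excitatory, inhibiting {3,4,5}; a nonspecific onset kick
        # reactivates exactly the imprinted ensemble
        p = NifParams(n_neurons=6, n_inputs=6, cycles_sing=5, sing_jitter=0.0)
        W = np.full((6, 6), -1.0)
        W[np.ix_([0, 1, 2], [0, 1, 2])] = 1.0
        np.fill_diagonal(W, 0.0)
        weights = NifWeights(W=W, W_B=np.eye(6), Sigma=np.zeros(6))
        state = NifState(Y=np.zeros(6), alpha=np.zeros(6))
        onset = np.full(6, 0.3)          # same kick to every neuron
        prog = InputProgram(patterns=np.zeros((1, 6)), onset_signal=onset,
                            schedule=[(-1, "sing")] * 5)
        log = run_singing(weights, state, prog, p)
        asn = extract_ensembles(log)
        assert asn.active_sets[0] == frozenset({0, 1, 2})


# ---------------------------------------------------------------------------
# Ensemble detection
# ---------------------------------------------------------------------------

class TestExtractEnsembles:
    def test_identical_sets_one_cluster(self):
        log = _toy_log([{1, 2, 3}, {1, 2, 3}, {1, 2, 3}])
        asn = extract_ensembles(log)
        assert asn.n_clusters == 1
        assert asn.clusters[0].members == [0, 1, 2]

    def test_disjoint_sets_two_clusters(self):
        log = _toy_log([set(range(1, 11)), set(range(11, 21))])
        asn = extract_ensembles(log, merge_jaccard=0.05)
        assert asn.n_clusters == 2

    def test_jaccard_two_thirds_merges_at_half_splits_at_point_seven(self):
        a = set(range(1, 11))                 # {1..10}
        b = set(range(1, 9)) | {21, 22}       # {1..8, 21, 22}; J = 8/12
        assert np.isclose(jaccard(frozenset(a), frozenset(b)), 8 / 12)
        log = _toy_log([a, b])
        assert extract_ensembles(log, merge_jaccard=0.5).n_clusters == 1
        assert extract_ensembles(log, merge_jaccard=0.7).n_clusters == 2

    def test_silent_presentations_flagged_not_clustered(self):
        log = _toy_log([{1, 2, 3, 4}, set(), {1, 2, 3, 4}])
        asn = extract_ensembles(log)
        assert asn.silent == [1]
        assert asn.n_clusters == 1

    def test_weak_flicker_presentation_counts_as_silent(self):
        # a presentation far below the log's strongest is background, not
        # an ensemble activation
        log = _toy_log([{1, 2, 3, 4}, {7, 8}])
        log.A[100:130] *= 0.02   # second presentation at 2% amplitude
        asn = extract_ensembles(log, silent_frac=0.1)
        assert asn.silent == [1]


# ---------------------------------------------------------------------------
# Outcome scoring
# ---------------------------------------------------------------------------

def _assignment(sets, phase, syllables=None):
    clusters = []
    for i, s in enumerate(sets):
        syl = [syllables[i]] if syllables else [-1]
        clusters.append(Ensemble(cluster_id=i, founder=frozenset(s),
                                 members=[i], syllables=syl, phase=phase))
    tutor_map = {}
    if syllables:
        for i, s in enumerate(syllables):
            tutor_map.setdefault(s, []).append(i)
    return EnsembleAssignment(active_sets=[frozenset(s) for s in sets],
                              clusters=clusters,
                              pres_cluster=np.arange(len(sets)),
                              tutor_map=tutor_map)


E1, E2, E3, E4, E5 = ({i * 10 + j for j in range(10)} for i in range(5))


class TestScoreRun:
    def test_full_reactivation_is_success(self):
        t = _assignment([E1, E2, E3, E4], "tutor", syllables=[0, 1, 2, 3])
        s = _assignment([E1, E2, E3, E4], "sing")
        assert score_run(t, s, 4).label == "success"

    def test_unreactivated_tutor_ensemble_is_deletion(self):
        t = _assignment([E1, E2, E3, E4, E5], "tutor",
                        syllables=[0, 1, 2, 3, 4])
        s = _assignment([E1, E2, E3, E4], "sing")
        out = score_run(t, s, 5)
        assert out.label == "deletion"
        assert out.flags["deletion"] and not out.flags["duplication"]

    def test_novel_singing_ensemble_is_improvisation(self):
        t = _assignment([E1, E2, E3], "tutor", syllables=[0, 1, 2])
        s = _assignment([E1, E2, E3, E4], "sing")
        out = score_run(t, s, 3)
        assert out.label == "improvisation"

    def test_small_flicker_cluster_not_improvisation(self):
        t = _assignment([E1, E2, E3], "tutor", syllables=[0, 1, 2])
        s = _assignment([E1, E2, E3, {95, 96}], "sing")
        assert score_run(t, s, 3).label == "success"

    def test_two_ensembles_for_one_syllable_is_duplication(self):
        t = _assignment([E1, E2, E3, E4], "tutor", syllables=[0, 0, 1, 2])
        s = _assignment([E1, E2, E3, E4], "sing")
        out = score_run(t, s, 3)
        assert out.label == "duplication"

    def test_pure_function(self):
        t = _assignment([E1, E2], "tutor", syllables=[0, 1])
        s = _assignment([E1, E2], "sing")
        a = score_run(t, s, 2)
        b = score_run(t, s, 2)
        assert a.label == b.label and a.flags == b.flags

    def test_empty_assignment_raises(self):
        t = _assignment([E1], "tutor", syllables=[0])
        empty = EnsembleAssignment(active_sets=[], clusters=[],
                                   pres_cluster=np.empty(0, dtype=int))
        with pytest.raises(ScoringError):
            score_run(t, empty, 1)


# ---------------------------------------------------------------------------
# Full runs and population properties
# ---------------------------------------------------------------------------

class TestFullRuns:
    def test_replays_bit_identical_given_seed(self):
        a = run_imitation(3, 11)
        b = run_imitation(3, 11)
        assert a.label == b.label
        assert a.n_tutor_ensembles == b.n_tutor_ensembles

    def test_sweep_table_shape_and_determinism(self):
        df = success_rate_experiment(3, n_runs=3, base_seed=5)
        assert len(df) == 3
        assert set(df.seed) == {5, 6, 7}
        df2 = success_rate_experiment(3, n_runs=3, base_seed=5)
        assert list(df.label) == list(df2.label)

    def test_anti_hebbian_phase_decorrelates_syllable_ensembles(self):
        # paired over seeds: mean pairwise overlap of per-syllable active
        # sets in the cycle after decorrelation is lower than in cycle 1
        from scipy import stats as sps
        lower = 0
        n_seeds = 20
        for seed in range(n_seeds):
            p = NifParams()
            prog = make_input_program(4, p, seed)
            weights, state = init_network(p, seed)
            weights.Sigma = compute_sigma(weights.W_B, prog.patterns,
                                          p.sigma_coeff)
            _, log = run_tutoring(weights, state, prog, p)
            def mean_overlap(cycle):
                asn = extract_ensembles(log, cycles=(cycle, cycle))
                sets = [s for s in asn.active_sets if s]
                js = [jaccard(sets[i], sets[j])
                      for i in range(len(sets)) for j in range(i + 1, len(sets))]
                return np.mean(js) if js else 1.0
            if mean_overlap(2) < mean_overlap(1):
                lower += 1
        # sign test at p < 0.01
        p_val = sps.binomtest(lower, n_seeds, 0.5,
                              alternative="greater").pvalue
        assert p_val < 0.01

    def test_normalization_improves_imitation(self):
        # the feedforward normalization subtracts each neuron's mean drive,
        # sharpening per-syllable selectivity; without it more neurons stay
        # unclaimed and improvised coalitions intrude during singing
        n = 40
        on = success_rate_experiment(4, n_runs=n, base_seed=0)
        off = success_rate_experiment(4, n_runs=n, base_seed=0,
                                      params=NifParams(sigma_coeff=0.0))
        assert (on.label == "success").sum() > (off.label == "success").sum()

    def test_decorrelation_ablation_reduces_success(self):
        # switching off the anti-Hebbian phase lowers the success rate
        n = 50
        base = success_rate_experiment(4, n_runs=n, base_seed=0)
        ablat = success_rate_experiment(4, n_runs=n, base_seed=0,
                                        params=NifParams(delta_ah=0.0))
        assert (base.label == "success").sum() > (ablat.label == "success").sum()


class TestSizeScaling:
    def test_identical_seed_identical_criterion_cycle(self):
        p = NifParams()
        a = cycles_to_criterion(3, 4, p)
        b = cycles_to_criterion(3, 4, p)
        assert a == b

    def test_learning_speed_consistent_across_sizes(self):
        # the cycle at which the correct ensemble count stabilizes is of
        # the same order for 100- and 500-neuron networks
        p100 = NifParams()
        p500 = NifParams(n_neurons=500, n_inputs=500)
        c100 = cycles_to_criterion(4, 1, p100)
        c500 = cycles_to_criterion(4, 1, p500)
        assert c100 > 0 and c500 > 0
        assert max(c100, c500) <= 2 * min(c100, c500) + 2
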