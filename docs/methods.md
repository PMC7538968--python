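# Methods

This note documents the models and statistics implemented in `songseed`:
their assumptions, the parameters that matter, the choices made where the
published description left the design open, and what the tests do and do
not establish.

## Sensorimotor (NIf) ensemble model

### Dynamics

A network of `n_neurons = 100` rate units is all-to-all recurrently
connected through a plastic matrix `W` (zero diagonal, entries clipped to
`[-1, +1]`). Each unit also receives high-dimensional feed-forward input
through a fixed matrix `W_B` whose entries are drawn from a de-meaned
log-normal distribution, `exp(N(0, s^2)) - exp(s^2/2)` with `s = 0.25`:
many weak negative entries, a few strong positive ones. The state is a
membrane potential `Y` and an adaptation variable `alpha`:

    tau   dY/dt     = -Y + W+ A + W- Y+ + W_B B - alpha - Sigma
    tau_i dalpha/dt = eps A - alpha

with `tau = 10 ms`, `tau_i = 125 ms`, `eps = 10`. The activity is the
capped threshold-linear function `A = min(max(Y, 0), y_cap)` with
`y_cap = 0.5`; the inhibitory term acts on the *uncapped* positive part
`Y+ = max(Y, 0)`. This asymmetry is deliberate and is why the equation
splits `W` into its positive and negative parts at all: excitation
saturates with activity while inhibition keeps growing with drive, so a
coherent, strongly driven ensemble can silence loose coalitions of
individually depolarized neurons. Under the alternative reading — the cap
applied to the state so that `Y+ = A` — the two recurrent terms collapse
into one and, empirically, "leftover" neurons that belong to no ensemble
form spurious coalitions during singing. The capped-state variant remains
available via `NifParams.uncapped_inhibition = False`.

Integration is classical fixed-step RK4 on a `dt = 1 ms` grid, with one
plasticity application per step. A convergence test checks the integrator
against the closed-form relaxation to `-Sigma` at `dt` and `dt/10`.

`Sigma = 0.75 * (1/K) sum_i W_B B_i` is computed once per run from the
tutor patterns. It subtracts (three quarters of) each neuron's mean
feed-forward drive, so a neuron responds only to syllables that drive it
above its own average — the main source of per-syllable selectivity. An
ablation test shows imitation success drops substantially without it.

### Inputs and protocol

Each of `K` tutor syllables is a sparse random pattern (uniform values on
(0, 1], 80% of entries forced to zero, in a 100-dimensional input space).
A shared *onset signal* with the same statistics represents the
nonspecific syllable-onset input (efference copy during babbling).
Tutoring presents the syllable patterns alone, sequentially, 30 ms on /
70 ms off, for 20 cycles; singing presents the onset signal alone for 20
cycles. The tutoring input deliberately excludes the onset signal: the
normalization formula is defined over the syllable patterns `B_i`, and an
additive onset component is a common-mode drive that `Sigma` would not
cancel — in simulation it destroys the uniformity of ensemble sizes.

The membrane potential is reset to 0 before every presentation
(adaptation carries over). After a presentation, activity is allowed to
reverberate `persist_ms = 23 ms` into the silent gap and is then
quenched, with adaptation decaying passively for the remainder. This
timing matters: with full-gap reverberation the just-active ensemble
builds so much adaptation that it surrenders contested neurons to earlier
syllables permanently (late syllables end with tiny ensembles); with no
reverberation a recovered ensemble re-fires during *other* syllables'
presentations and merges them. Singing-phase gaps keep full dynamics,
because the adaptation built there is what rotates the reactivated
ensemble. Singing presentations start from a small random potential
(`sing_jitter = 0.15`): which stored attractor wins a given onset is
determined by noise/initial conditions, and a deterministic network
otherwise locks into a rotation of at most four ensembles (the adaptation
recovery time, ~4 presentation periods, sets that number), systematically
deleting the fifth syllable.

### Plasticity

During the first presentation of each syllable (the first tutoring
cycle), the anti-Hebbian rule `dW = -eta_AH * outer(A, A)` with
`eta_AH = 0.05` per millisecond makes co-active pairs mutually
inhibitory, decorrelating overlapping input patterns. From the second
cycle on, a Hopfield-like rule consolidates ensembles: `W_ij` gains when
`i` and `j` are both active (`A > 0`), loses when exactly one is active,
and is unchanged when neither is. Both rules act only while a pattern is
on; silent gaps carry no plasticity.

The per-millisecond Hopfield increment is `delta_hop * hop_rate` with
`delta_hop = 0.01` and `hop_rate = 0.25`. The printed increment of 0.01
applied at every 1-ms step saturates all weights within about two cycles,
freezing the greedy first-come membership of the very first
presentations; the published protocol of 20 tutoring cycles only makes
sense if consolidation uses most of them. At 0.0025/ms the weights
saturate near the end of tutoring, and ensemble membership anneals toward
a balanced partition over the first ~15 cycles. This granularity
reinterpretation was calibrated — once, together with the persistence and
jitter values above — against the published success rates, which are the
only quantitative observable of the original implementation.

### Ensemble detection and outcome scoring

The detection rule is a reconstruction (none is published). Per
presentation, the active set is every neuron whose mean activity over the
30-ms on-window exceeds 0.1× the presentation's maximum; presentations
whose peak is below 0.1× the log's strongest presentation count as
silent. Active sets are greedily clustered (join the best cluster with
Jaccard ≥ 0.5 against its founding set). The tutoring assignment uses
cycles 11–20, after consolidation. A run is a **success** when tutoring
forms exactly `K` ensembles, each is matched (Jaccard ≥ 0.5) by a singing
ensemble, no syllable imprinted two ensembles, and no unmatched singing
cluster of at least 7 neurons appears. Unmatched singing clusters below 7
neurons are transient flickers, not improvised syllables — the smallest
genuine ensembles observed are ~9–13 neurons. Failure labels follow the
precedence duplication > deletion > improvisation, with all raw flags
kept in the outcome.

With the defaults, 100-seed sweeps give success counts of about 94/100
(K=4), 85/100 (K=3) and 73/100 (K=5), with K=4 the most reliable — the
failure modes (improvisation at small K from the larger pool of
unclaimed neurons; deletion at K=5 from rotation misses) match the
published pattern.

## Premotor (HVC) chain-growth model

The original description defers the premotor model's internals entirely,
fixing only the protocol: trials of 4 pulses spaced 10 steps apart
(rhythmic) or single pulses (non-rhythmic), Poisson(50) inter-trial
intervals truncated at 27 steps, 7200 trials, 1 step = 10 ms. The network
here is therefore a reconstruction in the lineage of seed-neuron chain
models, with all internal constants tuned once so that a planted chain
propagates reliably and rhythmic training locks the readout to the
period:

* binary probabilistic neurons: spike probability is a logistic function
  of drive (`threshold 0.4`, `temperature 0.05`), with Gaussian input
  noise (sd 0.05);
* winner-take-all fast inhibition: at most `k_wta = 3` non-seed neurons
  burst per step, and forced seed bursts consume capacity first, so a
  stimulation pulse *captures* the network and silences a running chain;
* spontaneous bursts: with probability `5e-4` per neuron-step a neuron
  receives a transient drive bump (amplitude 1.2, below the consolidated
  drive level so bumps can seed recruitment in empty steps but cannot
  displace consolidated members);
* plasticity: pre(t−1)→post(t) potentiation (`eta_ltp = 0.8`, per-synapse
  cap 0.8 — a single coincidence consolidates), reverse-pair depression
  (0.05), and depression of any existing synapse whose target stays
  silent one step after its source fired (`eta_prune = 0.25`);
* heterosynaptic competition: iterative subtractive renormalization of
  summed incoming (1.6) and outgoing (1.6; seeds 1.0) weights —
  subtractive rather than proportional, so weak synapses are pruned while
  consolidated ones barely move;
* weak spike-frequency adaptation (gain 0.1, recovery 400 ms).

Rhythm tracking emerges from the capture-prune interaction: links that
would extend the chain across a pulse boundary are depressed three times
per rhythmic trial but reinforced only once (in the tail after the last
pulse), so the chain is cut at the stimulation period. The duration
readout (plasticity off, single pulse, duration = last step with non-seed
activity, 10 probes per run) gives ≈95 ms after 100-ms-period training
and ≈46 ms after 50-ms-period training.

**Known limitation.** Chains longer than ~10 groups — required by the
150-ms rhythmic period and by non-rhythmic training — grow but do not
stabilize: parallel branches and reused neurons compete in the
winner-take-all, links hover at the prune/potentiation break-even, and
the evoked duration fluctuates between ~30 and ~300 ms across training
runs. The qualitative contract holds (non-rhythmic durations reach
several hundred milliseconds and are far more variable across runs than
rhythmic ones), but the lower end of the non-rhythmic duration
distribution is ~10–40 ms rather than ~150 ms, and the 150-ms rhythmic
condition undershoots its period in some runs. Extensive tuning of the
adaptation, pruning, recruitment and budget constants did not remove this
churn without breaking the (much better constrained) 100-ms rhythmic
lock; the corresponding acceptance checks are left failing rather than
loosened.

## NIf→HVC bridge and the combined model

NIf singing activity (1-ms grid, 100 neurons) is converted to seed drive
(10-ms grid, 10 channels) by block-averaging ×10 along both axes and
keeping only onsets. The onset is defined as a crossing of a small floor
(0.08) rather than of zero, because tonically active neurons (those whose
normalization constant is negative) keep a downsampled channel weakly
positive across gaps and a literal zero-crossing would register no events
after the first presentation. Each onset event is normalized so its
strongest channel receives the full seed drive, with channels below 50%
of the event peak zeroed (the absolute NIf→HVC gain is unconstrained);
an ensemble's seed-channel group is the set of channels recruited on at
least half of its reactivations. Sub-chains are measured by probing each
ensemble's channel group separately and comparing the evoked non-seed
populations (overlap = intersection over the smaller set; a split
requires < 50%).

In the combined K=2 pipeline the upstream imitation stage succeeds in
only ~20% of seeds (with two ensembles, the unclaimed-neuron pool is
large and improvisation dominates), and among successful runs the two
seed groups grow clearly separate sub-chains in only a minority — the
same long-chain churn as above, plus the fact that recruitment does not
disfavor neurons already used by the other syllable's chain. The
pipeline, bridge invariants and probing are fully implemented and tested;
the ≥80% split criterion is left failing.

## Spike-train statistics and the synthetic session generator

PSTHs use 1-ms bins over ±200 ms around alignment events and a centered
20-bin boxcar (edge bins use shrinking windows); the kernel shape is a
choice (only the smoothing width is published). Peak latency is the
argmax of the smoothed rate in ±100 ms, ties broken to the smallest
absolute latency and then to the negative one. The circular-shift test
rotates each event's spikes by an independent uniform ±100 ms within the
±200-ms window and compares the observed statistic (window peak for
singing-style tests, window mean for tutoring-style tests, one-sided in
either direction) against the surrogate distribution with the
`(1 + #{null ≥ obs}) / (1 + n)` estimator. Population analysis z-scores
each neuron's PSTH, averages, and bounds the result with pointwise
quantile bands and a peak p-value from shifted controls.

The generator produces a jittered syllable table (Gaussian durations and
gaps) and spikes from an inhomogeneous Poisson process — baseline plus a
per-type Gaussian bump of configurable latency, width (FWHM) and
amplitude — sampled exactly by thinning. Calibration tests verify
uniform null p-values, nominal type-I error, recovery of planted
latencies across −41…+25 ms within half the smoothing width, and ≥90%
ANOVA power for a doubled burst amplitude.

Two caveats. First, when syllables are closer than the analysis window
(as in real song), neighbouring rasters share spikes; the circular-shift
null is then slightly conservative/anticonservative depending on the
statistic, so the calibration tests use well-separated events. Second,
the generator plants bursts locked to onsets with stationary baseline —
it does not emulate bout structure, latency drift, or non-Poisson
burstiness, so passing tests establish the correctness of the statistics,
not their robustness to every property of real recordings.

## Problem sizes used by the tests and the acceptance script

Success-rate sweeps use the full 100 runs per condition at the study's
network size. Premotor results use the full 7200-trial protocol; the
rhythmic duration is averaged over 3 training runs × 10 probes and the
non-rhythmic floor pools 20 training runs × 10 probes. Statistical
calibration uses 200 null neurons (199 shuffles each), 12 synthetic units
per planted latency, and 30 simulations for the power check. A full
acceptance run takes a few minutes on one CPU.
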