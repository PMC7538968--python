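# songseed

Mechanistic models of how a higher-order sensorimotor area can chunk a
tutor song into syllable-sized neural ensembles and use their replay to
seed premotor sequence learning — together with the event-aligned
spike-train statistics used to characterize such circuits.

Juvenile songbirds memorize a tutor song and later practice until they can
reproduce it. The nucleus interface of the nidopallium (NIf) sits between
the auditory and vocal-motor systems and bursts at syllable onsets both
when a young bird listens to its tutor and when it babbles. `songseed`
implements, as a tested simulation and analysis library:

* **`songseed.nif_dynamics` / `nif_experiments`** — a recurrent
  threshold-linear rate model of NIf in which tutor exposure imprints one
  attractor ensemble per tutor syllable, and a nonspecific syllable-onset
  signal (an efference copy of babbling commands) reactivates those
  ensembles one at a time during singing. Runs are scored as successful
  imitation or as the natural failure modes: syllable *deletion*,
  *improvisation*, and *duplication*.
* **`songseed.hvc_chain`** — a premotor (HVC) chain-growth network of
  binary probabilistic neurons: seed neurons driven by external pulses
  grow synaptic chains whose length is controlled by the stimulation
  rhythm, read out as a syllable duration.
* **`songseed.bridge`** — the coupling from NIf singing-phase replay to
  HVC seed neurons (temporal and population downsampling plus onset
  filtering) and the combined two-area pipeline that tests chain
  *splitting*: one premotor sub-chain per imprinted syllable.
* **`songseed.spike_analysis`** — onset-aligned PSTHs (1-ms bins, 20-bin
  smoothing), peak latencies, circular-shift significance tests,
  z-normalized population averages, and one-way ANOVA syllable
  selectivity, validated on a synthetic inhomogeneous-Poisson session
  generator with planted ground truth.

## The model in brief

NIf neurons follow

```
tau   dY/dt = -Y + W+ A + W- Y+ + W_B B - alpha - Sigma
tau_i dalpha/dt = eps A - alpha
```

with membrane potential `Y`, activity `A = min(max(Y, 0), 0.5)`
(threshold-linear, capped), `Y+ = max(Y, 0)`, plastic recurrent weights `W`
(positive/negative parts `W+`/`W-`, zero diagonal, clipped to ±1), fixed
feed-forward input weights `W_B`, adaptation `alpha` (`tau_i = 125 ms`,
`eps = 10`), and a per-neuron normalization
`Sigma = 0.75 * mean_i(W_B B_i)` over the `K` tutor patterns. During the
first presentation of each syllable an anti-Hebbian rule
`dW = -eta_AH Y+ Y+'` decorrelates overlapping inputs; afterwards a
Hopfield-like rule potentiates co-active pairs and depresses
active/inactive pairs, consolidating each syllable's active set into a
self-exciting, mutually inhibitory ensemble. Tutoring presents each of
`K` sparse random patterns for 30 ms with 70-ms gaps for 20 cycles; during
singing the patterns are replaced by the shared onset signal and
adaptation rotates which stored ensemble reactivates.

The premotor network is a binary chain-growth model on a 10-ms grid with
winner-take-all fast inhibition, spontaneous bursts that seed recruitment,
saturating Hebbian potentiation of pre→post pairs, heterosynaptic weight
budgets, and depression of synapses whose target stays silent — so a
stimulation pulse that captures the network prunes chains at the rhythm
boundary, locking syllable duration to the training period.

## Worked example

```
$ python examples/nif_imitation.py
outcome: success
tutoring formed 4 ensembles (sizes [36, 24, 14, 19] neurons), one per tutor syllable: {0: [0], 1: [1], 2: [2], 3: [3]}
singing reactivated 5 ensembles; presentation-by-presentation sequence: [0, 1, 2, 3, 4, 0, 1, 2, 3, 0, 4, 2, 0, 1, 4, 0, 2, 0, 1, 2]
```

Four tutor syllables imprinted four distinct ensembles (36, 24, 14 and 19
of the 100 neurons); during singing the onset signal reactivates all four
in rotation (the fifth listed cluster is a transient below syllable
scale), so the run scores as a successful imitation. Other seeds produce
deletions (an ensemble never reactivates), improvisations (a novel
coalition of leftover neurons activates), or duplications (one syllable
imprints two alternating ensembles) at roughly the rates seen in real
song learning experiments.

```
$ python examples/hvc_rhythm.py
rhythmic     : durations (ms) = 90 90 90 90 90 90 120 90 90 90   mean 93, sd 9
non_rhythmic : durations (ms) = 180 180 180 180 180 180 180 180 180 180   mean 180, sd 0
```

After rhythmic training (pulses every 100 ms) a single probe pulse evokes
~100 ms of activity — the network has learned the stimulation period as
its syllable duration. Irregular training grows longer chains whose
length varies strongly between training runs.

The other examples (`combined_split.py`, `spike_statistics.py`) run the
two-area pipeline and the spike-train statistics the same way; each prints
a short interpretation of its numbers.

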