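"""Onset-locking statistics on a synthetic single-unit recording.

Generates an inhomogeneous-Poisson unit that bursts 16 ms before syllable
onset with one syllable type driving stronger bursts than the other, then
runs the full analysis chain: onset-aligned PSTH, peak latency,
circular-shift significance, and ANOVA selectivity across syllable types.
"""

import numpy as np

from songseed import (SynthConfig, synth_session, make_psth, peak_latency,
                      circular_shift_test, selectivity_tests)

cfg = SynthConfig(latency_ms=-16.0, burst_gain=(40.0, 90.0), n_types=2,
                  n_renditions=50, baseline_hz=10.0, seed=3)
session = synth_session(cfg)
print(f"session: {len(session.spike_times)} spikes over "
      f"{session.n_syllables} syllables of {cfg.n_types} types")

psth = make_psth(session)
print(f"PSTH peak latency: {peak_latency(psth):+.1f} ms "
      f"(planted {cfg.latency_ms:+.1f} ms)")

p, obs, _ = circular_shift_test(session, test_window_ms=(-50, 25),
                                n_shuffles=2000, seed=1)
print(f"circular-shift test: peak {obs:.1f} Hz in [-50, +25] ms, p = {p:.4g}")

counts, F, p_anova = selectivity_tests(session)
means = {int(k): float(np.mean(v)) for k, v in counts.items()}
print(f"spike counts per rendition by type: {means}")
print(f"one-way ANOVA across types: F = {F:.1f}, p = {p_anova:.3g}")
print()
print("The unit is onset-locked (shift test) and syllable-selective")
print("(ANOVA): the planted burst latency and type preference are both")
print("recovered by the analysis chain.")
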