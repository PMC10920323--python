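"""Detect silent beats — metronome ticks with no bark.

Simulates a pup-like bout on a 0.35 s grid where two beats are skipped:
the corresponding IOIs are near-integer multiples of the period, and the
detector recovers the skipped ticks from the intervals alone.
"""

import numpy as np

from barkbeat import SimConfig, compute_iois, detect_silent_beats, simulate_bout

config = SimConfig(period=0.35, n_beats=12, jitter_sd=0.01, production_prob=0.7)
rng = np.random.default_rng(4)
sim = simulate_bout(config, rng, bout_id="pup_demo")

iois = compute_iois(sim.bout)
n_silent, multiplicities = detect_silent_beats(iois, sim.true_period, tol=0.25)

skipped = sim.produced_mask.count(False)
print(f"grid beats: {len(sim.produced_mask)}, voiced: {sim.bout.n_events}, "
      f"skipped in ground truth: {skipped}")
print(f"IOIs (s):       {[round(x, 3) for x in iois.iois]}")
print(f"multiplicities: {multiplicities}  (2 = one silent beat inside)")
print(f"silent beats detected: {n_silent}")
print("A multiplicity of m means the interval spans m template periods,")
print("so m - 1 predicted barks failed to occur.")
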