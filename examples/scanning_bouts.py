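"""Detect scanning bouts in a jittered learning walk.

A scanning bout is on-the-spot rotation with at least two held head
directions.  The generator inserts three bouts and adds digitization-like
noise (0.05 cm positional, 3 deg orientation per frame); the detector
should still recover all three.
"""

import antwalks as aw
from antwalks.scanning import bout_table

traj, truth = aw.gen_learning_walk(aw.learning_params(
    seed=7, n_scan_bouts=3, noise_sd_pos=0.05, noise_sd_orient=3.0,
))
bouts = aw.detect_scanning_bouts(traj)

print(f"inserted {truth.n_scan_bouts} bouts, detected {len(bouts)}")
print(bout_table(bouts).round(2).to_string(index=False))
print("\ntruth intervals:")
for b in truth.bouts:
    print(f"  {b.start_t:6.2f} - {b.end_t:6.2f} s  ({b.n_fixations} fixations)")
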