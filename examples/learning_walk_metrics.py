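"""Generate one naive learning walk and summarize its path.

The walk is a loop from the nest and back, with two on-the-spot scanning
bouts spliced in.  The metrics below are the per-walk summary used to
compare learning walks with excavation trips: spatial extent (hull area,
maximum displacement), kinematics (duration, speed with stops excluded,
gaze angular velocity) and straightness indices.
"""

import antwalks as aw

traj, truth = aw.gen_learning_walk(aw.learning_params(seed=1, n_scan_bouts=2))
m = aw.compute_path_metrics(traj, n_scan_bouts=len(aw.detect_scanning_bouts(traj)))

print(f"frames: {traj.n_frames} at {traj.frame_rate:g} fps")
print(f"convex hull area:        {m.convex_hull_area:7.2f} cm^2")
print(f"max displacement:        {m.max_displacement:7.2f} cm   (truth {truth.max_excursion:.2f})")
print(f"duration:                {m.duration:7.2f} s")
print(f"mean speed (no stops):   {m.mean_speed:7.2f} cm/s (commanded {truth.commanded_speed:g})")
print(f"orient. angular velocity:{m.mean_orient_angular_velocity:7.1f} deg/s")
print(f"straightness:            {m.straightness:7.3f}  (loop returns to nest -> near 0)")
print(f"sinuosity:               {m.sinuosity:7.3f}")
print(f"E_max:                   {m.emax:7.1f}  (beta/(1-beta); high = locally straight)")
print(f"scanning bouts detected: {m.n_scan_bouts}  (inserted {truth.n_scan_bouts})")
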