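"""Docking-pose distance histogram with a bimodal approach geometry.

Simulates 2000 poses whose site distances mix two Gaussian modes (9 and
12.5 Å) and bins them at 0.5 Å — the standard view of whether a substrate
reaches electron-transfer distance of a catalytic metal.
"""

import numpy as np

import loopstates as ls

poses = ls.simulate_pose_set(2000, [(9.0, 0.5, 0.5), (12.5, 0.5, 0.5)],
                             site=np.zeros(3), seed=8)
d = ls.pose_site_distances(poses, "site", metric="min-atom")
hist = ls.distance_histogram(d, bin_width=0.5, bin_range=(2.0, 20.0),
                             scores=poses.scores())

frame = hist.to_frame()
busy = frame.sort_values("count", ascending=False).head(4).sort_values("bin_lo")
print("most populated distance bins:")
for row in busy.itertuples(index=False):
    print(f"  [{row.bin_lo:4.1f}, {row.bin_hi:4.1f}) Å : {row.count:4d} poses, "
          f"best score {row.score_min:6.2f} kcal/mol")
print(f"poses outside [2, 20] Å: {hist.overflow}")
# Two clusters of populated bins around 9 and 12.5 Å reproduce the planted
# bimodal approach geometry; lower (more negative) scores sit at shorter range.
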