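"""Angular coordination statistics and the bivariate density peak.

Computes, for the two calibrated scenarios, the latter-half (48-54 h)
axis-rotation / turning / accordance angles, the bivariate kernel
density (bandwidth 20 deg) and its peak, and the +/-15-degree accordance
rate — the statistics that separate tightly coordinated from weakly
coordinated migration.
"""

from shapepath import pathstats as ps
from shapepath import pipeline as pl
from shapepath import synthgen as sg
from shapepath import tracking as tk

for factory, label in ((sg.hc_like, "HC-like"), (sg.reln_del_like, "RELN-del-like")):
    scen = factory(n_cells=33, rng_seed=6)
    gt = sg.ground_truth_frame(sg.simulate_tracks(scen))
    trajs = tk.trajectories_from_positions(gt)
    shapes = pl.shapes_from_truth(gt)
    records = pl.angle_records_for_group(trajs, shapes)
    valid = [r for r in records if r.valid]
    surf = ps.bivariate_density(records, bandwidth_deg=20.0)
    print(f"{label}: n = {len(valid)} latter-half records")
    print(f"  accordance rate (|angle| < 15 deg): {100 * ps.accordance_rate(records):.1f} %")
    print(f"  KDE peak density: {surf.peak():.3e} per degree^2")
    print(f"  density integral: {surf.integral():.4f} (should be 1)")

print("\nHigher peaks and rates mean rotation and movement cling to the")
print("projected path; the weakly coupled scenario sits visibly lower.")
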