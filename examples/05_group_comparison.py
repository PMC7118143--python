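"""Full two-group pipeline with shape t tests and resampling tests.

Runs simulate -> track -> segment -> angles -> compare for the two
calibrated scenarios and prints the comparison report: per-metric t
tests (Student or Welch, chosen by an F test) and the two resampling
tests (peak density, 10,000 trials by default here reduced; accordance,
1,000 trials).
"""

import dataclasses
import tempfile

from shapepath import pipeline as pl
from shapepath import synthgen as sg

cfg = pl.PipelineConfig(
    out_dir=tempfile.mkdtemp(prefix="shapepath_"),
    rng_seed=12,
    scenario_a=sg.hc_like(n_cells=20),
    scenario_b=sg.reln_del_like(n_cells=20),
    peak_trials=1000,       # 10,000 is the full-analysis default
    accordance_trials=1000,
)
manifest = pl.run_pipeline(cfg)
print(f"pipeline wrote {len(manifest['files'])} files to {cfg.out_dir}\n")

import json
import os

report = json.load(open(os.path.join(cfg.out_dir, "compare_report.json")))
for g, s in report["groups"].items():
    print(
        f"group {g}: n={s['n_records']}, accordance {100 * s['accordance_rate']:.1f} %, "
        f"peak {s['peak_density_per_deg2']:.2e} /deg^2, excluded {s['exclusions']['formatted']}"
    )
print("\nshape metric tests (group A vs B):")
for m in report["shape_metric_tests"]:
    print(
        f"  {m['metric']:13s} {m['a']['mean']:6.2f} vs {m['b']['mean']:6.2f}  "
        f"{m['test_variant']:7s} t={m['t_statistic']:7.2f}  p={m['p_value']:.2e}"
    )
pk = report["peak_density_resample_test"]
print(
    f"\npeak-density resampling: {pk['n_extreme']} of {pk['n_trials']} trials at or "
    f"beyond the comparison peak -> p = {pk['p_value']:.4f} ({pk['direction']})"
)
ac = report["accordance_resample_test_forward"]
print(
    f"accordance resampling:   {ac['n_extreme']} of {ac['n_trials']} trials -> "
    f"p = {ac['p_value']:.4f} ({ac['direction']})"
)
print("\nSmall p values say the weakly coupled group's coordination level")
print("is essentially never reached by resamples of the tightly coupled one.")
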