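# shapepath

Quantitative analysis of **cell-body shape and directional-movement
coordination** in time-lapse imaging of migrating cells, built for the
sparse-migration assay in which labelled neurons crawl outward from a
plated aggregate (neurosphere) and are followed for hours at 15-minute
intervals through paired phase-contrast and nuclear-fluorescence frames.

The scientific question the package addresses: *does a cell's body
orientation predict and stabilise its direction of movement?* In healthy
dopaminergic neurons the cell-body major axis stays aligned with the
migration direction; neurons carrying a *RELN* deletion lose this
coordination, wander off their expected course, and have smaller, more
elongated cell bodies. `shapepath` turns that comparison into a tested,
reproducible pipeline.

## What it computes

**Step 1 — shape.** For each tracked cell and frame, the cell body is
segmented from the phase-contrast crop (Sobel edges → morphological
closing → nucleus-guided object selection → solidity QC at 0.7) and
profiled as the ellipse with the same normalized second central moments:
area *A*, full axis lengths *a* ≥ *b* (4·√eigenvalue of the moment
matrix), and eccentricity

> e = √(1 − (b/a)²) ∈ [0, 1)

(0 = circle, → 1 = line segment). Groups are compared per metric with
unpaired two-tailed *t* tests, Student's or Welch's chosen by an F test
of variance equality.

**Step 2 — coordination.** Nuclei detected in the fluorescence channel
are linked into trajectories, positions smoothed with a five-point
moving average, and movement vectors taken as forward differences. Each
cell's **projected path** is the robust line (IRLS, Tukey bisquare,
c = 4.685) fitted to its first-half (42–47.75 h) positions, oriented
along the net displacement. On the latter half (48–54 h) three angles
are measured per frame:

| angle | definition | range |
|---|---|---|
| axis rotation θ_rot | major-axis orientation − path heading | [−90°, 90°) |
| turning θ_turn | movement heading − path heading | (−180°, 180°] |
| accordance θ_acc | movement heading − axis orientation | [−90°, 90°) |

The joint (θ_rot, θ_turn) distribution is summarised by a bivariate
Gaussian kernel density (bandwidth 20° per dimension, 1° grid,
renormalised to integrate to 1); its maximum is the **peak probability
density** in per-degree². The **accordance rate** is the fraction of
frames with |θ_acc| < 15°. Two resampling tests (10,000 / 1,000 trials,
p = (count+1)/(trials+1)) ask whether resamples of one group reach the
other group's peak density or accordance rate.

Because no imaging data for this assay is public, the package ships a
first-class **synthetic-data generator** (`shapepath.synthgen`) whose
scenarios are calibrated to the published group statistics — HC-like
(area 60.6 ± 16.8 px², e = 0.719 ± 0.143, 39.6% accordance inside ±15°,
KDE peak 8.9 × 10⁻⁵/deg²) versus RELN-del-like (44.1 ± 15.6 px²,
e = 0.767 ± 0.145, 32.8%, 5.2 × 10⁻⁵/deg²) — so every stage is testable
end to end with known ground truth.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/04_angles_and_density.py` simulates both calibrated
scenarios (33 cells, 49 frames each), runs tracking + path statistics,
and prints:

```
HC-like: n = 792 latter-half records
  accordance rate (|angle| < 15 deg): 37.6 %
  KDE peak density: 1.496e-04 per degree^2
  density integral: 1.0000 (should be 1)
RELN-del-like: n = 792 latter-half records
  accordance rate (|angle| < 15 deg): 31.6 %
  KDE peak density: 1.067e-04 per degree^2
  density integral: 1.0000 (should be 1)
```

The accordance rates recover the calibrated central masses (39.6% and
32.8%) to within binomial noise at n ≈ 790. The peak densities are
higher than the angle-pair calibration targets because the five-point
smoothing attenuates frame-to-frame turning noise in the full track
route (see `docs/methods.md`); `examples/05_group_comparison.py` runs
the complete two-group pipeline and prints the t tests and both
resampling tests (`0 of 1000 trials → p = 0.0010`).

A thin CLI mirrors the stages:

```bash
shapepath simulate --scenario hc --seed 1 --out simdir --render
shapepath track --positions simdir/ground_truth.csv --out tracks.csv
shapepath run-all --seed 1 --out outdir
```

## Layout

- `src/shapepath/synthgen.py` — calibrated scenario generator + renderer
- `src/shapepath/cellbody.py` — segmentation and ellipse profiling
- `src/shapepath/tracking.py` — nucleus detection, linking, smoothing
- `src/shapepath/pathstats.py` — projected path, angles, KDE, rates
- `src/shapepath/grouptests.py` — t tests and resampling tests
- `src/shapepath/pipeline.py` — orchestration, manifests, exclusion report
- `docs/methods.md` — model assumptions, parameter choices, limitations
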