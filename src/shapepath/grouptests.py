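"""Group-level comparisons: shape-metric t tests and resampling tests.

Two kinds of comparison are provided.

* Per-metric two-sample t tests (unpaired, two-tailed) of the four
  cell-body shape metrics — area, minor axis, major axis, eccentricity —
  choosing Student's or Welch's variant by an F test of variance equality
  at the 5 percent level.

* Two bespoke resampling tests of the angular-coordination statistics:
  one asks whether resamples drawn from the seed group's (rotation,
  turning) pairs reach the comparison group's KDE peak density; the other
  asks whether resamples of the seed group's accordance angles reach the
  comparison group's central +/-15-degree rate.  Both report the raw count
  of at-or-beyond trials together with the add-one-corrected p value
  (count + 1) / (trials + 1), so a p of exactly zero is never claimed.

With the default data-adaptive direction the reported p value is
one-sided in the direction of the observed difference; see
docs/methods.md for the calibration caveats that follow from that and
from seed-sample noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pathstats import DEFAULT_BANDWIDTH_DEG, DEFAULT_HALF_WIDTH_DEG, _gauss_kernel_matrix
from .pathstats import ROTATION_GRID, TURNING_GRID, kde_surface

__all__ = [
    "GroupSummary",
    "MetricComparison",
    "ResampleResult",
    "compare_shape_metrics",
    "peak_density_resample_test",
    "accordance_resample_test",
]

SHAPE_METRICS = ("area_px", "minor_px", "major_px", "eccentricity")


@dataclass
class GroupSummary:
    group: str
    metric: str
    n_frames: int
    mean: float
    sd: float


@dataclass
class MetricComparison:
    metric: str
    a: GroupSummary
    b: GroupSummary
    t_statistic: float
    p_value: float
    test_variant: str  # "Student" | "Welch"
    variance_p: float


def _retained(df):
    if "excluded" in df.columns:
        return df[~df["excluded"].astype(bool)]
    return df


def compare_shape_metrics(
    group_a,
    group_b,
    labels=("A", "B"),
    metrics=SHAPE_METRICS,
    variance_alpha: float = 0.05,
) -> list:
    """Two-sample t tests of the shape metrics, Student vs Welch by F test.

    ``group_a`` / ``group_b`` are per-frame shape tables (DataFrames);
    excluded frames are dropped first.  For each metric the F test of
    variance equality (two-sided, alpha 0.05) selects the pooled-variance
    Student test when variances look equal and Welch's test otherwise.
    """
    da, db = _retained(group_a), _retained(group_b)
    if len(da) < 2 or len(db) < 2:
        raise ValueError("each group needs >= 2 retained fits")
    out = []
    for m in metrics:
        xa = da[m].to_numpy(dtype=float)
        xb = db[m].to_numpy(dtype=float)
        va, vb = xa.var(ddof=1), xb.var(ddof=1)
        # variance at rounding-noise level counts as constant data
        tiny_a = va <= 1e-24 * (1.0 + xa.mean() ** 2)
        tiny_b = vb <= 1e-24 * (1.0 + xb.mean() ** 2)
        if tiny_a and tiny_b:
            p_var = 1.0
        else:
            F = va / vb if vb > 0 else np.inf
            dist = stats.f(len(xa) - 1, len(xb) - 1)
            p_var = 2.0 * min(dist.cdf(F), dist.sf(F))
            p_var = min(p_var, 1.0)
        equal = p_var >= variance_alpha
        if tiny_a and tiny_b:  # degenerate: both groups constant
            same = np.isclose(xa.mean(), xb.mean(), rtol=1e-12, atol=1e-12)
            t, p = (0.0, 1.0) if same else (np.inf * np.sign(xa.mean() - xb.mean()), 0.0)
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=equal)
        out.append(
            MetricComparison(
                metric=m,
                a=GroupSummary(labels[0], m, len(xa), float(xa.mean()), float(xa.std(ddof=1))),
                b=GroupSummary(labels[1], m, len(xb), float(xb.mean()), float(xb.std(ddof=1))),
                t_statistic=float(t),
                p_value=float(p),
                test_variant="Student" if equal else "Welch",
                variance_p=float(p_var),
            )
        )
    return out


@dataclass
class ResampleResult:
    """Outcome of a resampling test.

    ``n_extreme`` counts trials at or beyond the comparison value in the
    tested direction; ``p_value`` carries the add-one correction
    (n_extreme + 1) / (n_trials + 1) so it is never exactly zero.
    """

    observed_seed_stat: float
    observed_comparison_stat: float
    n_trials: int
    n_extreme: int
    p_value: float
    direction: str  # "le" (trials <= comparison) or "ge"
    rng_seed: int
    resample_size: int

    def __post_init__(self):
        assert 0 <= self.n_extreme <= self.n_trials
        assert 0.0 < self.p_value <= 1.0


def _resolve_direction(direction, seed_stat, comparison_stat) -> str:
    if direction in ("le", "ge"):
        return direction
    if direction != "auto":
        raise ValueError("direction must be 'auto', 'le' or 'ge'")
    return "le" if seed_stat >= comparison_stat else "ge"


def peak_density_resample_test(
    seed_rotation_deg,
    seed_turning_deg,
    comparison_peak: float,
    n_trials: int = 10_000,
    resample_size: int | None = None,
    rng_seed: int = 0,
    bandwidth_deg: float = DEFAULT_BANDWIDTH_DEG,
    direction: str = "auto",
) -> ResampleResult:
    """Does the seed group's resampled KDE peak reach the comparison peak?

    Each trial resamples ``resample_size`` (rotation, turning) pairs with
    replacement from the seed records, recomputes the bivariate KDE with
    the pipeline's own settings and takes its peak.  Resampling with
    replacement is realised through multinomial count vectors, which gives
    exactly the same trial distribution as index resampling but lets each
    trial's density be a single weighted kernel sum.

    ``resample_size`` defaults to the seed size; passing the comparison
    group's record count makes the null distribution reflect that group's
    sampling noise.
    """
    rot = np.asarray(seed_rotation_deg, dtype=float).ravel()
    turn = np.asarray(seed_turning_deg, dtype=float).ravel()
    if rot.size != turn.size:
        raise ValueError("seed rotation/turning arrays differ in length")
    if comparison_peak < 0:
        raise ValueError("comparison_peak must be >= 0")
    m = rot.size
    n = m if resample_size is None else int(resample_size)
    if n < 10:
        raise ValueError("resample_size must be >= 10")
    observed = kde_surface(rot, turn, bandwidth_deg).peak()
    dirn = _resolve_direction(direction, observed, comparison_peak)

    A = _gauss_kernel_matrix(ROTATION_GRID, rot, bandwidth_deg)
    B = _gauss_kernel_matrix(TURNING_GRID, turn, bandwidth_deg)
    rng = np.random.default_rng(rng_seed)
    peaks = np.empty(n_trials)
    # Two exact samplers of the same trial distribution; pick the cheaper:
    # weighting the seed kernels by multinomial counts costs O(m) per trial,
    # gathering kernel columns for literal index draws costs O(n).
    use_counts = m <= 4 * n
    for i in range(n_trials):
        if use_counts:
            c = rng.multinomial(n, np.full(m, 1.0 / m))
            dens = (A * c) @ B.T / n
        else:
            idx = rng.integers(0, m, size=n)
            dens = A[:, idx] @ B[:, idx].T / n
        inner = np.trapezoid(dens, TURNING_GRID, axis=1)
        total = np.trapezoid(inner, ROTATION_GRID)
        peaks[i] = dens.max() / total
    n_extreme = int(np.sum(peaks <= comparison_peak) if dirn == "le" else np.sum(peaks >= comparison_peak))
    return ResampleResult(
        observed_seed_stat=float(observed),
        observed_comparison_stat=float(comparison_peak),
        n_trials=int(n_trials),
        n_extreme=n_extreme,
        p_value=(n_extreme + 1) / (n_trials + 1),
        direction=dirn,
        rng_seed=int(rng_seed),
        resample_size=n,
    )


def accordance_resample_test(
    seed_accordance_deg,
    comparison_rate: float,
    n_trials: int = 1000,
    resample_size: int | None = None,
    rng_seed: int = 0,
    half_width_deg: float = DEFAULT_HALF_WIDTH_DEG,
    direction: str = "auto",
) -> ResampleResult:
    """Does the seed group's resampled +/-15-degree rate reach the
    comparison group's rate?

    Each trial resamples ``resample_size`` accordance angles with
    replacement from the seed population and recomputes the central-band
    proportion.  The mirrored test (comparison group as seed) is a
    separate call.
    """
    ang = np.asarray(seed_accordance_deg, dtype=float).ravel()
    ang = ang[np.isfinite(ang)]
    if ang.size == 0:
        raise ValueError("seed angles empty")
    m = ang.size
    n = m if resample_size is None else int(resample_size)
    if n < 10:
        raise ValueError("resample_size must be >= 10")
    inside = (np.abs(ang) < half_width_deg).astype(float)
    observed = float(inside.mean())
    dirn = _resolve_direction(direction, observed, comparison_rate)
    rng = np.random.default_rng(rng_seed)
    rates = np.empty(n_trials)
    chunk = max(1, min(n_trials, int(2e7 // max(n, 1))))
    done = 0
    while done < n_trials:
        k = min(chunk, n_trials - done)
        idx = rng.integers(0, m, size=(k, n))
        rates[done : done + k] = inside[idx].mean(axis=1)
        done += k
    n_extreme = int(np.sum(rates <= comparison_rate) if dirn == "le" else np.sum(rates >= comparison_rate))
    return ResampleResult(
        observed_seed_stat=observed,
        observed_comparison_stat=float(comparison_rate),
        n_trials=int(n_trials),
        n_extreme=n_extreme,
        p_value=(n_extreme + 1) / (n_trials + 1),
        direction=dirn,
        rng_seed=int(rng_seed),
        resample_size=n,
    )
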