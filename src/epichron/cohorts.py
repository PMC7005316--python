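"""Reference synthetic cohorts used to benchmark the pipeline.

These specs define the package's standard validation conditions: a
breakpoint-recovery cohort with rapid epigenomic transitions planted at ages
40 and 66, a stationary (null) cohort for false-positive control, and a
QC cohort rich in benchmark-peak candidates.
"""

from __future__ import annotations

from .synthetic import SyntheticSpec, TrendShape, make_shape

#: planted breakpoint ages of the recovery benchmark, by cluster label
BREAKPOINT_TRUTH = {"down_0": 40, "up_early_1": 40, "down_2": 66, "up_late_3": 66}


def breakpoint_benchmark_spec(seed: int) -> SyntheticSpec:
    """Two sexes x 60 subjects over ages 22-90 with known breakpoints.

    Four trending clusters, one rapid-change ramp each (5 years wide, 1 log2
    unit total, about 2 within-age SD at this depth and dispersion), centered
    at 40 or 66.  Up- and down-going clusters are paired at each breakpoint
    age so library composition stays stable and normalization cannot imprint
    one cluster's transition onto the others.
    """
    ramps = {40: (37.5, 42.5), 66: (63.5, 68.5)}
    rate = 0.2  # log2 units per year inside the ramp
    return SyntheticSpec(
        n_per_sex=60, age_range=(22, 90), seed=seed, nb_dispersion=0.08,
        clusters=(
            TrendShape("down", 100, baseline=6.0, breakpoints=ramps[40],
                       slopes=(0.0, -rate, 0.0)),
            TrendShape("up_early", 100, baseline=6.0, breakpoints=ramps[40],
                       slopes=(0.0, rate, 0.0)),
            TrendShape("down", 100, baseline=6.0, breakpoints=ramps[66],
                       slopes=(0.0, -rate, 0.0)),
            TrendShape("up_late", 100, baseline=6.0, breakpoints=ramps[66],
                       slopes=(0.0, rate, 0.0)),
            make_shape("null", 200, baseline=6.0),
        ))


def stationary_spec(seed: int, n_features: int = 200) -> SyntheticSpec:
    """Null cohort: same design as the recovery benchmark, no trends."""
    return SyntheticSpec(
        n_per_sex=60, age_range=(22, 90), seed=seed, nb_dispersion=0.08,
        clusters=(make_shape("null", n_features, baseline=6.0),))


def qc_benchmark_spec(seed: int) -> SyntheticSpec:
    """Cohort with a large pool of strong invariant (benchmark) peaks."""
    return SyntheticSpec(
        n_per_sex=40, age_range=(22, 90), seed=seed, nb_dispersion=0.1,
        clusters=(
            make_shape("down", 150, effect=2.0, age_range=(22, 90), baseline=6.0),
            make_shape("up_late", 150, effect=2.0, age_range=(22, 90),
                       breakpoints=(60,), baseline=6.0),
            make_shape("null", 200, baseline=6.0),
            make_shape("null", 300, baseline=8.5),
        ))
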