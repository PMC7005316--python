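"""Synthetic cohort generator with known aging trends and breakpoints.

Emulates an age-structured genomic study: negative-binomial counts for a
feature x sample matrix over two sexes spanning the adult age range, with
planted trend clusters (closing with age, opening with age, sex-opposed),
piecewise-linear breakpoints, per-batch log shifts, library-size variation
and a fraction of stationary (null) features.  Every downstream stage of the
pipeline can be tested against the returned ground-truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

KINDS = ("down", "up_early", "up_late", "sex_opposed", "null")

FEMALE = "F"
MALE = "M"


@dataclass(frozen=True)
class TrendShape:
    """A piecewise-linear expected log2-abundance trajectory.

    ``slopes`` (log2 units per year) apply to the segments delimited by
    ``breakpoints`` (ages, strictly increasing), so ``len(slopes) ==
    len(breakpoints) + 1`` and the segments tile the age range without gaps.
    ``sex_opposed`` shapes flip the sign of every slope for males.
    """

    kind: str
    n_features: int
    baseline: float = 5.0
    breakpoints: tuple = ()
    slopes: tuple = (0.0,)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; valid: {KINDS}")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if len(self.slopes) != len(self.breakpoints) + 1:
            raise ValueError("need exactly one slope per segment "
                             "(len(slopes) == len(breakpoints) + 1)")
        if list(self.breakpoints) != sorted(self.breakpoints):
            raise ValueError("breakpoints must be increasing")
        if self.kind == "null" and any(s != 0 for s in self.slopes):
            raise ValueError("null shapes must have zero slopes")


def make_shape(kind, n_features, effect=1.0, age_range=(22, 93),
               breakpoints=(), slope_changes=(), baseline=5.0) -> TrendShape:
    """Build a :class:`TrendShape` from an effect size in log2 units.

    ``effect`` is the total log2 change across the age range attributable to
    the base slope (negative trends get a negative sign from ``kind``).
    ``slope_changes`` are added cumulatively to the running slope at each
    breakpoint.  ``up_early``/``up_late`` without explicit slope changes put
    the whole rise before / after the (single) breakpoint.
    """
    lo, hi = age_range
    span = hi - lo
    breakpoints = tuple(breakpoints)
    if kind == "null":
        return TrendShape("null", n_features, baseline, breakpoints,
                          (0.0,) * (len(breakpoints) + 1))
    if breakpoints and not slope_changes and kind in ("up_early", "up_late"):
        b = breakpoints[0] if kind == "up_early" else breakpoints[-1]
        if kind == "up_early":
            rise = effect / (b - lo)
            slopes = (rise,) + (0.0,) * len(breakpoints)
        else:
            rise = effect / (hi - b)
            slopes = (0.0,) * len(breakpoints) + (rise,)
        return TrendShape(kind, n_features, baseline, breakpoints, slopes)
    sign = -1.0 if kind == "down" else 1.0
    s0 = sign * effect / span
    slopes = [s0]
    for change in slope_changes:
        slopes.append(slopes[-1] + change)
    if len(slopes) != len(breakpoints) + 1:
        raise ValueError("slope_changes must have one entry per breakpoint")
    return TrendShape(kind, n_features, baseline, breakpoints, tuple(slopes))


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic cohort.

    ``batches`` maps batch label -> additive log2 shift applied to every
    feature of the samples in that batch.  ``nb_dispersion`` is the
    negative-binomial dispersion alpha (variance = mu + alpha * mu^2).
    """

    n_per_sex: int = 40
    age_range: tuple = (22, 93)
    clusters: tuple = ()
    nb_dispersion: float = 0.1
    libsize_log_mean: float = 0.0
    libsize_log_sd: float = 0.25
    batches: dict = field(default_factory=lambda: {"b1": 0.0})
    n_bad_samples: int = 0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range min must be < max")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not self.clusters:
            raise ValueError("at least one TrendShape cluster is required")

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["clusters"] = [asdict(c) for c in self.clusters]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["clusters"] = tuple(
            TrendShape(kind=c["kind"], n_features=c["n_features"],
                       baseline=c["baseline"],
                       breakpoints=tuple(c["breakpoints"]),
                       slopes=tuple(c["slopes"]))
            for c in doc["clusters"])
        doc["age_range"] = tuple(doc["age_range"])
        return cls(**doc)


def trend_function(shape: TrendShape, age, sex=FEMALE, age_range=(22, 93)) -> float:
    """Expected log2 abundance at ``age`` under ``shape``.

    Continuous piecewise-linear: the value accumulates each segment's slope
    over the part of [age_range[0], age] that the segment covers.
    """
    lo, hi = age_range
    age = float(age)
    if age < lo or age > hi:
        raise ValueError(f"age {age} outside range [{lo}, {hi}]")
    anchors = [lo, *shape.breakpoints, hi]
    value = shape.baseline
    for seg, slope in enumerate(shape.slopes):
        left, right = anchors[seg], anchors[seg + 1]
        if age <= left:
            break
        value += slope * (min(age, right) - left)
    if shape.kind == "sex_opposed" and sex == MALE:
        value = 2 * shape.baseline - value
    return value


def _expected_log2(spec: SyntheticSpec, shapes_per_feature, ages, sexes) -> np.ndarray:
    """Matrix of expected log2 abundances (features x samples)."""
    out = np.empty((len(shapes_per_feature), len(ages)))
    for i, shape in enumerate(shapes_per_feature):
        for j, (a, s) in enumerate(zip(ages, sexes)):
            out[i, j] = trend_function(shape, a, s, spec.age_range)
    return out


def simulate_cohort(spec: SyntheticSpec):
    """Draw a synthetic cohort.

    Returns ``(counts, samples, truth)``:

    - ``counts``: integer DataFrame, features x samples, NB(mu, alpha) with
      mu = libsize_scale * 2^(trend(age, sex) + batch shift);
    - ``samples``: per-sample table (subject, age, sex, batch, lib_scale,
      libsize = realized total counts);
    - ``truth``: per-feature table (cluster label, kind, breakpoints,
      baseline) partitioning the features exactly.

    Identical spec (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range

    n = spec.n_per_sex
    ages = np.concatenate([rng.integers(lo, hi + 1, size=n),
                           rng.integers(lo, hi + 1, size=n)])
    sexes = np.array([FEMALE] * n + [MALE] * n)
    sample_ids = [f"S{i:03d}" for i in range(2 * n)]
    batch_labels = list(spec.batches)
    batch = np.array(batch_labels)[rng.integers(0, len(batch_labels), size=2 * n)]
    batch_shift = np.array([spec.batches[b] for b in batch])
    lib_scale = rng.lognormal(spec.libsize_log_mean, spec.libsize_log_sd, size=2 * n)

    shapes, rows = [], []
    idx = 0
    for c, shape in enumerate(spec.clusters):
        label = f"{shape.kind}_{c}"
        for _ in range(shape.n_features):
            shapes.append(shape)
            rows.append({
                "feature": f"peak{idx:05d}",
                "cluster": label,
                "kind": shape.kind,
                "breakpoints": ",".join(str(b) for b in shape.breakpoints),
                "baseline": shape.baseline,
            })
            idx += 1
    truth = pd.DataFrame(rows).set_index("feature")

    log2mu = _expected_log2(spec, shapes, ages, sexes)
    mu = lib_scale[None, :] * np.exp2(log2mu + batch_shift[None, :])
    alpha = spec.nb_dispersion
    counts = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu), size=mu.shape)
    counts = pd.DataFrame(counts, index=truth.index, columns=sample_ids)

    samples = pd.DataFrame({
        "subject": sample_ids,
        "age": ages,
        "sex": sexes,
        "batch": batch,
        "lib_scale": lib_scale,
        "libsize": counts.sum(axis=0).to_numpy(),
    }, index=pd.Index(sample_ids, name="sample"))

    if spec.n_bad_samples:
        counts, bad = inject_bad_samples(counts, spec.n_bad_samples,
                                         dropout_rate=0.3,
                                         rng=np.random.default_rng(spec.seed + 1))
        samples["planted_bad"] = samples.index.isin(bad)
        samples["libsize"] = counts.sum(axis=0).to_numpy()
    return counts, samples, truth


def inject_bad_samples(counts: pd.DataFrame, n_bad: int, dropout_rate: float,
                       rng=None):
    """Zero out a fraction of high-signal features in ``n_bad`` samples.

    High-signal features are those with above-median mean count; within a
    selected sample, a ``dropout_rate`` fraction of them is set to zero,
    mimicking libraries with consistently poor signal.  Returns the modified
    matrix and the list of corrupted sample ids.
    """
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    if n_bad >= counts.shape[1]:
        raise ValueError("n_bad must be smaller than the number of samples")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = counts.copy()
    if n_bad == 0 or dropout_rate == 0:
        return out, []
    mean = counts.mean(axis=1)
    high = counts.index[mean.to_numpy() > np.median(mean)]
    bad_cols = rng.choice(counts.shape[1], size=n_bad, replace=False)
    bad_ids = [counts.columns[j] for j in sorted(bad_cols)]
    for col in bad_ids:
        k = int(round(dropout_rate * len(high)))
        dropped = rng.choice(high, size=k, replace=False)
        out.loc[dropped, col] = 0
    return out, bad_ids
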