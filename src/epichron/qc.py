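"""Peak filtering, benchmark-peak discovery and sample quality flagging.

A *benchmark peak* is one expected to be called in essentially every
library: approximately invariant between the age groups (|logFC| in the
bottom quartile), strong (maximum normalized count in the top decile) and
called in at least 90% of samples.  Samples that miss calls for more than
7.5% of the benchmark set are flagged as poor quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import as_count_frame

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BenchmarkCriteria:
    logfc_quantile: float = 0.25
    maxct_quantile: float = 0.90
    call_fraction: float = 0.90
    sample_pass_fraction: float = 0.925

    def __post_init__(self):
        for name in ("logfc_quantile", "maxct_quantile", "call_fraction",
                     "sample_pass_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


def _raw_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("sample(s) with zero total count")
    return counts / libsize * 1e6


def _overlaps(peaks: pd.DataFrame, regions: pd.DataFrame) -> pd.Series:
    """Any >=1 bp overlap between 0-based half-open intervals."""
    hit = pd.Series(False, index=peaks.index)
    for chrom, sub in regions.groupby("chrom"):
        sel = peaks["chrom"] == chrom
        if not sel.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ps = peaks.loc[sel, "start"].to_numpy()[:, None]
        pe = peaks.loc[sel, "end"].to_numpy()[:, None]
        hit.loc[sel] = ((ps < ends[None, :]) & (pe > starts[None, :])).any(axis=1)
    return hit


def filter_peaks(counts, min_reads: int = 20, max_cpm: float = 500,
                 peaks: pd.DataFrame | None = None,
                 blacklist: pd.DataFrame | None = None) -> pd.Index:
    """Peak-level filters; returns the ids of the kept features.

    Keeps features whose maximum raw count strictly exceeds ``min_reads`` in
    at least one sample, whose maximum counts-per-million never exceeds
    ``max_cpm`` (potential artifact regions), and which do not overlap any
    blacklisted region (requires ``peaks`` coordinates).
    """
    counts = as_count_frame(counts)
    keep = (counts.max(axis=1) > min_reads) & (_raw_cpm(counts).max(axis=1) <= max_cpm)
    if blacklist is not None:
        if peaks is None:
            raise ValueError("blacklist given but no peak coordinates supplied")
        keep &= ~_overlaps(peaks.loc[counts.index], blacklist)
    return counts.index[keep]


def derive_calls(counts: pd.DataFrame) -> pd.DataFrame:
    """Fallback call matrix when external peak calls are unavailable: called = count > 0."""
    log.info("deriving call matrix as count > 0 (no external calls supplied)")
    return counts > 0


def discover_benchmark_peaks(counts, calls: pd.DataFrame, old: pd.Series,
                             criteria: BenchmarkCriteria = BenchmarkCriteria()) -> pd.Index:
    """Select relatively invariant, strong, ubiquitously called peaks.

    ``old`` is a boolean per-sample series (True = older group).  All three
    criteria must hold; quantile boundaries are inclusive.
    """
    counts = as_count_frame(counts)
    old = pd.Series(old).reindex(counts.columns).astype(bool)
    if old.all() or (~old).all():
        raise ValueError("both young and old groups must be non-empty")
    norm = _raw_cpm(counts)
    mean_old = norm.loc[:, old].mean(axis=1)
    mean_young = norm.loc[:, ~old].mean(axis=1)
    if mean_old.sum() == 0 or mean_young.sum() == 0:
        raise ValueError("a group has zero total counts")
    logfc = np.log2((mean_old + 0.5) / (mean_young + 0.5)).abs()
    maxct = norm.max(axis=1)
    call_rate = calls.loc[counts.index].mean(axis=1)

    invariant = logfc <= logfc.quantile(criteria.logfc_quantile)
    strong = maxct >= maxct.quantile(criteria.maxct_quantile)
    ubiquitous = call_rate >= criteria.call_fraction
    return counts.index[invariant & strong & ubiquitous]


def flag_samples(calls: pd.DataFrame, benchmark: pd.Index,
                 criteria: BenchmarkCriteria = BenchmarkCriteria()) -> pd.DataFrame:
    """Per-sample benchmark call rate and pass/fail (boundary inclusive)."""
    if len(benchmark) == 0:
        raise ValueError("benchmark set is empty")
    rate = calls.loc[benchmark].mean(axis=0)
    return pd.DataFrame({
        "benchmark_call_rate": rate,
        "qc_pass": rate >= criteria.sample_pass_fraction,
    })
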