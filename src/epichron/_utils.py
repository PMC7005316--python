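"""Shared numerical helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR).

    Accepts any 1-d sequence; NaNs are propagated and excluded from the
    adjustment of the remaining values.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    result = np.empty(m)
    result[order] = np.clip(adj, 0.0, 1.0)
    out[ok] = result
    return out


def child_seed(seed: int, index: int) -> int:
    """Derive a per-stage child seed from a global seed.

    Counter-based: independent stages get independent streams while any
    stage can be rerun in isolation from the same global seed.
    """
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, int(index)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def as_count_frame(counts) -> pd.DataFrame:
    """Validate and coerce a features x samples count matrix."""
    df = pd.DataFrame(counts)
    if df.size == 0:
        raise ValueError("empty count matrix")
    vals = df.to_numpy()
    if np.any(vals < 0):
        raise ValueError("counts must be nonnegative")
    return df
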