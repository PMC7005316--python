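"""Multi-scale breakpoint detection in age-structured multivariate profiles.

For each temporal cluster, adjusted values are reduced to a few principal
components; at every candidate age t the subjects in [t-w, t) and (t, t+w]
are compared by one-way MANOVA (Pillai trace), producing a -log10 p curve
per window span w.  Each curve is LOESS-smoothed under a grid of bandwidths,
the smoothed p-values are combined per age by Fisher's method, the combined
curve is smoothed again and its local maxima are screened by a chi-square
significance test and a prominence rule.  Candidate maxima from all window
spans are grouped into breakpoint intervals by a 1-D Gaussian mixture with
BIC-selected component count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

log = logging.getLogger(__name__)


def loess_smooth(y, x, frac: float, degree: int = 2) -> np.ndarray:
    """Local polynomial (LOESS) smooth with tricube weights.

    Local quadratic by default: degree-2 fits track curvature at the curve
    boundaries, where local-linear smoothers flatten peaks — important here
    because early breakpoints sit near the first tested ages.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    k = max(int(np.ceil(frac * n)), degree + 1)
    k = min(k, n)
    out = np.empty(n)
    powers = np.arange(degree + 1)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        wts = (1 - (d[idx] / dmax) ** 3) ** 3
        wts = np.clip(wts, 0, None)
        X = (x[idx, None] - x[i]) ** powers[None, :]
        sw = np.sqrt(wts)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y[idx] * sw, rcond=None)
        out[i] = beta[0]
    return out

LOGINVP_CAP = 300.0  # numerical floor for back-transformed p-values


@dataclass(frozen=True)
class ScanConfig:
    windows: tuple = tuple(range(10, 21))
    bandwidths: tuple = tuple(np.round(np.arange(0.25, 0.751, 0.05), 2))
    n_pcs: int = 3
    prominence_fraction: float = 0.25
    alpha: float = 0.01
    max_components: int = 4
    seed: int = 0

    def __post_init__(self):
        if any(w <= 0 for w in self.windows):
            raise ValueError("window spans must be > 0")
        if any(not 0 < b <= 1 for b in self.bandwidths):
            raise ValueError("bandwidths must be in (0, 1]")
        if self.n_pcs < 1:
            raise ValueError("need at least one PC")


# ---------------------------------------------------------------------------
# Dimensionality reduction
# ---------------------------------------------------------------------------

def reduce_cluster(adjusted: pd.DataFrame, n_pcs: int = 3) -> pd.DataFrame:
    """Subject x n_pcs PCA score matrix for one cluster's adjusted values.

    ``adjusted`` is features x samples restricted to the cluster.  If the
    matrix rank is below ``n_pcs`` fewer components are returned (warned).
    """
    X = adjusted.to_numpy(dtype=float).T
    if X.shape[0] < n_pcs + 1:
        raise ValueError("need at least n_pcs + 1 subjects")
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max() * max(Xc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if rank < n_pcs:
        log.warning("cluster rank %d < %d requested PCs; returning %d", rank, n_pcs, rank)
    k = min(n_pcs, rank)
    scores = u[:, :k] * s[:k]
    return pd.DataFrame(scores, index=adjusted.columns,
                        columns=[f"PC{i + 1}" for i in range(k)])


# ---------------------------------------------------------------------------
# Windowed MANOVA
# ---------------------------------------------------------------------------

def pillai_trace(groups) -> tuple[float, float]:
    """One-way MANOVA Pillai trace and its F-approximation p-value.

    ``groups`` is a sequence of (n_i x p) arrays.  V = tr(H (H + E)^-1) with
    H/E the between/within sums-of-squares-and-products matrices; for two
    groups the F statistic is exact.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    p = groups[0].shape[1]
    N = sum(g.shape[0] for g in groups)
    g = len(groups)
    grand = np.vstack(groups).mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for X in groups:
        m = X.mean(axis=0)
        d = (m - grand)[:, None]
        H += X.shape[0] * (d @ d.T)
        R = X - m
        E += R.T @ R
    V = float(np.trace(H @ np.linalg.pinv(H + E)))
    s = min(p, g - 1)
    m_ = (abs(p - (g - 1)) - 1) / 2
    n_ = (N - g - p - 1) / 2
    df1 = s * (2 * m_ + s + 1)
    df2 = s * (2 * n_ + s + 1)
    if df2 <= 0 or V >= s:
        return V, np.nan
    F = (df2 / df1) * (V / s) / (1 - V / s)
    return V, float(stats.f.sf(F, df1, df2))


def window_test(scores: pd.DataFrame, ages, t: float, w: float,
                min_per_side: int | None = None):
    """MANOVA p-value comparing subjects in [t-w, t) against (t, t+w].

    Subjects exactly at age t belong to neither side.  Returns None (the age
    is skipped) when either window holds fewer than ``min_per_side``
    subjects (default: n_pcs + 2).
    """
    ages = np.asarray(ages, dtype=float)
    X = scores.to_numpy(dtype=float)
    if min_per_side is None:
        min_per_side = X.shape[1] + 2
    left = (ages >= t - w) & (ages < t)
    right = (ages > t) & (ages <= t + w)
    if left.sum() < min_per_side or right.sum() < min_per_side:
        return None
    _, p = pillai_trace([X[left], X[right]])
    return p


@dataclass
class BreakpointCurve:
    w: float
    table: pd.DataFrame  # columns: t, p, loginvp

    @property
    def t_min(self):
        return self.table["t"].min() if len(self.table) else np.nan

    @property
    def t_max(self):
        return self.table["t"].max() if len(self.table) else np.nan


def scan_offsets(ages, w: float) -> tuple[int, int]:
    """First and last tested ages for span ``w``: youngest + w, oldest - w."""
    ages = np.asarray(ages, dtype=float)
    return int(np.ceil(ages.min() + w)), int(np.floor(ages.max() - w))


def scan_ages(scores: pd.DataFrame, ages, w: float,
              min_per_side: int | None = None) -> BreakpointCurve:
    """-log10 p at every integer age from youngest + w to oldest - w."""
    ages = np.asarray(ages, dtype=float)
    t_lo, t_hi = scan_offsets(ages, w)
    if ages.max() - ages.min() <= 2 * w:
        log.warning("age span <= 2w for w=%s: empty curve", w)
        return BreakpointCurve(w, pd.DataFrame(columns=["t", "p", "loginvp"]))
    rows = []
    for t in range(t_lo, t_hi + 1):
        p = window_test(scores, ages, t, w, min_per_side)
        if p is None or not np.isfinite(p):
            log.debug("w=%s: skipping age %d (insufficient subjects)", w, t)
            continue
        rows.append({"t": t, "p": p, "loginvp": -np.log10(max(p, 10.0 ** -LOGINVP_CAP))})
    return BreakpointCurve(w, pd.DataFrame(rows, columns=["t", "p", "loginvp"]))


# ---------------------------------------------------------------------------
# LOESS smoothing, Fisher combination, extrema
# ---------------------------------------------------------------------------

def _extrema(y: np.ndarray):
    """Local maxima/minima indices by sign change of the first difference."""
    d = np.sign(np.diff(y))
    maxima, minima = [], []
    for i in range(1, len(y) - 1):
        before = d[:i][d[:i] != 0]
        after = d[i:][d[i:] != 0]
        if before.size == 0 or after.size == 0:
            continue
        if before[-1] > 0 and after[0] < 0:
            maxima.append(i)
        elif before[-1] < 0 and after[0] > 0:
            minima.append(i)
    return maxima, minima


def combine_and_smooth(curve: BreakpointCurve, bandwidths=None,
                       final_bandwidth: float | None = None) -> pd.DataFrame:
    """Multi-bandwidth LOESS + Fisher combination for one w-curve.

    Each bandwidth's LOESS smooth of the -log10 p curve is back-transformed
    to p (clipped into (0, 1]); at every tested age the per-bandwidth
    p-values are combined as X^2 = -2 sum ln p with df = 2 * n_bandwidths.
    The combined -log10 p curve is LOESS-smoothed once more (smallest grid
    bandwidth by default, so nearby breakpoints are not merged) for extremum
    detection.  Columns: t, combined_p, combined_loginvp, smooth, is_max,
    is_min.
    """
    if bandwidths is None:
        bandwidths = ScanConfig().bandwidths
    tab = curve.table
    if len(tab) < 5:
        raise ValueError("need >= 5 tested ages to smooth")
    t = tab["t"].to_numpy(dtype=float)
    y = tab["loginvp"].to_numpy(dtype=float)
    ps = []
    for bw in bandwidths:
        sm = loess_smooth(y, t, frac=bw)
        p = 10.0 ** (-np.clip(sm, 0.0, LOGINVP_CAP))
        clipped = np.clip(p, 10.0 ** -LOGINVP_CAP, 1.0)
        if np.any(p != clipped):
            log.info("w=%s bw=%s: smoothed p clipped into (0, 1]", curve.w, bw)
        ps.append(clipped)
    P = np.vstack(ps)
    x2 = -2.0 * np.log(P).sum(axis=0)
    df = 2 * len(bandwidths)
    combined_p = stats.chi2.sf(x2, df)
    combined = -np.log10(np.clip(combined_p, 10.0 ** -LOGINVP_CAP, 1.0))
    if final_bandwidth is None:
        final_bandwidth = float(np.min(bandwidths))
    smooth = loess_smooth(combined, t, frac=final_bandwidth)
    maxima, minima = _extrema(smooth)
    out = pd.DataFrame({
        "t": t, "combined_p": combined_p, "combined_loginvp": combined,
        "smooth": smooth,
    })
    out["is_max"] = False
    out["is_min"] = False
    out.loc[out.index[maxima], "is_max"] = True
    out.loc[out.index[minima], "is_min"] = True
    return out


def candidate_breakpoints(combined: pd.DataFrame,
                          config: ScanConfig = ScanConfig()) -> pd.DataFrame:
    """Screen local maxima of one combined curve.

    A maximum is a candidate when its Fisher-combined chi-square p-value is
    <= alpha and its prominence (smoothed -log10 p at the maximum minus at
    the nearest minimum; curve endpoints count as minima when no interior
    minimum exists) is at least ``prominence_fraction`` of the global
    maximum of the smoothed curve.
    """
    if combined.empty:
        return pd.DataFrame(columns=["t", "combined_p", "loginvp", "prominence"])
    smooth = combined["smooth"].to_numpy()
    t = combined["t"].to_numpy()
    global_max = smooth.max()
    max_idx = np.flatnonzero(combined["is_max"].to_numpy())
    min_idx = np.flatnonzero(combined["is_min"].to_numpy())
    rows = []
    for i in max_idx:
        if min_idx.size:
            j = min_idx[np.argmin(np.abs(t[min_idx] - t[i]))]
            floor = smooth[j]
        else:
            floor = min(smooth[0], smooth[-1])
        prom = smooth[i] - floor
        if combined["combined_p"].iloc[i] <= config.alpha and \
                prom >= config.prominence_fraction * global_max:
            rows.append({"t": t[i], "combined_p": combined["combined_p"].iloc[i],
                         "loginvp": smooth[i], "prominence": prom})
    return pd.DataFrame(rows, columns=["t", "combined_p", "loginvp", "prominence"])


# ---------------------------------------------------------------------------
# Grouping maxima across window spans
# ---------------------------------------------------------------------------

@dataclass
class BreakpointInterval:
    median_age: float
    age_min: float
    age_max: float
    combined_p: float
    member_ages: tuple
    member_windows: tuple


def group_breakpoints(candidates: pd.DataFrame,
                      config: ScanConfig = ScanConfig()) -> list:
    """Group per-window candidate maxima into breakpoint intervals.

    1-D Gaussian mixture over candidate ages with the component count (1 to
    ``max_components``) chosen by BIC.  Each interval reports the median and
    range of its member ages and the most significant member p-value.
    """
    if candidates.empty:
        return []
    ages = candidates["t"].to_numpy(dtype=float).reshape(-1, 1)
    n_distinct = np.unique(ages).size
    if len(candidates) == 1 or n_distinct == 1:
        labels = np.zeros(len(candidates), dtype=int)
    else:
        best_bic, best = np.inf, None
        for k in range(1, min(config.max_components, n_distinct) + 1):
            # variance floor of 1 year^2: ages are tested on an integer grid
            gm = GaussianMixture(n_components=k, random_state=config.seed,
                                 reg_covar=1.0, n_init=3)
            gm.fit(ages)
            bic = gm.bic(ages)
            if bic < best_bic:
                best_bic, best = bic, gm
        labels = best.predict(ages)
    out = []
    for lab in np.unique(labels):
        sel = labels == lab
        a = candidates.loc[sel, "t"]
        out.append(BreakpointInterval(
            median_age=float(a.median()),
            age_min=float(a.min()), age_max=float(a.max()),
            combined_p=float(candidates.loc[sel, "combined_p"].min()),
            member_ages=tuple(a), member_windows=tuple(candidates.loc[sel, "w"])
            if "w" in candidates.columns else ()))
    out.sort(key=lambda iv: iv.median_age)
    return out


# ---------------------------------------------------------------------------
# End-to-end detector
# ---------------------------------------------------------------------------

class BreakpointDetector(BaseEstimator):
    """Full multi-scale breakpoint scan for one cluster of features.

    ``fit(X, ages)`` with X = samples x features (adjusted values of the
    cluster members).  Fitted attributes: ``scores_`` (PCA scores),
    ``curves_`` (per-w -log10 p curves), ``combined_`` (per-w combined
    curves), ``candidates_`` and ``intervals_``.
    """

    def __init__(self, config: ScanConfig = ScanConfig()):
        self.config = config

    def fit(self, X, ages):
        X = pd.DataFrame(X)
        cfg = self.config
        self.scores_ = reduce_cluster(X.T, cfg.n_pcs)
        ages = np.asarray(ages, dtype=float)
        self.curves_ = {}
        self.combined_ = {}
        pooled = []
        for w in cfg.windows:
            curve = scan_ages(self.scores_, ages, w)
            self.curves_[w] = curve
            if len(curve.table) < 5:
                log.warning("w=%s: too few tested ages; span excluded", w)
                continue
            combined = combine_and_smooth(curve, cfg.bandwidths)
            self.combined_[w] = combined
            cand = candidate_breakpoints(combined, cfg)
            if not cand.empty:
                cand = cand.assign(w=w)
                pooled.append(cand)
        self.candidates_ = (pd.concat(pooled, ignore_index=True)
                            if pooled else pd.DataFrame(columns=["t", "combined_p",
                                                                 "loginvp", "prominence", "w"]))
        self.intervals_ = group_breakpoints(self.candidates_, cfg)
        return self


def detect_breakpoints(adjusted: pd.DataFrame, ages,
                       config: ScanConfig = ScanConfig()) -> list:
    """Breakpoint intervals for one cluster (features x samples input)."""
    det = BreakpointDetector(config).fit(adjusted.T, ages)
    return det.intervals_
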