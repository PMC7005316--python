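"""Chronological trend discovery via stepwise-AIC ARIMA and trajectory clustering.

Per feature, adjusted values are averaged within (sex, age in years) to form
an ordered age series, treated as an equally spaced sequence.  The
differencing order D (<= 2) is chosen by successive KPSS stationarity
testing; (p, q) by a stepwise neighborhood search minimizing AIC.  A feature
carries a significant trend when D > 0 and at least one AR or MA coefficient
is in the selected model.  Fitted trajectories are z-scored and grouped by
best-of-n-restarts k-means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from statsmodels.tsa.arima.model import ARIMA
from statsmodels.tsa.stattools import kpss

from .annotate import enrichment_test

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Age series
# ---------------------------------------------------------------------------

def build_age_series(adjusted: pd.DataFrame, samples: pd.DataFrame, sex: str):
    """Per-feature series over the distinct ages observed for one sex.

    Values from subjects sharing (sex, age) are averaged.  Returns
    ``(ages, series)`` where ``series`` is features x len(ages), columns in
    increasing age order (equally spaced index downstream).
    """
    cols = samples.index[samples["sex"] == sex]
    ages = samples.loc[cols, "age"]
    distinct = np.sort(ages.unique())
    if distinct.size < 3:
        raise ValueError(f"need >= 3 distinct ages for sex {sex!r}, got {distinct.size}")
    series = adjusted[cols].T.groupby(ages).mean().T
    series = series[distinct]
    return distinct, series


# ---------------------------------------------------------------------------
# Stepwise ARIMA
# ---------------------------------------------------------------------------

@dataclass
class TrendModel:
    p: int
    D: int
    q: int
    aic: float
    params: dict
    fitted: np.ndarray
    searched: dict = field(repr=False, default_factory=dict)

    @property
    def selected(self) -> bool:
        return self.D > 0 and (self.p + self.q) > 0


def _choose_D(y: np.ndarray, max_D: int, alpha: float) -> int:
    """Difference until KPSS no longer rejects level stationarity."""
    d = 0
    z = y
    while d < max_D:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, pval, *_ = kpss(z, regression="c", nlags="auto")
        if pval > alpha:
            break
        d += 1
        z = np.diff(z)
    return d


def _fit_order(y, p, D, q, root_tol: float = 0.05):
    # constant mean when stationary; drift when differenced once
    trend = "c" if D == 0 else ("t" if D == 1 else "n")
    model = ARIMA(y, order=(p, D, q), trend=trend)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit()
    # non-converged optimizations carry spurious likelihoods
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError(f"ARIMA({p},{D},{q}) did not converge")
    # a near-common AR/MA root means parameter redundancy; not a valid candidate
    if p > 0 and q > 0:
        ar, ma = fit.arroots, fit.maroots
        if ar.size and ma.size and \
                np.min(np.abs(ar[:, None] - ma[None, :])) < root_tol:
            raise RuntimeError(f"ARIMA({p},{D},{q}): canceling AR/MA roots")
    return fit


def fit_arima_stepwise(y, max_p: int = 5, max_q: int = 5, max_D: int = 2,
                       kpss_alpha: float = 0.05) -> TrendModel:
    """Best ARIMA(p, D, q) by stepwise AIC search.

    Greedy +-1 neighborhood paths in (p, q) are run from each of the four
    canonical starting points (0,0), (1,0), (0,1) and (2,2), accepting
    strictly better AIC; the best endpoint wins.  Invalid candidates
    (non-convergent, or with canceling AR/MA roots) are skipped with a log
    entry.  ML estimation; AIC (not AICc); a drift term is included for
    D = 1 and a constant for D = 0.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 8:
        raise ValueError("series too short (need >= 8 points)")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    D = _choose_D(y, max_D, kpss_alpha)

    tried: dict[tuple, float] = {}
    fits: dict[tuple, object] = {}

    def evaluate(p, q):
        if (p, q) in tried:
            return tried[(p, q)]
        if not (0 <= p <= max_p and 0 <= q <= max_q):
            tried[(p, q)] = np.inf
            return np.inf
        try:
            fit = _fit_order(y, p, D, q)
            aic = fit.aic
        except Exception as exc:
            log.info("ARIMA(%d,%d,%d) failed to converge: %s", p, D, q, exc)
            aic = np.inf
            fit = None
        tried[(p, q)] = aic
        fits[(p, q)] = fit
        return aic

    endpoints = []
    for start in [(0, 0), (1, 0), (0, 1), (2, 2)]:
        evaluate(*start)
        best = start
        improved = True
        while improved:
            improved = False
            p, q = best
            for dp, dq in [(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, -1)]:
                cand = (p + dp, q + dq)
                if evaluate(*cand) < tried[best]:
                    best = cand
                    improved = True
        endpoints.append(best)
    best = min(endpoints, key=tried.get)
    if not np.isfinite(tried[best]):
        raise ValueError("no candidate ARIMA model converged")
    fit = fits[best]
    return TrendModel(p=best[0], D=D, q=best[1], aic=tried[best],
                      params=dict(zip(fit.param_names, fit.params)),
                      fitted=np.asarray(fit.fittedvalues),
                      searched=dict(tried))


def fit_all(series: pd.DataFrame, **kwargs) -> dict:
    """Stepwise ARIMA fit for every row of an age-series matrix."""
    return {fid: fit_arima_stepwise(series.loc[fid].to_numpy(), **kwargs)
            for fid in series.index}


def select_trending(models: dict) -> list:
    """Features whose model has D > 0 and at least one AR or MA term."""
    return [fid for fid, m in models.items() if m.selected]


def fitted_zscores(models: dict, ids) -> pd.DataFrame:
    """Row-wise z-scores of fitted trajectories (mean 0, SD 1 per feature)."""
    rows, kept = [], []
    for fid in ids:
        f = models[fid].fitted
        sd = f.std()
        if sd == 0 or not np.isfinite(sd):
            log.warning("dropping %s: constant fitted series (z undefined)", fid)
            continue
        rows.append((f - f.mean()) / sd)
        kept.append(fid)
    return pd.DataFrame(rows, index=kept)


# ---------------------------------------------------------------------------
# Trajectory clustering
# ---------------------------------------------------------------------------

class TrendClusterer(BaseEstimator, ClusterMixin):
    """Best-of-``nstart`` k-means on z-scored trajectories.

    Mirrors R's kmeans(nstart=, iter.max=) protocol: ``nstart`` random
    initializations, each run at most ``max_iter`` Lloyd iterations; the
    partition with the lowest within-cluster sum of squares wins.
    """

    def __init__(self, k: int = 3, nstart: int = 1000, max_iter: int = 100,
                 seed: int = 0):
        self.k = k
        self.nstart = nstart
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > X.shape[0]:
            raise ValueError("k cannot exceed the number of features")
        km = KMeans(n_clusters=self.k, n_init=self.nstart,
                    max_iter=self.max_iter, init="random",
                    algorithm="lloyd", random_state=self.seed)
        km.fit(X)
        self.labels_ = km.labels_
        self.cluster_centers_ = km.cluster_centers_
        self.inertia_ = km.inertia_
        return self


@dataclass
class TemporalClusters:
    labels: pd.Series          # feature -> cluster id
    centers: np.ndarray        # k x series length
    k: int
    inertia: float

    def members(self, cluster) -> pd.Index:
        return self.labels.index[self.labels == cluster]


def cluster_trends(zscores: pd.DataFrame, k: int, nstart: int = 1000,
                   max_iter: int = 100, seed: int = 0) -> TemporalClusters:
    est = TrendClusterer(k=k, nstart=nstart, max_iter=max_iter, seed=seed)
    est.fit(zscores.to_numpy())
    return TemporalClusters(
        labels=pd.Series(est.labels_, index=zscores.index, name="cluster"),
        centers=est.cluster_centers_, k=k, inertia=est.inertia_)


def concat_shared(models_f: dict, models_m: dict, shared_ids, k: int,
                  nstart: int = 1000, max_iter: int = 100, seed: int = 0):
    """Cluster features trending in both sexes on concatenated trajectories.

    The female and male fitted series of each feature are concatenated as a
    single sequence of two age-ordered halves, then z-scored over the
    concatenation (so a sex-opposed feature keeps opposite-sign halves) and
    clustered.  Returns ``(clusters, zscores)``.
    """
    rows = []
    for fid in shared_ids:
        if fid not in models_f or fid not in models_m:
            raise ValueError(f"feature {fid!r} lacks a fit in one sex")
        rows.append(np.concatenate([models_f[fid].fitted, models_m[fid].fitted]))
    mat = np.asarray(rows)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant concatenated series")
    z = pd.DataFrame((mat - mean) / sd, index=list(shared_ids))
    return cluster_trends(z, k, nstart, max_iter, seed), z


# ---------------------------------------------------------------------------
# Enrichment-guided choice of k
# ---------------------------------------------------------------------------

def _signatures(zscores, labels, collection, fdr=0.05):
    """Per-cluster frozenset of significantly enriched set names."""
    universe = list(zscores.index)
    sigs = []
    for c in np.unique(labels):
        members = labels.index[labels == c]
        enr = enrichment_test(members, collection, universe)
        sigs.append(frozenset(enr.index[enr["fdr"] <= fdr]))
    return sigs


def _collapse(signatures):
    """Merge clusters sharing an identical enrichment signature.

    Implemented as single-linkage hierarchical grouping cut at distance 0,
    i.e. exact-signature groups; returns the collapsed signature set and a
    cluster -> group map.
    """
    groups: dict[frozenset, list] = {}
    for i, s in enumerate(signatures):
        groups.setdefault(s, []).append(i)
    mapping = {i: j for j, (s, idxs) in enumerate(sorted(groups.items(), key=lambda t: min(t[1])))
               for i in idxs}
    return set(groups), mapping


def choose_k(zscores: pd.DataFrame, collection: dict, k_range=range(2, 16),
             nstart: int = 100, max_iter: int = 100, seed: int = 0,
             fdr: float = 0.05):
    """Scan k, compute per-cluster enrichment profiles and pick k.

    For each k the clusters' significant-set signatures are computed against
    the background of all trending features; clusters with identical
    signatures collapse into one biological group.  The recommended k is the
    smallest whose collapsed signature set equals that of k + 1 (no new
    biology from an extra cluster); falls back to the largest k scanned.
    """
    if not collection:
        raise ValueError("gene-set collection must be non-empty")
    profiles, collapsed, maps = {}, {}, {}
    for k in k_range:
        cl = cluster_trends(zscores, k, nstart=nstart, max_iter=max_iter, seed=seed)
        sigs = _signatures(zscores, cl.labels, collection, fdr)
        profiles[k] = sigs
        collapsed[k], maps[k] = _collapse(sigs)
    ks = sorted(profiles)
    recommended = ks[-1]
    for a, b in zip(ks, ks[1:]):
        if collapsed[a] == collapsed[b]:
            recommended = a
            break
    return profiles, recommended, maps[recommended]
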