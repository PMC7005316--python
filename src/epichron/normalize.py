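"""TMM normalization, NB-GLM differential testing and model-adjusted values.

The negative-binomial GLM uses a log link with per-feature dispersions
moderated toward a mean-abundance trend (method-of-moments estimates,
lowess trend, fixed-weight shrinkage in log space) and a likelihood-ratio
test for the contrast of interest, followed by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._utils import as_count_frame, bh_adjust

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# TMM (trimmed mean of M-values)
# ---------------------------------------------------------------------------

def _tmm_pair(obs, ref, n_obs, n_ref, trim_M=0.30, trim_A=0.05):
    """Scaling factor of one library against the reference.

    Doubly trimmed (by M and by A), precision-weighted mean of the log2
    count ratios, exponentiated.
    """
    obs = obs.astype(float)
    ref = ref.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logR = np.log2((obs / n_obs) / (ref / n_ref))
        absE = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2
        v = (n_obs - obs) / n_obs / obs + (n_ref - ref) / n_ref / ref
    fin = np.isfinite(logR) & np.isfinite(absE)
    logR, absE, v = logR[fin], absE[fin], v[fin]
    if logR.size == 0:
        raise ValueError("sample shares no co-expressed features with the reference")
    if np.max(np.abs(logR)) < 1e-6:
        return 1.0
    n = logR.size
    loL = np.floor(n * trim_M) + 1
    hiL = n + 1 - loL
    loS = np.floor(n * trim_A) + 1
    hiS = n + 1 - loS
    rR = rankdata(logR)
    rA = rankdata(absE)
    keep = (rR >= loL) & (rR <= hiL) & (rA >= loS) & (rA <= hiS)
    if not keep.any():
        raise ValueError("trimming removed every feature; libraries too discordant")
    f = np.sum(logR[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return 2.0 ** f


def tmm_factors(counts, lib_size=None, trim_M: float = 0.30,
                trim_A: float = 0.05) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference library is the one whose upper-quartile CPM is closest to
    the mean upper-quartile over samples.
    """
    counts = as_count_frame(counts)
    x = counts.to_numpy(dtype=float)
    if lib_size is None:
        lib_size = x.sum(axis=0)
    lib_size = np.asarray(lib_size, dtype=float)
    if np.any(lib_size <= 0):
        raise ValueError("each sample must have positive total count")
    uq = np.array([np.quantile(x[:, j] / lib_size[j], 0.75) for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    f = np.array([
        _tmm_pair(x[:, j], x[:, ref], lib_size[j], lib_size[ref], trim_M, trim_A)
        for j in range(x.shape[1])
    ])
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="tmm_factor")


def effective_lib_size(counts, factors: pd.Series | None = None) -> pd.Series:
    counts = as_count_frame(counts)
    if factors is None:
        factors = tmm_factors(counts)
    return counts.sum(axis=0) * factors


def cpm(counts, factors: pd.Series | None = None, log2: bool = False,
        prior: float = 0.5) -> pd.DataFrame:
    """Counts per million of effective (TMM-scaled) library size."""
    counts = as_count_frame(counts)
    eff = effective_lib_size(counts, factors)
    if (eff <= 0).any():
        raise ValueError("zero effective library size")
    out = counts / eff * 1e6
    if log2:
        out = np.log2(out + prior)
    return out


# ---------------------------------------------------------------------------
# Dispersion estimation and NB GLM differential test
# ---------------------------------------------------------------------------

def _design_matrix(design: pd.DataFrame) -> np.ndarray:
    X = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is not full column rank")
    return X


def estimate_dispersions(counts: pd.DataFrame, design: pd.DataFrame,
                         prior_weight: float = 0.5) -> pd.Series:
    """Moderated per-feature NB dispersions.

    Method-of-moments (Pearson-residual) estimates from Poisson fits, a
    lowess trend on log mean abundance, and shrinkage of each raw estimate
    toward the trend with fixed weight ``prior_weight`` in log space.
    """
    X = _design_matrix(design)
    y = counts.to_numpy(dtype=float)
    n, p = X.shape
    raw = np.empty(y.shape[0])
    mean_log = np.empty(y.shape[0])
    for i in range(y.shape[0]):
        fit = sm.GLM(y[i], X, family=sm.families.Poisson()).fit()
        mu = fit.mu
        raw[i] = np.sum(((y[i] - mu) ** 2 - mu) / mu**2) / max(n - p, 1)
        mean_log[i] = np.log(mu.mean())
    raw = np.clip(raw, 1e-6, 10.0)
    trend = lowess(np.log(raw), mean_log, frac=0.5, return_sorted=False)
    trend = np.clip(trend, np.log(1e-6), np.log(10.0))
    shrunk = np.exp(prior_weight * trend + (1 - prior_weight) * np.log(raw))
    return pd.Series(shrunk, index=counts.index, name="dispersion")


@dataclass
class DifferentialResult:
    table: pd.DataFrame
    fdr_threshold: float

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def _nb_llf(y, X, alpha):
    model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit()
    return fit


def differential_test(counts, design: pd.DataFrame, contrast: str,
                      fdr_threshold: float = 0.05,
                      dispersions: pd.Series | None = None) -> DifferentialResult:
    """Per-feature NB-GLM likelihood-ratio test for ``contrast``.

    ``design`` is a numeric per-sample covariate table (aligned to the
    columns of ``counts``); an intercept column is added if absent.
    ``contrast`` names the design column under test.  Returns log2 fold
    change (the contrast coefficient in log2 units), mean logCPM, raw p,
    BH-adjusted FDR and a significance flag at ``fdr_threshold``.
    """
    counts = as_count_frame(counts)
    design = design.loc[counts.columns].astype(float)
    if "intercept" not in design.columns:
        design = design.copy()
        design.insert(0, "intercept", 1.0)
    if contrast not in design.columns:
        raise ValueError(f"contrast {contrast!r} is not a design column")

    zero = counts.sum(axis=1) == 0
    if zero.any():
        log.warning("dropping %d all-zero features", int(zero.sum()))
        counts = counts.loc[~zero]

    X_full = _design_matrix(design)
    cols = [c for c in design.columns if c != contrast]
    X_null = _design_matrix(design[cols])
    if dispersions is None:
        dispersions = estimate_dispersions(counts, design)
    dispersions = dispersions.reindex(counts.index)

    y = counts.to_numpy(dtype=float)
    j = list(design.columns).index(contrast)
    logfc = np.empty(len(counts))
    pvals = np.empty(len(counts))
    logcpm = np.log2(cpm(counts).mean(axis=1) + 0.5)
    for i in range(len(counts)):
        alpha = float(dispersions.iloc[i])
        try:
            full = _nb_llf(y[i], X_full, alpha)
            null = _nb_llf(y[i], X_null, alpha)
            lr = 2.0 * (full.llf - null.llf)
            pvals[i] = stats.chi2.sf(max(lr, 0.0), df=1)
            logfc[i] = full.params[j] / np.log(2)
        except Exception as exc:  # non-estimable feature
            log.warning("feature %s failed to fit: %s", counts.index[i], exc)
            pvals[i] = np.nan
            logfc[i] = np.nan

    fdr = bh_adjust(pvals)
    table = pd.DataFrame({
        "logFC": logfc,
        "logCPM": logcpm,
        "p": pvals,
        "fdr": fdr,
        "significant": fdr <= fdr_threshold,
    }, index=counts.index)
    return DifferentialResult(table, fdr_threshold)


# ---------------------------------------------------------------------------
# Model-adjusted values and surrogate covariates
# ---------------------------------------------------------------------------

def _ols_fitted(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Row-wise fitted values of OLS of each row of Y on columns of X."""
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return (X @ beta).T


def model_adjusted_values(counts, null_design: pd.DataFrame,
                          factors: pd.Series | None = None,
                          protect: tuple = ()) -> pd.DataFrame:
    """Log2 CPM minus the fitted values of the null (nuisance-only) model.

    ``null_design`` holds only nuisance covariates (batch, library size,
    surrogate variables); listing a protected factor of interest in it is an
    error.  The result retains age/sex-driven variation plus noise, centered
    per feature when the null model has an intercept.
    """
    for name in protect:
        if name in null_design.columns:
            raise ValueError(f"null design must not contain the contrast factor {name!r}")
    counts = as_count_frame(counts)
    y = cpm(counts, factors, log2=True)
    design = null_design.loc[counts.columns].astype(float)
    if "intercept" not in design.columns:
        design = design.copy()
        design.insert(0, "intercept", 1.0)
    X = _design_matrix(design)
    fitted = _ols_fitted(y.to_numpy(), X)
    return pd.DataFrame(y.to_numpy() - fitted, index=y.index, columns=y.columns)


class ResidualPCACovariates(BaseEstimator, TransformerMixin):
    """Surrogate covariates from principal components of residual variation.

    Fits OLS of each feature (column of ``X``, samples x features) on the
    known design, then extracts the top ``n_sv`` principal components of the
    residual matrix; the scores are orthogonal to the design columns by
    construction.
    """

    def __init__(self, n_sv: int = 1):
        self.n_sv = n_sv

    def fit(self, X, y=None, design: pd.DataFrame | None = None):
        X = np.asarray(X, dtype=float)
        n, m = X.shape
        if self.n_sv < 0:
            raise ValueError("n_sv must be >= 0")
        if self.n_sv >= min(n, m):
            raise ValueError("n_sv must be < min(n_features, n_samples)")
        if design is None:
            D = np.ones((n, 1))
        else:
            D = _design_matrix(pd.DataFrame(design))
        beta, *_ = np.linalg.lstsq(D, X, rcond=None)
        resid = X - D @ beta
        resid = resid - resid.mean(axis=0, keepdims=True)
        u, s, vt = np.linalg.svd(resid, full_matrices=False)
        self.components_ = vt[: self.n_sv]
        self.scores_ = u[:, : self.n_sv] * s[: self.n_sv]
        return self

    def transform(self, X=None):
        return self.scores_


def surrogate_covariates(counts, known_design: pd.DataFrame, n_sv: int,
                         factors: pd.Series | None = None) -> pd.DataFrame:
    """Residual-PC surrogate covariates on the log2 CPM scale."""
    counts = as_count_frame(counts)
    y = cpm(counts, factors, log2=True)
    design = known_design.loc[counts.columns].astype(float)
    if "intercept" not in design.columns:
        design = design.copy()
        design.insert(0, "intercept", 1.0)
    est = ResidualPCACovariates(n_sv=n_sv).fit(y.to_numpy().T, design=design)
    cols = [f"SV{i + 1}" for i in range(n_sv)]
    return pd.DataFrame(est.scores_, index=counts.columns, columns=cols)


class TMMNormalizer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: samples x features counts -> CPM.

    Fitted attributes: ``factors_`` (TMM scaling factors, geometric mean 1)
    and ``effective_lib_size_``.
    """

    def __init__(self, trim_M: float = 0.30, trim_A: float = 0.05,
                 log2: bool = False, prior: float = 0.5):
        self.trim_M = trim_M
        self.trim_A = trim_A
        self.log2 = log2
        self.prior = prior

    def fit(self, X, y=None):
        counts = pd.DataFrame(X).T  # internal convention: features x samples
        self.factors_ = tmm_factors(counts, trim_M=self.trim_M, trim_A=self.trim_A)
        self.effective_lib_size_ = effective_lib_size(counts, self.factors_)
        return self

    def transform(self, X):
        counts = pd.DataFrame(X).T
        out = counts / self.effective_lib_size_ * 1e6
        if self.log2:
            out = np.log2(out + self.prior)
        return out.T


# ---------------------------------------------------------------------------
# PC1 marker selection
# ---------------------------------------------------------------------------

def pc1_markers(matrix, quantile: float = 0.25):
    """Marker features from first-principal-component loadings.

    Samples are observations, features are variables.  The PC1 sign is fixed
    so that the loading vector correlates positively with mean abundance.
    Returns (positive marker ids, negative marker ids, per-sample PC1
    scores): the top ``quantile`` fraction of positive loadings and of
    negative loadings by magnitude.
    """
    matrix = pd.DataFrame(matrix)
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    X = matrix.to_numpy(dtype=float).T
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        raise ValueError("constant matrix: PC1 undefined")
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt[0]
    scores = u[:, 0] * s[0]
    mean_abund = X.mean(axis=0)
    if np.corrcoef(loadings, mean_abund)[0, 1] < 0:
        loadings = -loadings
        scores = -scores
    pos = loadings > 0
    neg = loadings < 0
    pos_ids = matrix.index[pos & (loadings >= np.quantile(loadings[pos], 1 - quantile))] \
        if pos.any() else matrix.index[[]]
    neg_ids = matrix.index[neg & (-loadings >= np.quantile(-loadings[neg], 1 - quantile))] \
        if neg.any() else matrix.index[[]]
    return pos_ids, neg_ids, pd.Series(scores, index=matrix.columns, name="PC1")
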