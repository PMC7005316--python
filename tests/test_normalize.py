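import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest, rankdata

from epichron import normalize
from epichron._utils import bh_adjust


def tmm_oracle(counts, trim_M=0.30, trim_A=0.05):
    """Independent TMM reimplementation straight from the definition.

    Reference = library with upper-quartile CPM closest to the mean;
    per-pair factor = precision-weighted mean of M-values after removing the
    30% most extreme M and 5% most extreme A (rank-based double trim).
    """
    x = np.asarray(counts, dtype=float)
    lib = x.sum(axis=0)
    uq = np.quantile(x / lib, 0.75, axis=0)
    ref = np.argmin(np.abs(uq - uq.mean()))
    factors = []
    for j in range(x.shape[1]):
        o, r = x[:, j], x[:, ref]
        use = (o > 0) & (r > 0)
        M = np.log2((o[use] / lib[j]) / (r[use] / lib[ref]))
        A = 0.5 * (np.log2(o[use] / lib[j]) + np.log2(r[use] / lib[ref]))
        w = 1.0 / ((lib[j] - o[use]) / (lib[j] * o[use])
                   + (lib[ref] - r[use]) / (lib[ref] * r[use]))
        if np.max(np.abs(M)) < 1e-6:
            factors.append(1.0)
            continue
        n = M.size
        lo_m = np.floor(n * trim_M) + 1
        lo_a = np.floor(n * trim_A) + 1
        keep = ((rankdata(M) >= lo_m) & (rankdata(M) <= n + 1 - lo_m)
                & (rankdata(A) >= lo_a) & (rankdata(A) <= n + 1 - lo_a))
        factors.append(2.0 ** (np.sum(M[keep] * w[keep]) / np.sum(w[keep])))
    f = np.array(factors)
    return f / np.exp(np.mean(np.log(f)))


class TestTMM:
    def test_identical_libraries_have_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30, 5], "b": [10, 20, 30, 5]})
        assert normalize.tmm_factors(counts).tolist() == [1.0, 1.0]

    def test_global_scaling_absorbed_by_library_size(self):
        counts = pd.DataFrame({"a": [10, 20, 30, 5], "b": [20, 40, 60, 10]})
        f = normalize.tmm_factors(counts)
        assert f.tolist() == pytest.approx([1.0, 1.0])

    def test_matches_independent_oracle(self, rng):
        counts = pd.DataFrame(rng.negative_binomial(8, 0.05, size=(200, 5)) + 1)
        f = normalize.tmm_factors(counts)
        np.testing.assert_allclose(f.to_numpy(), tmm_oracle(counts), atol=1e-8)

    def test_matches_edgers_calcnormfactors(self, rng, tmp_path):
        counts = pd.DataFrame(rng.negative_binomial(10, 0.1, size=(300, 6)),
                              index=[f"g{i}" for i in range(300)])
        counts.iloc[:50, 0] *= 3
        path = tmp_path / "c.tsv"
        counts.to_csv(path, sep="\t")
        out = subprocess.run(
            ["Rscript", "-e",
             f'suppressMessages(library(edgeR));'
             f'x <- as.matrix(read.delim("{path}", row.names=1));'
             f'cat(sprintf("%.12f\\n", calcNormFactors(x, method="TMM")))'],
            capture_output=True, text=True, check=True)
        edger = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(normalize.tmm_factors(counts).to_numpy(),
                                   edger, atol=1e-8)

    def test_geometric_mean_is_one(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(100, 8)) + 1)
        f = normalize.tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_libraries_error(self):
        counts = pd.DataFrame({"a": [10, 0, 20, 0], "b": [0, 5, 0, 8]})
        with pytest.raises(ValueError):
            normalize.tmm_factors(counts)


class TestCPM:
    def test_basic_value(self):
        counts = pd.DataFrame({"a": [100, 999_900]})
        out = normalize.cpm(counts, factors=pd.Series([1.0], index=["a"]))
        assert out.iloc[0, 0] == pytest.approx(100.0)

    def test_scaling_invariance(self, toy_counts):
        f = pd.Series(1.0, index=toy_counts.columns)
        before = normalize.cpm(toy_counts, f)
        doubled = toy_counts.copy()
        doubled["b"] *= 2
        after = normalize.cpm(doubled, f)
        np.testing.assert_allclose(before["b"], after["b"])

    def test_matches_hand_computation(self, toy_counts):
        f = pd.Series([1.0, 1.0, 1.0], index=toy_counts.columns)
        out = normalize.cpm(toy_counts, f)
        lib = toy_counts.sum(axis=0)
        assert out.loc["g2", "b"] == pytest.approx(420 / lib["b"] * 1e6)


class TestBH:
    def test_matches_bruteforce_oracle(self, rng):
        p = rng.random(200)

        def oracle(pvals):
            m = len(pvals)
            order = np.argsort(pvals)
            out = np.empty(m)
            prev = 1.0
            for rank_from_top, i in enumerate(order[::-1]):
                r = m - rank_from_top
                prev = min(prev, pvals[i] * m / r)
                out[i] = prev
            return out

        np.testing.assert_allclose(bh_adjust(p), oracle(p), atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_adjusted_monotone_in_raw_p_and_bounded(self, pvals):
        p = np.array(pvals)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all((adj >= 0) & (adj <= 1))
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestDifferentialTest:
    def _design(self, columns, n_group):
        n = len(columns)
        return pd.DataFrame({
            "group": np.repeat([0.0, 1.0], [n - n_group, n_group]),
        }, index=columns)

    def test_identical_groups_give_null_results(self):
        rng = np.random.default_rng(3)
        half = pd.DataFrame(rng.poisson(40, size=(30, 6)))
        counts = pd.concat([half, half], axis=1, ignore_index=True)
        design = self._design(counts.columns, 6)
        res = normalize.differential_test(counts, design, "group")
        assert res.table["logFC"].abs().max() < 1e-6
        assert (res.table["p"] > 0.99).all()

    def test_recovers_twofold_change(self):
        rng = np.random.default_rng(8)
        n = 40
        mu = np.full((200, n), 100.0)
        mu[:, n // 2:] *= 2.0
        counts = pd.DataFrame(rng.negative_binomial(10, 10 / (10 + mu)))
        res = normalize.differential_test(counts, self._design(counts.columns, n // 2),
                                          "group")
        assert 0.8 < res.table["logFC"].mean() < 1.2

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(21)
        n = 30
        mu = rng.lognormal(4, 0.8, size=800)[:, None] * np.ones(n)
        counts = pd.DataFrame(rng.negative_binomial(10, 10 / (10 + mu)))
        res = normalize.differential_test(counts, self._design(counts.columns, n // 2),
                                          "group")
        ks = kstest(res.table["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_fdr_never_below_raw_p(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(30, size=(50, 12)))
        res = normalize.differential_test(counts, self._design(counts.columns, 6),
                                          "group")
        ok = res.table.dropna()
        assert (ok["fdr"] >= ok["p"] - 1e-12).all()

    def test_unknown_contrast_errors(self, toy_counts):
        design = self._design(toy_counts.columns, 1)
        with pytest.raises(ValueError, match="contrast"):
            normalize.differential_test(toy_counts, design, "age")


class TestModelAdjustedValues:
    def test_intercept_only_centers_rows(self, toy_counts):
        adj = normalize.model_adjusted_values(toy_counts,
                                              pd.DataFrame(index=toy_counts.columns))
        assert adj.mean(axis=1).abs().max() < 1e-10

    def test_removes_planted_batch_shift(self):
        rng = np.random.default_rng(5)
        n = 40
        batch = np.repeat([0.0, 1.0], n // 2)
        mu = 100 * 2 ** (batch * 1.0)  # 1 log2-unit batch shift
        counts = pd.DataFrame(rng.poisson(mu, size=(300, n)))
        design = pd.DataFrame({"batch": batch}, index=counts.columns)
        adj = normalize.model_adjusted_values(counts, design)
        gap = adj.loc[:, batch == 1].mean().mean() - adj.loc[:, batch == 0].mean().mean()
        assert abs(gap) < 0.05

    def test_projection_is_idempotent(self, toy_counts):
        design = pd.DataFrame({"x": [0.0, 1.0, 2.0]}, index=toy_counts.columns)
        adj = normalize.model_adjusted_values(toy_counts, design)
        X = np.column_stack([np.ones(3), design["x"]])
        refit = adj.to_numpy() - (X @ np.linalg.lstsq(X, adj.to_numpy().T, rcond=None)[0]).T
        np.testing.assert_allclose(refit, adj.to_numpy(), atol=1e-10)

    def test_protected_factor_in_null_design_errors(self, toy_counts):
        design = pd.DataFrame({"age_group": [0.0, 1.0, 1.0]}, index=toy_counts.columns)
        with pytest.raises(ValueError, match="age_group"):
            normalize.model_adjusted_values(toy_counts, design, protect=("age_group",))


class TestSurrogateCovariates:
    def test_zero_sv_returns_empty(self, small_cohort):
        counts, _, _ = small_cohort
        design = pd.DataFrame(index=counts.columns)
        sv = normalize.surrogate_covariates(counts, design, 0)
        assert sv.shape == (counts.shape[1], 0)

    def test_recovers_hidden_batch_label(self):
        rng = np.random.default_rng(6)
        n = 40
        hidden = np.repeat([0.0, 1.0], n // 2)
        # shift a subset of features, else the effect is pure library size
        mu = np.full((400, n), 100.0)
        mu[:150] *= 2 ** (hidden * 1.5)
        counts = pd.DataFrame(rng.poisson(mu))
        known = pd.DataFrame({"x": rng.normal(size=n)}, index=counts.columns)
        sv = normalize.surrogate_covariates(counts, known, 1)
        r = np.corrcoef(sv["SV1"], hidden)[0, 1]
        assert abs(r) > 0.8

    def test_orthogonal_to_known_design(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.poisson(50, size=(100, 20)))
        known = pd.DataFrame({"x": rng.normal(size=20)}, index=counts.columns)
        sv = normalize.surrogate_covariates(counts, known, 2)
        X = np.column_stack([np.ones(20), known["x"]])
        assert np.abs(X.T @ sv.to_numpy()).max() < 1e-6

    def test_too_many_svs_error(self, toy_counts):
        with pytest.raises(ValueError, match="n_sv"):
            normalize.surrogate_covariates(toy_counts,
                                           pd.DataFrame(index=toy_counts.columns), 5)


class TestPC1Markers:
    def _matrix(self, rng, n=50, m=12):
        mat = pd.DataFrame(rng.normal(size=(n, m)),
                           index=[f"g{i}" for i in range(n)])
        return mat

    def test_trending_feature_lands_in_positive_set(self, rng):
        mat = self._matrix(rng) * 0.05
        mat.loc["g0"] = np.linspace(0, 8, mat.shape[1])  # dominant increasing feature
        mat.loc["g0"] += 10  # high abundance pins the sign convention
        pos, neg, scores = normalize.pc1_markers(mat)
        assert "g0" in pos
        # oracle: scores must track the planted gradient
        assert abs(np.corrcoef(scores, np.arange(mat.shape[1]))[0, 1]) > 0.99

    def test_negating_matrix_swaps_marker_sets(self, rng):
        mat = self._matrix(rng)
        mat.iloc[:25] += np.linspace(-2, 2, mat.shape[1])
        mat.iloc[25:] -= np.linspace(-2, 2, mat.shape[1])
        pos, neg, _ = normalize.pc1_markers(mat)
        pos2, neg2, _ = normalize.pc1_markers(-mat)
        assert set(pos) == set(neg2) and set(neg) == set(pos2)

    def test_marker_count_tracks_quantile(self, rng):
        mat = self._matrix(rng, n=400)
        pos, neg, _ = normalize.pc1_markers(mat, quantile=0.25)
        u, s, vt = np.linalg.svd(mat.to_numpy().T - mat.to_numpy().T.mean(0), full_matrices=False)
        n_pos = (vt[0] != 0).sum()  # loadings split roughly in half
        assert len(pos) + len(neg) == pytest.approx(0.25 * n_pos, rel=0.2)

    def test_constant_matrix_errors(self):
        with pytest.raises(ValueError, match="constant"):
            normalize.pc1_markers(pd.DataFrame(np.ones((5, 4))))


def test_estimators_support_sklearn_protocol(toy_counts):
    from sklearn.base import clone
    from epichron.breakpoints import BreakpointDetector, ScanConfig
    from epichron.trajectory import TrendClusterer
    for est in (normalize.TMMNormalizer(log2=True),
                normalize.ResidualPCACovariates(n_sv=2),
                TrendClusterer(k=2, nstart=5),
                BreakpointDetector(ScanConfig(seed=3))):
        cl = clone(est)
        assert cl.get_params() == est.get_params()


def test_tmm_normalizer_estimator_round_trip(toy_counts):
    est = normalize.TMMNormalizer().fit(toy_counts.T)
    assert np.exp(np.log(est.factors_).mean()) == pytest.approx(1.0)
    out = est.transform(toy_counts.T)
    expected = normalize.cpm(toy_counts, est.factors_)
    np.testing.assert_allclose(out.T.to_numpy(), expected.to_numpy())
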