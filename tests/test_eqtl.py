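import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from admixqtl import (
    CovariateTable,
    ExpressionMatrix,
    GeneRecord,
    GenotypeMatrix,
    SNPRecord,
    adjust_traits,
    differential_expression_fraction,
    effect_size_r2,
    filter_call_rate,
    kruskal_wallis,
    quantile_normalize_batches,
    scan_eqtls,
)
from admixqtl.eqtl import kw_scan_matrix


def _geno(dosage, positions=None, chrom="1"):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    positions = positions if positions is not None else [1000 * (j + 1) for j in range(m)]
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        snps=[SNPRecord(f"v{j}", chrom, positions[j], "A", "G") for j in range(m)],
        dosage=dosage,
    )


class TestCallRateFilter:
    def _with_missing(self, frac_missing, n=100):
        col = np.zeros((n, 1))
        col[: int(round(n * frac_missing)), 0] = np.nan
        col[-1, 0] = 1.0
        return _geno(col)

    def test_snp_below_threshold_removed(self):
        G = self._with_missing(0.11)  # 89% call rate
        assert filter_call_rate(G, 0.9).n_snps == 0

    def test_snp_at_exact_threshold_retained(self):
        # the rule excludes only SNPs strictly below the threshold
        G = self._with_missing(0.10)  # exactly 90%
        assert filter_call_rate(G, 0.9).n_snps == 1

    def test_zero_threshold_is_identity(self):
        G = self._with_missing(0.5)
        assert filter_call_rate(G, 0.0).n_snps == 1


class TestQuantileNormalization:
    def _expr(self, values, batches):
        values = np.asarray(values, dtype=float)
        n, t = values.shape
        return ExpressionMatrix(
            sample_ids=[f"s{i}" for i in range(n)],
            genes=[GeneRecord(f"t{j}", f"G{j}", "1", 100 + j) for j in range(t)],
            values=values,
            batch_labels=batches,
        )

    def test_location_shift_removed(self, rng):
        base = rng.normal(size=(30, 5))
        vals = np.vstack([base, base + 10.0])
        E = self._expr(vals, ["a"] * 30 + ["b"] * 30)
        out = quantile_normalize_batches(E)
        a = out.values[:30]
        b = out.values[30:]
        np.testing.assert_allclose(a.mean(axis=0), b.mean(axis=0), atol=1e-9)

    def test_batch_distributions_coincide(self, rng):
        vals = rng.normal(size=(40, 3))
        vals[20:] = vals[20:] * 3 - 4
        E = self._expr(vals, ["a"] * 20 + ["b"] * 20)
        out = quantile_normalize_batches(E)
        for j in range(3):
            d, _ = stats.ks_2samp(out.values[:20, j], out.values[20:, j])
            assert d <= 1 / 20 + 1e-12  # KS distance of identical EDFs on n=20

    def test_within_batch_order_preserved(self, rng):
        vals = rng.normal(size=(50, 4))
        vals[25:] += 5
        E = self._expr(vals, ["a"] * 25 + ["b"] * 25)
        out = quantile_normalize_batches(E)
        for j in range(4):
            for sl in (slice(0, 25), slice(25, 50)):
                rho = stats.spearmanr(vals[sl, j], out.values[sl, j]).statistic
                assert rho == pytest.approx(1.0)

    def test_singleton_batch_maps_to_pooled_median(self, rng):
        vals = rng.normal(size=(9, 2))
        E = self._expr(vals, ["a"] * 8 + ["b"])
        out = quantile_normalize_batches(E)
        np.testing.assert_allclose(out.values[8], np.median(vals, axis=0))

    def test_requires_two_batches(self, rng):
        E = self._expr(rng.normal(size=(4, 2)), ["a"] * 4)
        with pytest.raises(ValueError):
            quantile_normalize_batches(E)


class TestAdjustTraits:
    def _cov(self, n, rng):
        return CovariateTable(
            sample_ids=[f"s{i}" for i in range(n)],
            age=rng.uniform(20, 80, n),
            sex=(rng.random(n) < 0.5).astype(float),
        )

    def _expr(self, values):
        n, t = values.shape
        return ExpressionMatrix(
            sample_ids=[f"s{i}" for i in range(n)],
            genes=[GeneRecord(f"t{j}", f"G{j}", "1", 100 + j) for j in range(t)],
            values=values,
        )

    def test_exact_linear_age_trait_removed(self, rng):
        cov = self._cov(40, rng)
        y = (0.3 * cov.age + 1.0).reshape(-1, 1)
        adj = adjust_traits(self._expr(y), cov)
        assert np.abs(adj.residuals).max() < 1e-8

    def test_residual_mean_zero(self, rng):
        cov = self._cov(60, rng)
        vals = rng.normal(size=(60, 5)) + 0.1 * cov.age[:, None]
        adj = adjust_traits(self._expr(vals), cov)
        assert np.abs(adj.residuals.mean(axis=0)).max() < 1e-6

    def test_huber_fit_resists_gross_outlier(self, rng):
        """The robust slope stays nearer 0 than least squares under one outlier."""
        n = 50
        cov = self._cov(n, rng)
        y = rng.normal(size=n)
        y[0] = 200.0  # gross outlier at an extreme age
        cov.age[0] = 80.0
        X = np.column_stack([np.ones(n), cov.age])
        ols_slope = np.linalg.lstsq(X, y, rcond=None)[0][1]
        adj = adjust_traits(self._expr(y.reshape(-1, 1)), cov)
        fitted = y - adj.residuals[:, 0]
        huber_slope = np.polyfit(cov.age, fitted, 1)[0]
        assert abs(huber_slope) < abs(ols_slope)

    def test_adjusting_by_causal_dosage_kills_the_eqtl(self, rng):
        n = 80
        cov = self._cov(n, rng)
        g = rng.binomial(2, 0.5, n).astype(float)
        y = 2.0 * g + rng.normal(0, 0.5, n)
        adj = adjust_traits(
            self._expr(y.reshape(-1, 1)), cov, pcs=g.reshape(-1, 1), n_pcs=1
        )
        res = kruskal_wallis(adj.residuals[:, 0], g)
        assert res.p > 0.01
        # and without the adjustment the signal is overwhelming
        raw = kruskal_wallis(y, g)
        assert raw.p < 1e-6

    def test_constant_pc_column_dropped(self, rng):
        cov = self._cov(30, rng)
        pcs = np.column_stack([np.ones(30), rng.normal(size=30)])
        adj = adjust_traits(self._expr(rng.normal(size=(30, 2))), cov, pcs=pcs, n_pcs=2)
        assert "PC1" not in adj.adjustment_spec["covariates"]
        assert "PC2" in adj.adjustment_spec["covariates"]

    def test_missing_pcs_rejected(self, rng):
        cov = self._cov(10, rng)
        with pytest.raises(ValueError):
            adjust_traits(self._expr(rng.normal(size=(10, 1))), cov, n_pcs=2)


def exact_kw_pvalue(values, genotypes):
    """Exact permutation p-value of the KW statistic by full enumeration."""
    obs = kruskal_wallis(values, genotypes).K
    n = len(values)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        k = kruskal_wallis(values[list(perm)], genotypes).K
        total += 1
        if k >= obs - 1e-12:
            count += 1
    return count / total


class TestKruskalWallis:
    def test_hand_case_two_groups(self):
        """{1,2} vs {3,4}: rank sums 3 and 7 give K = 2.4."""
        res = kruskal_wallis(np.array([1, 2, 3, 4.0]), np.array([0, 0, 2, 2.0]))
        assert res.K == pytest.approx(2.4, abs=1e-12)
        assert res.p == pytest.approx(stats.chi2.sf(2.4, 1), abs=1e-12)
        assert res.g == 2 and res.n_used == 4

    def test_constant_values_give_null_result(self):
        res = kruskal_wallis(np.ones(10), np.array([0] * 5 + [2] * 5, dtype=float))
        assert res.K == 0.0 and res.p == 1.0

    def test_invariant_under_monotone_transforms(self, rng):
        v = rng.normal(size=30)
        g = rng.integers(0, 3, 30).astype(float)
        base = kruskal_wallis(v, g)
        for f in (np.exp, lambda x: x**3, lambda x: -1 / (1 + np.exp(-x))):
            res = kruskal_wallis(f(v), g)
            assert res.K == pytest.approx(base.K, abs=1e-10)
            assert res.p == pytest.approx(base.p, abs=1e-10)

    def test_matches_scipy_on_random_vectors_with_ties(self, rng):
        """Statistic and p agree with an independent mid-rank implementation."""
        for _ in range(300):
            n = int(rng.integers(6, 40))
            v = np.round(rng.normal(size=n), 1)  # rounding forces ties
            g = rng.integers(0, 3, n).astype(float)
            groups = [v[g == lev] for lev in (0, 1, 2) if (g == lev).any()]
            if len(groups) < 2 or np.ptp(v) == 0:
                continue
            ours = kruskal_wallis(v, g)
            ref = stats.kruskal(*groups)
            assert ours.K == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_pairwise_missing_exclusion(self):
        v = np.array([1.0, 2, 3, 4, np.nan])
        g = np.array([0.0, 0, 2, 2, 0])
        res = kruskal_wallis(v, g)
        assert res.n_used == 4
        assert res.K == pytest.approx(2.4, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis(np.arange(4.0), np.zeros(4))

    @pytest.mark.parametrize(
        "values,genotypes",
        [
            (np.array([1.0, 2, 3, 4, 5, 6]), np.array([0.0, 0, 0, 2, 2, 2])),
            (np.array([3.0, 1, 4, 1, 5, 9, 2, 6]), np.array([0.0, 0, 1, 1, 2, 2, 0, 1])),
            (np.array([1.0, 1, 2, 2, 3, 3]), np.array([0.0, 2, 0, 2, 0, 2])),
        ],
    )
    def test_chisquare_p_tracks_exact_permutation_p(self, values, genotypes):
        """At n <= 8 the chi-square tail stays within 3x of the exact p."""
        exact = exact_kw_pvalue(values, genotypes)
        approx = kruskal_wallis(values, genotypes).p
        assert approx >= exact / 3

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matrix_scan_agrees_with_single_tests(self, seed):
        rng = np.random.default_rng(seed)
        n, t, m = 25, 3, 6
        V = rng.normal(size=(n, t))
        D = rng.integers(0, 3, size=(n, m)).astype(float)
        K, P, g = kw_scan_matrix(V, D)
        for i in range(t):
            for j in range(m):
                lev = len(np.unique(D[:, j]))
                if lev < 2:
                    assert np.isnan(K[i, j])
                    continue
                res = kruskal_wallis(V[:, i], D[:, j])
                assert K[i, j] == pytest.approx(res.K, abs=1e-10)
                assert P[i, j] == pytest.approx(res.p, abs=1e-10)


class TestScan:
    def _traits(self, residuals, genes):
        from admixqtl.eqtl import AdjustedTraits

        return AdjustedTraits(
            sample_ids=[f"s{i}" for i in range(residuals.shape[0])],
            genes=genes,
            residuals=residuals,
            adjustment_spec={"covariates": [], "n_pcs": 0, "pc_source": "none"},
        )

    def test_cis_boundary_inclusive_and_trans_across_chromosomes(self, rng):
        G = GenotypeMatrix(
            sample_ids=[f"s{i}" for i in range(30)],
            snps=[
                SNPRecord("near", "1", 1_000_001, "A", "G"),
                SNPRecord("far", "1", 1_000_002, "A", "G"),
                SNPRecord("other", "2", 1_000_001, "A", "G"),
            ],
            dosage=rng.integers(0, 3, size=(30, 3)).astype(float),
        )
        genes = [GeneRecord("t0", "G0", "1", 1)]
        adj = self._traits(rng.normal(size=(30, 1)), genes)
        df = scan_eqtls(adj, G, min_shared=5)
        rel = df.set_index("snp_id")["relation"]
        assert rel["near"] == "cis"  # exactly 1 Mbp away
        assert rel["far"] == "trans"
        assert rel["other"] == "trans"

    def test_every_record_has_exactly_one_relation(self, small_study):
        _, cohort, expr, _ = small_study
        adj = adjust_traits(expr, cohort.covariates)
        df = scan_eqtls(adj, cohort.genotypes)
        assert set(df["relation"]) <= {"cis", "trans"}
        assert df["relation"].notna().all()

    def test_scan_deterministic(self, small_study):
        _, cohort, expr, _ = small_study
        adj = adjust_traits(expr, cohort.covariates)
        d1 = scan_eqtls(adj, cohort.genotypes)
        d2 = scan_eqtls(adj, cohort.genotypes)
        assert d1.equals(d2)

    def test_planted_cis_eqtl_detected(self, small_study):
        """The causal SNP for a planted trait lands among its smallest p-values."""
        _, cohort, expr, truth = small_study
        adj = adjust_traits(expr, cohort.covariates)
        df = scan_eqtls(adj, cohort.genotypes)
        hits = 0
        causal = truth.table.dropna(subset=["causal_snp_id"])
        for _, row in causal.iterrows():
            sub = df[df["trait_id"] == row["trait_id"]]
            rec = sub[sub["snp_id"] == row["causal_snp_id"]]
            if rec["p"].iloc[0] < 1e-4:
                hits += 1
        assert hits >= 0.6 * len(causal)

    def test_no_shared_samples_rejected(self, rng):
        G = _geno(rng.integers(0, 3, size=(5, 2)).astype(float))
        genes = [GeneRecord("t0", "G0", "1", 1)]
        adj = self._traits(rng.normal(size=(5, 1)), genes)
        adj.sample_ids = [f"x{i}" for i in range(5)]
        with pytest.raises(ValueError):
            scan_eqtls(adj, G)

    def test_missing_genotypes_fall_back_to_pairwise_path(self, rng):
        d = rng.integers(0, 3, size=(30, 3)).astype(float)
        d[0, 0] = np.nan
        G = _geno(d)
        genes = [GeneRecord("t0", "G0", "1", 1)]
        adj = self._traits(rng.normal(size=(30, 1)), genes)
        df = scan_eqtls(adj, G, min_shared=5)
        assert len(df) == 3
        v = adj.residuals[:, 0]
        ref = kruskal_wallis(v, d[:, 0])
        rec = df[df["snp_id"] == "v0"].iloc[0]
        assert rec["K"] == pytest.approx(ref.K, abs=1e-10)


class TestEffectSize:
    def test_perfect_linear_relation_gives_r2_one(self, rng):
        g = rng.integers(0, 3, 40).astype(float)
        assert effect_size_r2(2.0 * g - 1.0, g) == pytest.approx(1.0, abs=1e-6)

    def test_null_r2_small_at_large_n(self, rng):
        g = rng.binomial(2, 0.4, 500).astype(float)
        y = rng.normal(size=500)
        assert effect_size_r2(y, g) < 0.05

    def test_monomorphic_genotype_returns_none(self, rng):
        assert effect_size_r2(rng.normal(size=20), np.ones(20)) is None


class TestDifferentialExpression:
    def test_identical_groups_zero_fraction(self, rng):
        A = rng.normal(size=(10, 50))
        assert differential_expression_fraction(A, A.copy()) == 0.0

    def test_null_calibration(self, rng):
        A = rng.normal(size=(30, 10000))
        B = rng.normal(size=(30, 10000))
        frac = differential_expression_fraction(A, B, alpha=0.01)
        assert frac == pytest.approx(0.01, abs=0.005)

    def test_shifted_groups_detected(self, rng):
        A = rng.normal(size=(30, 200))
        B = rng.normal(size=(30, 200)) + 1.5
        assert differential_expression_fraction(A, B, alpha=0.01) > 0.5
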