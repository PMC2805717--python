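"""Trait preprocessing and Kruskal-Wallis eQTL mapping.

Traits are first quantile-normalized across the two collection batches, then
adjusted for age, sex and a chosen number of genotype PCs by a robust
(Huber) linear fit; the residuals feed a Kruskal-Wallis one-way rank test
against every SNP.  Associations are partitioned into cis (SNP and gene on
one chromosome, at most ``cis_window`` apart — inclusive boundary) and trans.

The Kruskal-Wallis statistic over genotype groups i with mid-ranks r_ij:

    K = 12 / (N (N+1)) * sum_i n_i (rbar_i - (N+1)/2)^2

divided (by default) by the standard tie-correction factor
1 - sum(t^3 - t) / (N^3 - N); the p-value is the upper chi-square tail with
g - 1 degrees of freedom, g = number of non-empty genotype groups.  The scan
is vectorized: for a fixed trait the sample ranks do not depend on the SNP,
so group rank-sums for all SNPs are three indicator-matrix products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

from .io_formats import (
    ASSOCIATION_COLUMNS,
    CovariateTable,
    ExpressionMatrix,
    GenotypeMatrix,
)

logger = logging.getLogger(__name__)

HUBER_T = 1.345
RLM_MAXITER = 50
RLM_TOL = 1e-8


class KWTestResult(NamedTuple):
    K: float
    p: float
    g: int
    n_used: int


@dataclass
class AdjustedTraits:
    """Covariate/PC-adjusted expression residuals ready for rank testing."""

    sample_ids: list[str]
    genes: list
    residuals: np.ndarray  # samples x traits
    adjustment_spec: dict

    @property
    def trait_ids(self) -> list[str]:
        return [g.trait_id for g in self.genes]


# ---------------------------------------------------------------------------
# genotype QC


def filter_call_rate(G: GenotypeMatrix, min_rate: float = 0.9) -> GenotypeMatrix:
    """Drop SNPs whose fraction of called genotypes is below ``min_rate``.

    The rule is strict: a SNP called in exactly ``min_rate`` of samples is
    retained.
    """
    called = ~np.isnan(G.dosage)
    rate = called.mean(axis=0)
    keep = np.where(rate >= min_rate)[0]
    n_dropped = G.n_snps - keep.size
    if n_dropped:
        logger.info("filter_call_rate: removed %d SNPs below %.0f%% call rate",
                    n_dropped, 100 * min_rate)
    return G.take_snps(keep)


# ---------------------------------------------------------------------------
# batch normalization


def quantile_normalize_batches(E: ExpressionMatrix) -> ExpressionMatrix:
    """Force each trait's distribution to coincide between collection batches.

    Per trait, each batch's values are rank-mapped (mid-ranks at plotting
    positions (r - 1/2) / n_batch) onto the pooled empirical quantiles of
    that trait, so within-batch orderings are preserved while the per-batch
    distributions become identical (exactly so for equal batch sizes).
    """
    if E.batch_labels is None:
        raise ValueError("expression matrix carries no batch labels")
    labels = np.asarray(E.batch_labels)
    batches = sorted(set(labels))
    if len(batches) != 2:
        raise ValueError(f"expected 2 batches, found {len(batches)}")
    masks = [labels == b for b in batches]
    if not all(m.any() for m in masks):
        raise ValueError("both batches must be non-empty")
    out = np.empty_like(E.values)
    for j in range(E.n_traits):
        pooled = np.sort(E.values[:, j])
        for mask in masks:
            v = E.values[mask, j]
            nb = v.size
            if nb == 1:
                logger.info("quantile_normalize_batches: singleton batch mapped "
                            "to pooled median (trait %d)", j)
            r = stats.rankdata(v, method="average")
            q = (r - 0.5) / nb
            out[mask, j] = np.quantile(pooled, q, method="linear")
    return E.with_values(out)


# ---------------------------------------------------------------------------
# covariate / PC adjustment


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop columns (after the intercept) that do not increase the design rank."""
    keep = [0]
    for j in range(1, X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
        else:
            logger.warning("adjust_traits: dropping rank-deficient column %r",
                           names[j])
    return X[:, keep], [names[i] for i in keep]


def adjust_traits(
    E: ExpressionMatrix,
    covariates: CovariateTable,
    pcs: Optional[np.ndarray] = None,
    n_pcs: int = 0,
    pc_source: str = "none",
) -> AdjustedTraits:
    """Residualize each trait on age, sex and the leading ``n_pcs`` PCs.

    Fits a Huber M-estimated linear model per trait (tuning constant 1.345)
    and returns its residuals, re-centered to mean zero (a location shift is
    irrelevant to the rank test downstream).  ``n_pcs = 0`` is the
    "unadjusted" analysis arm, which still removes age and sex.
    """
    if list(covariates.sample_ids) != list(E.sample_ids):
        cov_index = {s: i for i, s in enumerate(covariates.sample_ids)}
        try:
            order = [cov_index[s] for s in E.sample_ids]
        except KeyError as exc:
            raise ValueError(f"sample {exc} missing from covariate table") from exc
        age = covariates.age[order]
        sex = covariates.sex[order]
    else:
        age, sex = covariates.age, covariates.sex
    n = E.n_samples
    cols = [np.ones(n), age, sex]
    names = ["intercept", "age", "sex"]
    if n_pcs > 0:
        if pcs is None:
            raise ValueError("n_pcs > 0 but no PC coordinates supplied")
        pcs = np.asarray(pcs, dtype=float)
        if pcs.shape[0] != n:
            raise ValueError("PC coordinate rows must match samples")
        if pcs.shape[1] < n_pcs:
            raise ValueError(f"requested {n_pcs} PCs but only {pcs.shape[1]} given")
        for k in range(n_pcs):
            cols.append(pcs[:, k])
            names.append(f"PC{k + 1}")
    X = np.column_stack(cols)
    X, names = _drop_collinear(X, names)
    resid = np.empty_like(E.values)
    for j in range(E.n_traits):
        y = E.values[:, j]
        fit = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=HUBER_T)).fit(
            maxiter=RLM_MAXITER, tol=RLM_TOL, conv="coefs"
        )
        r = y - X @ fit.params
        resid[:, j] = r - r.mean()
    return AdjustedTraits(
        sample_ids=list(E.sample_ids),
        genes=list(E.genes),
        residuals=resid,
        adjustment_spec={
            "covariates": names[1:],
            "n_pcs": n_pcs,
            "pc_source": pc_source if n_pcs > 0 else "none",
        },
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def _tie_factor(ranked_values: np.ndarray) -> float:
    """Tie-correction divisor 1 - sum(t^3 - t) / (N^3 - N)."""
    N = ranked_values.size
    if N < 2:
        return 1.0
    _, counts = np.unique(ranked_values, return_counts=True)
    return 1.0 - (counts**3 - counts).sum() / (N**3 - N)


def kruskal_wallis(
    values: np.ndarray,
    genotypes: np.ndarray,
    tie_correction: bool = True,
    min_group: int = 1,
) -> KWTestResult:
    """Kruskal-Wallis rank test of one trait against one SNP's genotype groups.

    Samples with a missing genotype or value are excluded pairwise; genotype
    groups smaller than ``min_group`` are dropped (reducing g).  All-tied
    values give (K=0, p=1).  Raises ``ValueError`` when fewer than 2 groups
    survive.
    """
    values = np.asarray(values, dtype=float)
    genotypes = np.asarray(genotypes, dtype=float)
    ok = ~(np.isnan(values) | np.isnan(genotypes))
    v, g = values[ok], genotypes[ok]
    levels = [lev for lev in (0.0, 1.0, 2.0) if (g == lev).sum() >= max(1, min_group)]
    use = np.isin(g, levels)
    v, g = v[use], g[use]
    if len(levels) < 2:
        raise ValueError("fewer than 2 genotype groups after exclusions")
    N = v.size
    ranks = stats.rankdata(v, method="average")
    H = 0.0
    for lev in levels:
        mask = g == lev
        H += ranks[mask].sum() ** 2 / mask.sum()
    K = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    if tie_correction:
        C = _tie_factor(v)
        if C == 0.0:  # every value tied
            return KWTestResult(0.0, 1.0, len(levels), N)
        K /= C
    K = max(K, 0.0)
    df = len(levels) - 1
    return KWTestResult(float(K), float(stats.chi2.sf(K, df)), len(levels), N)


def kw_scan_matrix(
    values: np.ndarray,
    dosage: np.ndarray,
    tie_correction: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Kruskal-Wallis scan of every (trait, SNP) pair.

    ``values``: samples x traits (no missing); ``dosage``: samples x SNPs
    (no missing).  Returns (K, p, g) where K and p are traits x SNPs and g is
    the per-SNP count of non-empty genotype groups.  Pairs with g < 2 get
    K = NaN, p = NaN.
    """
    if np.isnan(values).any() or np.isnan(dosage).any():
        raise ValueError("matrix scan path requires complete data")
    n, t = values.shape
    m = dosage.shape[1]
    R = np.empty((n, t))
    tie_div = np.empty(t)
    for j in range(t):
        R[:, j] = stats.rankdata(values[:, j], method="average")
        tie_div[j] = _tie_factor(values[:, j]) if tie_correction else 1.0
    H = np.zeros((m, t))
    g_count = np.zeros(m, dtype=int)
    for lev in (0.0, 1.0, 2.0):
        ind = (dosage == lev).astype(float)  # n x m
        n_g = ind.sum(axis=0)  # m
        nonzero = n_g > 0
        g_count += nonzero.astype(int)
        S = ind.T @ R  # m x t rank sums
        with np.errstate(invalid="ignore", divide="ignore"):
            H += np.where(nonzero[:, None], S**2 / np.where(nonzero, n_g, 1.0)[:, None], 0.0)
    K = 12.0 / (n * (n + 1)) * H - 3.0 * (n + 1)  # m x t
    K = K.T  # traits x SNPs
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(tie_div[:, None] > 0, K / np.where(tie_div > 0, tie_div, 1.0)[:, None], 0.0)
    K = np.clip(K, 0.0, None)
    df = (g_count - 1).astype(float)
    p = np.full_like(K, np.nan)
    valid = df >= 1
    if valid.any():
        p[:, valid] = stats.chi2.sf(K[:, valid], df[valid][None, :])
    all_tied = tie_div == 0.0
    if all_tied.any():
        K[all_tied, :] = 0.0
        p[np.ix_(all_tied, valid)] = 1.0
    K[:, ~valid] = np.nan
    return K, p, g_count


# ---------------------------------------------------------------------------
# full scan


def cis_trans_relation(
    gene_chrom: str, gene_pos: int, snp_chrom: str, snp_pos: int,
    cis_window: int = 1_000_000,
) -> str:
    """"cis" when gene and SNP share a chromosome within ``cis_window`` bp
    (inclusive), else "trans"."""
    if gene_chrom == snp_chrom and abs(int(snp_pos) - int(gene_pos)) <= cis_window:
        return "cis"
    return "trans"


def scan_eqtls(
    traits: AdjustedTraits,
    G: GenotypeMatrix,
    cis_window: int = 1_000_000,
    tie_correction: bool = True,
    min_shared: int = 20,
) -> pd.DataFrame:
    """Test every (trait, SNP) pair and label each record cis or trans.

    Returns a DataFrame with the association-table schema (one row per
    testable pair; pairs with fewer than two genotype groups are omitted
    with a logged count).  ``r2`` is left absent; use
    :func:`effect_size_r2` on the discoveries of interest.
    """
    shared = [s for s in traits.sample_ids if s in set(G.sample_ids)]
    if not shared:
        raise ValueError("no shared samples between traits and genotypes")
    if len(shared) < min_shared:
        logger.warning("scan_eqtls: only %d shared samples (minimum advised %d)",
                       len(shared), min_shared)
    t_idx = [traits.sample_ids.index(s) for s in shared]
    g_idx = [G.sample_ids.index(s) for s in shared]
    V = traits.residuals[t_idx, :]
    D = G.dosage[g_idx, :]

    n_skipped = 0
    if not np.isnan(D).any():
        K, p, g_count = kw_scan_matrix(V, D, tie_correction)
        valid_snps = g_count >= 2
        n_skipped = int((~valid_snps).sum()) * traits.residuals.shape[1]
    else:
        t_n, m = V.shape[1], D.shape[1]
        K = np.full((t_n, m), np.nan)
        p = np.full((t_n, m), np.nan)
        g_count = np.zeros(m, dtype=int)
        for j in range(m):
            for i in range(t_n):
                try:
                    res = kruskal_wallis(V[:, i], D[:, j], tie_correction)
                except ValueError:
                    n_skipped += 1
                    continue
                K[i, j], p[i, j] = res.K, res.p
                g_count[j] = max(g_count[j], res.g)
        valid_snps = ~np.isnan(K).all(axis=0)
    if n_skipped:
        logger.info("scan_eqtls: skipped %d pairs with <2 genotype groups",
                    n_skipped)

    snp_ids = np.asarray(G.snp_ids, dtype=object)
    snp_chrom = G.chroms
    snp_pos = G.positions
    gene_chrom = np.array([g.chrom for g in traits.genes], dtype=object)
    gene_pos = np.array([g.pos for g in traits.genes], dtype=np.int64)
    trait_ids = np.asarray(traits.trait_ids, dtype=object)

    ti, sj = np.where(~np.isnan(K))
    same_chrom = gene_chrom[ti] == snp_chrom[sj]
    within = np.abs(snp_pos[sj] - gene_pos[ti]) <= cis_window
    relation = np.where(same_chrom & within, "cis", "trans")
    df = pd.DataFrame(
        {
            "trait_id": trait_ids[ti],
            "snp_id": snp_ids[sj],
            "chrom_trait": gene_chrom[ti],
            "pos_trait": gene_pos[ti],
            "chrom_snp": snp_chrom[sj],
            "pos_snp": snp_pos[sj],
            "K": K[ti, sj],
            "p": p[ti, sj],
            "relation": relation,
            "r2": np.nan,
        },
        columns=ASSOCIATION_COLUMNS,
    )
    logger.info("scan_eqtls: %d records (%d cis, %d trans)", len(df),
                int((df["relation"] == "cis").sum()),
                int((df["relation"] == "trans").sum()))
    return df


# ---------------------------------------------------------------------------
# effect size


def effect_size_r2(trait_adj: np.ndarray, genotypes: np.ndarray) -> Optional[float]:
    """Variance explained by additive dosage under the robust linear fit.

    Fits trait_adj ~ intercept + dosage by the same Huber M-estimation and
    returns r^2 = 1 - sum(w e^2) / sum(w (y - ybar_w)^2) with the converged
    weights; ``None`` when the weighted variance vanishes.
    """
    y = np.asarray(trait_adj, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(g))
    y, g = y[ok], g[ok]
    if y.size < 3 or np.ptp(g) == 0.0:
        return None
    X = np.column_stack([np.ones(y.size), g])
    fit = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=HUBER_T)).fit(
        maxiter=RLM_MAXITER, tol=RLM_TOL, conv="coefs"
    )
    w = fit.weights
    e = y - X @ fit.params
    denom_mean = (w * y).sum() / w.sum()
    tss = (w * (y - denom_mean) ** 2).sum()
    if tss <= 0.0:
        return None
    r2 = 1.0 - (w * e**2).sum() / tss
    return float(np.clip(r2, 0.0, 1.0))


# ---------------------------------------------------------------------------
# group differential expression


def differential_expression_fraction(
    E_groupA: np.ndarray, E_groupB: np.ndarray, alpha: float = 0.01
) -> float:
    """Fraction of traits differentially expressed between two sample groups.

    Welch two-sample t-test per trait (columns); traits constant in both
    groups are excluded with a logged count.
    """
    A = np.asarray(E_groupA, dtype=float)
    B = np.asarray(E_groupB, dtype=float)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("both groups need at least 2 samples")
    const = (np.ptp(A, axis=0) == 0.0) & (np.ptp(B, axis=0) == 0.0)
    if const.any():
        logger.info("differential_expression_fraction: excluded %d constant traits",
                    int(const.sum()))
    keep = ~const
    if not keep.any():
        return 0.0
    res = stats.ttest_ind(A[:, keep], B[:, keep], axis=0, equal_var=False)
    pvals = np.asarray(res.pvalue)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    return float((pvals < alpha).mean())
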