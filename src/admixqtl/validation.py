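"""Empirical FDR, power comparison, pseudo-cis null and stratification summaries.

The FDR machinery follows the permutation recipe used in large eQTL scans:
sample ids of the whole expression matrix are shuffled (traits move
together, so trait-trait and SNP-SNP correlation survive), the scan is
repeated per permutation, and the threshold t is chosen as the largest
observed p-value at which

    FDRhat(t) = mean_perms #{null p <= t} / max(1, #{observed p <= t})

stays at or below the requested level (pi0 = 1, conservative).  cis and
trans classes get separate cutoffs.  The pseudo-cis null relocates each
trait's cis window uniformly at random and counts traits that would still be
called cis discoveries — the background rate a stratification-driven signal
would produce everywhere in the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl import AdjustedTraits, kw_scan_matrix
from .io_formats import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class FdrDecision:
    """A per-class discovery threshold at a fixed FDR level."""

    fdr_level: float
    relation: str  # "cis" or "trans"
    p_cutoff: Optional[float]  # None when no threshold qualifies
    n_discoveries: int
    expected_false: int


# ---------------------------------------------------------------------------
# permutations


def permute_expression(E: ExpressionMatrix, seed: int) -> ExpressionMatrix:
    """Shuffle the sample axis of the whole expression matrix.

    One permutation is applied to all traits jointly, breaking any
    trait-genotype association while preserving the trait-trait correlation
    structure (and, trivially, the genotype side).
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(E.n_samples)
    return E.with_values(E.values[perm, :])


def permute_residuals(traits: AdjustedTraits, seed: int) -> AdjustedTraits:
    """Same joint sample-axis shuffle, applied to adjusted residuals."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(traits.sample_ids))
    return AdjustedTraits(
        sample_ids=list(traits.sample_ids),
        genes=list(traits.genes),
        residuals=traits.residuals[perm, :],
        adjustment_spec=dict(traits.adjustment_spec),
    )


# ---------------------------------------------------------------------------
# FDR estimation


def estimate_fdr_cutoffs(
    obs_p: np.ndarray,
    null_sets: Sequence[np.ndarray],
    fdr_level: float,
    relation: str = "cis",
) -> FdrDecision:
    """Permutation-FDR threshold for one association class.

    Candidate thresholds are the sorted observed p-values; the cutoff is the
    largest one whose estimated FDR stays at or below ``fdr_level``.  With no
    qualifying threshold the decision carries ``p_cutoff=None`` and zero
    discoveries.
    """
    obs = np.sort(np.asarray(obs_p, dtype=float))
    obs = obs[~np.isnan(obs)]
    if obs.size == 0:
        return FdrDecision(fdr_level, relation, None, 0, 0)
    if not null_sets:
        raise ValueError("need at least one permutation null set")
    B = len(null_sets)
    null_sorted = [np.sort(np.asarray(s, dtype=float)) for s in null_sets]
    # average #{null <= t} at every candidate t, vectorized; the observed
    # scan counts as one more (degenerate) null set, the usual conservative
    # convention for permutation p-values, which keeps the estimator
    # calibrated under a global null
    null_counts = np.ones(obs.size)
    for s in null_sorted:
        null_counts += np.searchsorted(s, obs, side="right")
    null_counts /= B + 1
    k = np.arange(1, obs.size + 1)  # #{obs <= t} at t = k-th observed p
    # at tied observed p-values only the largest index is a coherent threshold
    is_last_of_tie = np.r_[obs[1:] != obs[:-1], True]
    fdr_hat = null_counts / np.maximum(1, k)
    qualifies = (fdr_hat <= fdr_level) & is_last_of_tie
    if not qualifies.any():
        return FdrDecision(fdr_level, relation, None, 0, 0)
    i = int(np.max(np.where(qualifies)[0]))
    cutoff = float(obs[i])
    n_disc = int(k[i])
    return FdrDecision(
        fdr_level, relation, cutoff, n_disc,
        expected_false_count(fdr_level, n_disc),
    )


def fdr_decisions_from_scan(
    observed: pd.DataFrame,
    null_scans: Sequence[pd.DataFrame],
    fdr_level: float = 0.10,
) -> dict[str, FdrDecision]:
    """Per-class (cis/trans) FDR decisions from observed and permuted scans."""
    out = {}
    for relation in ("cis", "trans"):
        obs_p = observed.loc[observed["relation"] == relation, "p"].to_numpy()
        nulls = [
            s.loc[s["relation"] == relation, "p"].to_numpy() for s in null_scans
        ]
        out[relation] = estimate_fdr_cutoffs(obs_p, nulls, fdr_level, relation)
    return out


def expected_false_count(fdr_level: float, n_discoveries: int) -> int:
    """Expected number of false discoveries: integer part of level x count."""
    if fdr_level < 0 or n_discoveries < 0:
        raise ValueError("inputs must be non-negative")
    return int(fdr_level * n_discoveries)


def relative_power(n1: int, n2: int, fdr_level: float = 0.10) -> float:
    """Relative empirical power of two analyses from their discovery counts.

    At a common FDR, (1 - FDR) n_1 and (1 - FDR) n_2 of the discoveries are
    true, so the ratio of true findings — the relative power — reduces to
    n_1 / n_2 (independent of the level).
    """
    if n2 <= 0:
        raise ValueError("n2 must be positive")
    return ((1.0 - fdr_level) * n1) / ((1.0 - fdr_level) * n2)


# ---------------------------------------------------------------------------
# pseudo-cis null


def pseudo_cis_null(
    traits: AdjustedTraits,
    G: GenotypeMatrix,
    p_cutoff: float,
    chrom_lengths: dict,
    window_bp: int = 2_000_000,
    n_runs: int = 1000,
    seed: int = 0,
    cis_window: int = 1_000_000,
    exclude_true_cis: bool = True,
    p_matrix: Optional[np.ndarray] = None,
) -> tuple[float, np.ndarray]:
    """Random-window background rate of "cis" discoveries.

    Per run, every trait is assigned a uniformly random window of width
    ``window_bp`` fully inside a random chromosome (chromosomes weighted by
    the number of placeable windows); windows overlapping the trait's true
    cis region (gene position +/- ``cis_window``) are excluded by redrawing,
    so the count measures background only.  A trait scores a pseudo
    discovery when any SNP in its window has KW p <= ``p_cutoff``.  Returns
    the mean count over runs and the per-run counts.
    """
    chroms = sorted(chrom_lengths)
    placeable = np.array(
        [max(0, chrom_lengths[c] - window_bp + 1) for c in chroms], dtype=float
    )
    if placeable.sum() <= 0:
        raise ValueError("window wider than every chromosome")
    weights = placeable / placeable.sum()
    rng = np.random.default_rng(seed)

    if p_matrix is None:
        _, p_matrix, _ = kw_scan_matrix(traits.residuals, G.dosage)
    snp_pos = G.positions
    snp_chrom = G.chroms
    # per-chromosome sorted SNP positions and their column indices
    chrom_snps = {}
    for ci, c in enumerate(chroms):
        idx = np.where(snp_chrom == c)[0]
        order = np.argsort(snp_pos[idx], kind="mergesort")
        idx = idx[order]
        chrom_snps[c] = (snp_pos[idx], idx)

    t = len(traits.genes)
    counts = np.zeros(n_runs, dtype=int)
    gene_chrom = [g.chrom for g in traits.genes]
    gene_pos = [g.pos for g in traits.genes]
    for run in range(n_runs):
        hits = 0
        for i in range(t):
            for _ in range(1000):  # rejection sampling of the window
                ci = rng.choice(len(chroms), p=weights)
                c = chroms[ci]
                start = int(rng.integers(1, chrom_lengths[c] - window_bp + 2))
                end = start + window_bp - 1
                if exclude_true_cis and c == gene_chrom[i]:
                    lo = gene_pos[i] - cis_window
                    hi = gene_pos[i] + cis_window
                    if start <= hi and end >= lo:
                        continue
                break
            else:
                raise RuntimeError("could not place a window off the cis region")
            pos_c, idx_c = chrom_snps[c]
            a = np.searchsorted(pos_c, start, side="left")
            b = np.searchsorted(pos_c, end, side="right")
            if a < b and (
                np.nan_to_num(p_matrix[i, idx_c[a:b]], nan=1.0) <= p_cutoff
            ).any():
                hits += 1
        counts[run] = hits
    return float(counts.mean()), counts


def pseudo_cis_expected_count(
    traits: AdjustedTraits,
    G: GenotypeMatrix,
    p_cutoff: float,
    chrom_lengths: dict,
    window_bp: int = 2_000_000,
    grid_step: int = 100_000,
    cis_window: int = 1_000_000,
    exclude_true_cis: bool = True,
    p_matrix: Optional[np.ndarray] = None,
) -> float:
    """Brute-force expectation of the pseudo-cis count by window enumeration.

    Walks a regular grid of window start positions over every chromosome and
    averages, per trait, the indicator that a window contains a SNP with
    p <= cutoff.  Serves as an independent check of the Monte-Carlo
    estimate in :func:`pseudo_cis_null`.
    """
    chroms = sorted(chrom_lengths)
    if p_matrix is None:
        _, p_matrix, _ = kw_scan_matrix(traits.residuals, G.dosage)
    snp_pos = G.positions
    snp_chrom = G.chroms
    total = 0.0
    gene_chrom = [g.chrom for g in traits.genes]
    gene_pos = [g.pos for g in traits.genes]
    placeable = {c: max(0, chrom_lengths[c] - window_bp + 1) for c in chroms}
    weight_sum = float(sum(placeable.values()))
    for i in range(len(traits.genes)):
        hit_prob = 0.0
        total_weight = 0.0
        for c in chroms:
            if placeable[c] <= 0:
                continue
            idx = np.where(snp_chrom == c)[0]
            order = np.argsort(snp_pos[idx], kind="mergesort")
            idx = idx[order]
            pos_c = snp_pos[idx]
            sig = idx[
                np.nan_to_num(p_matrix[i, idx], nan=1.0) <= p_cutoff
            ]
            sig_pos = np.sort(snp_pos[sig])
            starts = np.arange(1, placeable[c] + 1, grid_step)
            w = placeable[c] / weight_sum / starts.size
            for start in starts:
                end = start + window_bp - 1
                if exclude_true_cis and c == gene_chrom[i]:
                    if start <= gene_pos[i] + cis_window and end >= gene_pos[i] - cis_window:
                        continue
                total_weight += w
                a = np.searchsorted(sig_pos, start, side="left")
                b = np.searchsorted(sig_pos, end, side="right")
                if b > a:
                    hit_prob += w
        if total_weight > 0:
            total += hit_prob / total_weight
    return total


# ---------------------------------------------------------------------------
# overlap enrichment


def overlap_enrichment(
    discoveries_A: set, discoveries_B: set, universe: set
) -> tuple[int, float]:
    """Overlap of two discovery sets and a one-sided Fisher enrichment p.

    The 2x2 table classifies every universe member by membership in A and B;
    the p-value is the hypergeometric upper tail (enrichment direction).
    """
    if not universe:
        raise ValueError("empty universe")
    A = set(discoveries_A) & set(universe)
    B = set(discoveries_B) & set(universe)
    if set(discoveries_A) - set(universe) or set(discoveries_B) - set(universe):
        raise ValueError("discovery sets must be subsets of the universe")
    k = len(A & B)
    table = [
        [k, len(A - B)],
        [len(B - A), len(universe) - len(A | B)],
    ]
    _, p = stats.fisher_exact(table, alternative="greater")
    return k, float(p)


# ---------------------------------------------------------------------------
# allele-frequency disparity


def allele_freq_disparity(
    G_A: GenotypeMatrix, G_B: GenotypeMatrix, diff_threshold: float = 0.1
) -> tuple[np.ndarray, float, np.ndarray]:
    """Per-SNP allele-frequency differences between two cohorts.

    Returns (|freq_A - freq_B| per SNP, fraction of SNPs at or above
    ``diff_threshold``, per-SNP chi-square p on the 2x2 allele-count table
    without continuity correction).  SNPs with no calls in either group are
    excluded (NaN in the outputs) with a logged count.
    """
    if G_A.snp_ids != G_B.snp_ids:
        raise ValueError("cohorts must share one SNP set, in order")

    def _counts(G):
        called = ~np.isnan(G.dosage)
        alt = np.where(called, G.dosage, 0.0).sum(axis=0)
        tot = 2.0 * called.sum(axis=0)
        return alt, tot

    altA, totA = _counts(G_A)
    altB, totB = _counts(G_B)
    ok = (totA > 0) & (totB > 0)
    if (~ok).any():
        logger.info("allele_freq_disparity: excluded %d SNPs with no calls "
                    "in a group", int((~ok).sum()))
    diff = np.full(len(G_A.snps), np.nan)
    pvals = np.full(len(G_A.snps), np.nan)
    fA = altA[ok] / totA[ok]
    fB = altB[ok] / totB[ok]
    diff[ok] = np.abs(fA - fB)
    # 2x2 chi-square without continuity correction, vectorized:
    # [[altA, refA], [altB, refB]], N (ad - bc)^2 / row/col products
    a, b = altA[ok], totA[ok] - altA[ok]
    c, d = altB[ok], totB[ok] - altB[ok]
    N = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = np.where(denom > 0, N * (a * d - b * c) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    pvals[ok] = stats.chi2.sf(chi2, 1)
    fraction = float((diff[ok] >= diff_threshold).mean()) if ok.any() else float("nan")
    return diff, fraction, pvals
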