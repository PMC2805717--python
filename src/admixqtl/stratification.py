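"""Stratification detection: LD thinning, PCA, reference projection, Tracy-Widom.

Two ways of reading population structure are supported:

* *self-eigen*: EIGENSTRAT-style PCA on the study cohort's own genotypes;
* *reference-eigen*: build the PC space from a labelled reference diversity
  panel, then project study genotypes into it.  Projection reuses the
  reference panel's per-SNP normalization (center and frequency), so study
  and reference samples land in one comparable coordinate system and the
  position of a study sample between two reference population centroids
  reads off its admixture fraction directly.

The number of PCs carrying real structure is decided with the Tracy-Widom
statistic on the leading eigenvalues (Patterson-style moment-matched null).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import svd

from .io_formats import GenotypeMatrix

logger = logging.getLogger(__name__)

#: upper 5% critical value of the Tracy-Widom (beta=1) distribution
TW_CRITICAL_005 = 0.9794


@dataclass
class PCSpace:
    """A fitted PC space: normalization parameters, loadings and reference coords."""

    snp_ids: list[str]
    norm_center: np.ndarray  # per-SNP mean dosage used for centering
    norm_freqs: np.ndarray  # per-SNP posterior allele frequency used for scaling
    loadings: np.ndarray  # SNPs x D, orthonormal columns
    eigenvalues: np.ndarray  # length D, non-increasing
    ref_coords: np.ndarray  # reference samples x D
    ref_sample_ids: list[str]
    ref_pop_labels: Optional[list[str]] = None
    #: per-SNP (ref, alt) alleles, for mismatch exclusion at projection time
    snp_alleles: Optional[dict] = None
    #: full nonzero eigenvalue spectrum (for Tracy-Widom testing)
    eigenvalues_full: Optional[np.ndarray] = None
    n_samples: int = 0
    n_snps: int = 0

    def __post_init__(self) -> None:
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("loadings columns must be orthonormal")
        if (np.diff(self.eigenvalues) > 1e-10).any():
            raise ValueError("eigenvalues must be sorted non-increasing")
        if (self.eigenvalues < -1e-12).any():
            raise ValueError("eigenvalues must be non-negative")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class ProjectionResult:
    """Coordinates of projected samples in a :class:`PCSpace`."""

    sample_ids: list[str]
    coords: np.ndarray  # samples x D

    def __post_init__(self) -> None:
        if not np.isfinite(self.coords).all():
            raise ValueError("projected coordinates must be finite")


@dataclass
class TWResult:
    """Tracy-Widom statistics for the leading eigenvalues."""

    tw_stats: np.ndarray
    n_significant: int

    def __post_init__(self) -> None:
        if self.n_significant > len(self.tw_stats):
            raise ValueError("n_significant exceeds number of statistics")


# ---------------------------------------------------------------------------
# LD thinning


def thin_ld(
    G: GenotypeMatrix, r2_max: float = 0.2, window_bp: int = 1_000_000
) -> GenotypeMatrix:
    """Greedy positional LD pruning.

    Scans each chromosome left to right; a SNP is dropped when its squared
    Pearson correlation of dosages with any already-retained SNP within
    ``window_bp`` exceeds ``r2_max``.  Monomorphic SNPs (zero variance among
    called genotypes) are dropped up front since their correlation is
    undefined.  Missing genotypes are mean-imputed for the correlation only.
    """
    X = G.dosage.copy()
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    X = X - X.mean(axis=0)
    norms = np.sqrt((X**2).sum(axis=0))
    mono = norms == 0.0
    if mono.any():
        logger.info("thin_ld: dropped %d monomorphic SNPs", int(mono.sum()))

    pos = G.positions
    chroms = G.chroms
    keep: list[int] = []
    for chrom in pd_unique(chroms):
        idx = np.where(chroms == chrom)[0]
        if (np.diff(pos[idx]) < 0).any():
            raise ValueError(f"SNPs on chromosome {chrom} are not position-sorted")
        kept_here: list[int] = []
        for j in idx:
            if mono[j]:
                continue
            ok = True
            for k in reversed(kept_here):
                if pos[j] - pos[k] > window_bp:
                    break
                r = float(X[:, j] @ X[:, k]) / (norms[j] * norms[k])
                if r * r > r2_max:
                    ok = False
                    break
            if ok:
                kept_here.append(j)
        keep.extend(kept_here)
    keep.sort()
    logger.info("thin_ld: retained %d of %d SNPs", len(keep), G.n_snps)
    return G.take_snps(keep)


def pd_unique(values: np.ndarray) -> list:
    """Unique values preserving first-appearance order."""
    seen: dict = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


# ---------------------------------------------------------------------------
# normalization and PCA


def normalize_genotypes(
    G: GenotypeMatrix, freqs: Optional[np.ndarray] = None,
    center: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """EIGENSTRAT normalization of a dosage matrix.

    Per SNP j: the allele frequency is the posterior estimate
    p_j = (1 + sum_i g_ij) / (2 + 2 n_called); entries are centered at the
    mean called dosage and scaled by sqrt(p_j (1 - p_j)); missing entries
    become 0 after centering, so they contribute nothing to any PC.

    ``freqs``/``center`` override the estimates (used when normalizing a
    study cohort with the reference panel's parameters).

    Returns ``(X_norm, norm_center, norm_freqs, kept)`` where ``kept`` is a
    boolean mask of SNPs retained (all-missing columns are dropped).
    """
    X = np.asarray(G.dosage, dtype=float)
    called = ~np.isnan(X)
    n_called = called.sum(axis=0)
    kept = n_called > 0
    if (~kept).any():
        logger.info("normalize_genotypes: dropped %d all-missing SNPs",
                    int((~kept).sum()))
    X = X[:, kept]
    called = called[:, kept]
    n_called = n_called[kept]
    sums = np.where(np.isnan(X), 0.0, X).sum(axis=0)
    if center is None:
        center_ = sums / n_called
    else:
        center_ = np.asarray(center, dtype=float)[kept]
    if freqs is None:
        freqs_ = (1.0 + sums) / (2.0 + 2.0 * n_called)
    else:
        freqs_ = np.asarray(freqs, dtype=float)[kept]
    scale = np.sqrt(freqs_ * (1.0 - freqs_))
    Xn = (X - center_) / scale
    Xn[~called] = 0.0
    return Xn, center_, freqs_, kept


def fit_pca(
    G: GenotypeMatrix,
    n_components: int = 10,
    freqs: Optional[np.ndarray] = None,
) -> PCSpace:
    """Self-eigen PCA of a genotype panel (EIGENSTRAT normalization + SVD).

    Loadings are the top right singular vectors of the normalized matrix,
    eigenvalues the squared singular values over (n - 1), and the panel's own
    coordinates ``ref_coords = X_norm @ loadings`` (= U S), so projecting the
    panel into its own space reproduces them exactly.
    """
    n = G.n_samples
    if n <= 2:
        raise ValueError("need more than 2 samples for PCA")
    Xn, center, phat, kept = normalize_genotypes(G, freqs=freqs)
    m = Xn.shape[1]
    U, s, Vt = svd(Xn, full_matrices=False)
    nonzero = s > s[0] * 1e-12 if s.size else np.zeros(0, bool)
    rank = int(nonzero.sum())
    D = n_components
    if D > rank:
        logger.warning("fit_pca: requested %d components but rank is %d", D, rank)
        D = rank
    if m < D:
        raise ValueError("need more SNPs than requested components")
    eig_full = (s[:rank] ** 2) / (n - 1)
    loadings = Vt[:D].T
    coords = U[:, :D] * s[:D]
    snp_ids = [sid for sid, k in zip(G.snp_ids, kept) if k]
    return PCSpace(
        snp_ids=snp_ids,
        norm_center=center,
        norm_freqs=phat,
        loadings=loadings,
        eigenvalues=eig_full[:D],
        ref_coords=coords,
        ref_sample_ids=list(G.sample_ids),
        ref_pop_labels=None if G.pop_labels is None else list(G.pop_labels),
        snp_alleles={
            s.id: (s.ref_allele, s.alt_allele) for s, k in zip(G.snps, kept) if k
        },
        eigenvalues_full=eig_full,
        n_samples=n,
        n_snps=m,
    )


def project_onto_space(
    space: PCSpace, G_study: GenotypeMatrix, min_overlap: int = 10_000
) -> ProjectionResult:
    """Project study genotypes into a fitted PC space (reference-eigen step 2).

    Study dosages are normalized with the *reference* panel's per-SNP center
    and frequency, then multiplied by the loadings.  Only SNPs shared by id
    are used; loadings of unshared SNPs are dropped, which leaves projected
    coordinates comparable to ``ref_coords`` up to the mass of the missing
    loadings (with full overlap they are exactly comparable).
    """
    study_index = {sid: j for j, sid in enumerate(G_study.snp_ids)}
    shared_space_idx, shared_study_idx = [], []
    n_mismatch = 0
    for i, sid in enumerate(space.snp_ids):
        j = study_index.get(sid)
        if j is None:
            continue
        if space.snp_alleles is not None:
            snp = G_study.snps[j]
            expect = space.snp_alleles.get(sid)
            if expect is not None and expect != (snp.ref_allele, snp.alt_allele):
                n_mismatch += 1
                continue
        shared_space_idx.append(i)
        shared_study_idx.append(j)
    if n_mismatch:
        logger.info("project_onto_space: excluded %d allele-mismatched SNPs",
                    n_mismatch)
    if len(shared_space_idx) < min_overlap:
        logger.warning(
            "project_onto_space: only %d SNPs shared with the PC space "
            "(minimum recommended %d)", len(shared_space_idx), min_overlap,
        )
    if not shared_space_idx:
        raise ValueError("no SNPs shared between study and PC space")
    si = np.asarray(shared_space_idx)
    ji = np.asarray(shared_study_idx)
    X = G_study.dosage[:, ji]
    called = ~np.isnan(X)
    center = space.norm_center[si]
    scale = np.sqrt(space.norm_freqs[si] * (1.0 - space.norm_freqs[si]))
    Xn = (X - center) / scale
    Xn[~called] = 0.0
    coords = Xn @ space.loadings[si]
    return ProjectionResult(sample_ids=list(G_study.sample_ids), coords=coords)


# ---------------------------------------------------------------------------
# Tracy-Widom


def _tw_moments(m: int, n_eff: float) -> tuple[float, float]:
    """Center and scale of the largest-eigenvalue null (m samples, n_eff markers)."""
    a = np.sqrt(n_eff - 1.0)
    b = np.sqrt(float(m))
    mu = (a + b) ** 2 / n_eff
    sigma = (a + b) / n_eff * (1.0 / a + 1.0 / b) ** (1.0 / 3.0)
    return mu, sigma


def tracy_widom_count(
    eigenvalues: np.ndarray,
    n_samples: int,
    n_snps: int,
    max_test: Optional[int] = None,
    rule: str = "critical",
    critical: float = TW_CRITICAL_005,
) -> TWResult:
    """Tracy-Widom statistics for leading eigenvalues and the significant count.

    For the i-th eigenvalue the remaining spectrum is treated as a fresh
    dataset of ``m - i`` dimensions; the effective marker count is estimated
    from the eigenvalue moments (n' = (m+1) S1^2 / ((m-1) S2 - S1^2)), the
    eigenvalue is normalized to l = m lambda / S1 and standardized with the
    moment-matched center and scale.  ``n_significant`` counts *leading
    consecutive* statistics that pass the decision rule:

    * ``rule="critical"`` (default): statistic > the 5% critical value 0.9794;
    * ``rule="positive"``: statistic > 0 (the looser convention).
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples for Tracy-Widom testing")
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 2:
        raise ValueError("need at least 2 eigenvalues")
    if (np.diff(lam) > 1e-10 * max(lam[0], 1.0)).any():
        raise ValueError("eigenvalues must be sorted non-increasing")
    # drop numerically-zero eigenvalues (centering removes one dimension)
    lam = lam[lam > lam[0] * 1e-12]
    m_total = lam.size
    if max_test is None:
        max_test = min(m_total - 1, 20)
    stats = np.full(max_test, -np.inf)
    for i in range(max_test):
        tail = lam[i:]
        mi = m_total - i
        if mi < 2:
            break
        s1 = tail.sum()
        s2 = (tail**2).sum()
        denom = (mi - 1.0) * s2 - s1 * s1
        if denom <= 0:
            # spectrum flatter than the null allows: not significant
            continue
        n_eff = (mi + 1.0) * s1 * s1 / denom
        # the effective marker count cannot exceed the actual count; the
        # moment estimate overshoots it for uncorrelated markers
        if n_snps:
            n_eff = min(n_eff, float(n_snps))
        if n_eff <= 1.0:
            continue
        ell = mi * tail[0] / s1
        mu, sigma = _tw_moments(mi, n_eff)
        stats[i] = (ell - mu) / sigma
    threshold = critical if rule == "critical" else 0.0
    if rule not in ("critical", "positive"):
        raise ValueError("rule must be 'critical' or 'positive'")
    n_sig = 0
    for s in stats:
        if s > threshold:
            n_sig += 1
        else:
            break
    return TWResult(tw_stats=stats, n_significant=n_sig)


# ---------------------------------------------------------------------------
# admixture magnitude


def population_centroid(
    space: PCSpace, pop_label: str, n_dims: int = 2
) -> np.ndarray:
    """Mean reference coordinates of one labelled population (leading dims)."""
    if space.ref_pop_labels is None:
        raise ValueError("PC space carries no reference population labels")
    mask = np.array([lab == pop_label for lab in space.ref_pop_labels])
    if not mask.any():
        raise ValueError(f"no reference samples labelled {pop_label!r}")
    return space.ref_coords[mask, :n_dims].mean(axis=0)


def ancestry_fraction(
    proj: ProjectionResult,
    centroid_A: np.ndarray,
    centroid_B: np.ndarray,
) -> np.ndarray:
    """Position of each sample along the A-to-B axis, clamped to [0, 1].

    The scalar projection of (x - centroid_A) onto (centroid_B - centroid_A)
    over |centroid_B - centroid_A|: 0 means "at A", 1 "at B", 0.5 midway —
    i.e. the admixture magnitude read directly off the PC space.
    """
    a = np.asarray(centroid_A, dtype=float)
    b = np.asarray(centroid_B, dtype=float)
    axis = b - a
    norm2 = float(axis @ axis)
    if norm2 == 0.0:
        raise ValueError("centroids coincide; ancestry axis undefined")
    d = proj.coords[:, : a.size] - a
    frac = (d @ axis) / norm2
    return np.clip(frac, 0.0, 1.0)
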