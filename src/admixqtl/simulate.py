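"""Synthetic reference panels, admixed cohorts and expression with planted eQTLs.

The generator is a Balding-Nichols test-bed for stratification methods:

* a multi-population reference panel with tight per-population clusters
  (ancestral allele frequency p ~ Uniform(0.1, 0.9); population-k frequency
  p_k ~ Beta(p (1-F_k)/F_k, (1-p)(1-F_k)/F_k); genotypes Binomial(2, p_k));
* an admixed study cohort whose per-individual ancestry proportions q are
  Dirichlet(alpha), so each individual's allele frequency is sum_k q_k p_k;
* expression traits with planted cis effects, a continuous ancestry-driven
  shift (proportional to q_1, the dose of the first ancestry), age and sex
  covariate effects, Gaussian noise, and two collection batches.

SNPs are independent (no LD) by default; an optional block-copy LD mode
duplicates each SNP into a local block of near-copies so that LD thinning has
something to remove.  Ground truth (admixture proportions, causal SNPs,
effect sizes) is returned alongside the data for parameter-recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CovariateTable,
    ExpressionMatrix,
    GeneRecord,
    GenotypeMatrix,
    SNPRecord,
)

logger = logging.getLogger(__name__)

#: default chromosome map: 5 chromosomes x 50 Mbp
DEFAULT_CHROM_LENGTHS = {str(c): 50_000_000 for c in range(1, 6)}

# sub-generator seed offsets from the master seed (documented contract)
_PANEL_OFFSET = 1
_COHORT_OFFSET = 2
_EXPRESSION_OFFSET = 3


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the small-admixed-cohort regime this package targets:
    a two-way admixed cohort of 60 (roughly the size where stratification
    adjustment trades off hardest against power), a reference panel of 100
    per population at F_ST = 0.2 (continental-scale drift), and cis effects
    sized so a planted eQTL explains about half the trait variance, matching
    the effect-size range reported for strong liver cis-eQTLs.
    """

    n_populations: int = 2
    fst: Sequence[float] = (0.2, 0.2)
    n_ref_per_pop: int = 100
    n_study: int = 60
    n_snps: int = 2000
    admix_dirichlet_alpha: Sequence[float] = (1.0, 1.0)
    n_traits: int = 100
    n_cis_true: int = 30
    cis_beta: float = 1.4
    ancestry_effect_sd: float = 1.0
    age_beta: float = 0.02
    sex_beta: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0
    chrom_lengths: dict = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    cis_window: int = 1_000_000
    #: restrict causal SNPs to those with inter-population frequency
    #: difference >= this value (None = unrestricted)
    causal_min_freq_diff: Optional[float] = None
    #: LD block size (1 = independent SNPs; >1 copies each SNP into a block)
    ld_block_size: int = 1
    #: location/scale distortion applied to the second collection batch
    batch_shift: float = 0.0
    batch_scale: float = 1.0

    def __post_init__(self) -> None:
        K = self.n_populations
        if K < 2:
            raise ValueError("need at least 2 populations")
        self.fst = tuple(float(f) for f in self.fst)
        if len(self.fst) != K:
            raise ValueError("fst must have one entry per population")
        if not all(0.0 < f < 1.0 for f in self.fst):
            raise ValueError("fst entries must be in (0, 1)")
        self.admix_dirichlet_alpha = tuple(
            float(a) for a in self.admix_dirichlet_alpha
        )
        if len(self.admix_dirichlet_alpha) != K:
            raise ValueError("admix_dirichlet_alpha length must equal n_populations")
        if self.n_cis_true > self.n_traits:
            raise ValueError("n_cis_true cannot exceed n_traits")
        for name in ("n_ref_per_pop", "n_study", "n_snps", "n_traits"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrueEqtlTable:
    """Ground truth: one causal SNP per cis trait, none for null traits."""

    table: pd.DataFrame  # trait_id, causal_snp_id, beta, ancestry_effect

    @property
    def causal_traits(self) -> list[str]:
        return list(self.table.loc[self.table["causal_snp_id"].notna(), "trait_id"])


@dataclass
class AdmixedCohort:
    """Study genotypes with ground-truth admixture, plus the reference panel."""

    genotypes: GenotypeMatrix
    true_Q: np.ndarray  # samples x K, rows sum to 1
    covariates: CovariateTable
    reference: GenotypeMatrix  # carries pop_labels
    ancestral_freqs: np.ndarray  # K x SNPs (population frequencies p_k)

    def __post_init__(self) -> None:
        if not np.allclose(self.true_Q.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("true_Q rows must sum to 1")
        if ((self.ancestral_freqs <= 0) | (self.ancestral_freqs >= 1)).any():
            raise ValueError("ancestral frequencies must lie in (0, 1)")


def _snp_positions(n_snps: int, chrom_lengths: dict, rng: np.random.Generator):
    """Uniform SNP placement over the chromosome map, sorted within chromosome."""
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_snps, p=lengths / lengths.sum())
    pos = np.array(
        [rng.integers(1, chrom_lengths[chroms[i]] + 1) for i in chrom_idx],
        dtype=np.int64,
    )
    order = np.lexsort((pos, chrom_idx))
    return [chroms[i] for i in chrom_idx[order]], pos[order]


def _balding_nichols_freqs(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Population allele frequencies (K x SNPs) under Balding-Nichols drift."""
    K, m = config.n_populations, config.n_snps
    p_anc = rng.uniform(0.1, 0.9, size=m)
    freqs = np.empty((K, m))
    for k, F in enumerate(config.fst):
        shape = (1.0 - F) / F
        pk = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        # Beta draws can hit 0/1 in floating point; resample those SNPs
        bad = (pk <= 0.0) | (pk >= 1.0)
        while bad.any():
            pk[bad] = rng.beta(p_anc[bad] * shape, (1.0 - p_anc[bad]) * shape)
            bad = (pk <= 0.0) | (pk >= 1.0)
        freqs[k] = pk
    return freqs


def _make_snp_records(config: SimulationConfig, rng: np.random.Generator):
    chroms, pos = _snp_positions(config.n_snps, config.chrom_lengths, rng)
    return [
        SNPRecord(id=f"snp{j:06d}", chrom=chroms[j], pos=int(pos[j]),
                  ref_allele="A", alt_allele="G")
        for j in range(config.n_snps)
    ]


def _apply_ld_blocks(
    dosage: np.ndarray, snps: list[SNPRecord], block: int, rng: np.random.Generator
):
    """Block-copy LD mode: each SNP becomes a block of near-duplicates.

    Copies flip a small fraction of genotypes so pairwise r^2 within a block
    is high but below 1; spacing within a block is 10 kb.
    """
    if block <= 1:
        return dosage, snps
    cols, recs = [], []
    for j, s in enumerate(snps):
        for b in range(block):
            g = dosage[:, j].copy()
            if b > 0:
                flip = rng.random(g.shape[0]) < 0.02
                g[flip] = rng.integers(0, 3, size=int(flip.sum()))
            cols.append(g)
            recs.append(
                SNPRecord(id=f"{s.id}_b{b}", chrom=s.chrom, pos=s.pos + 10_000 * b,
                          ref_allele=s.ref_allele, alt_allele=s.alt_allele)
            )
    order = np.lexsort(
        ([r.pos for r in recs], [r.chrom for r in recs])
    )
    return (
        np.column_stack([cols[i] for i in order]),
        [recs[i] for i in order],
    )


def generate_reference_panel(
    config: SimulationConfig, seed: Optional[int] = None
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate the multi-population reference panel.

    Returns the labelled panel and the K x SNPs matrix of population allele
    frequencies used to draw it (the admixed cohort is built from the same
    frequencies so panel and cohort share one genealogy).
    """
    master = config.seed if seed is None else seed
    rng = np.random.default_rng(master + _PANEL_OFFSET)
    freqs = _balding_nichols_freqs(config, rng)
    snps = _make_snp_records(config, rng)
    K, m = freqs.shape
    n = config.n_ref_per_pop
    dosage = np.empty((K * n, m), dtype=float)
    labels, ids = [], []
    for k in range(K):
        dosage[k * n : (k + 1) * n] = rng.binomial(2, freqs[k], size=(n, m))
        labels += [f"pop{k}"] * n
        ids += [f"ref_pop{k}_{i:04d}" for i in range(n)]
    panel = GenotypeMatrix(sample_ids=ids, snps=snps, dosage=dosage, pop_labels=labels)
    if config.ld_block_size > 1:
        d, s = _apply_ld_blocks(panel.dosage, panel.snps, config.ld_block_size, rng)
        panel = GenotypeMatrix(sample_ids=ids, snps=s, dosage=d, pop_labels=labels)
    return panel, freqs


def generate_admixed_cohort(
    config: SimulationConfig,
    ancestral_freqs: np.ndarray,
    seed: Optional[int] = None,
    reference: Optional[GenotypeMatrix] = None,
) -> AdmixedCohort:
    """Simulate the admixed study cohort on top of the panel's frequencies.

    Per individual: q ~ Dirichlet(alpha); per SNP the individual allele
    frequency is sum_k q_k p_k and the dosage is Binomial(2, that).  Age is
    Uniform(20, 80) years, sex Bernoulli(1/2).
    """
    master = config.seed if seed is None else seed
    rng = np.random.default_rng(master + _COHORT_OFFSET)
    K, m = ancestral_freqs.shape
    if len(config.admix_dirichlet_alpha) != K:
        raise ValueError("alpha length does not match number of populations")
    n = config.n_study
    Q = rng.dirichlet(config.admix_dirichlet_alpha, size=n)
    indiv_freq = Q @ ancestral_freqs  # n x m
    dosage = rng.binomial(2, indiv_freq).astype(float)
    if reference is None:
        reference, _ = generate_reference_panel(config, seed=master)
    # study SNP metadata mirrors the panel's pre-LD-block records
    snp_rng = np.random.default_rng(master + _PANEL_OFFSET)
    _balding_nichols_freqs(config, snp_rng)  # advance state identically to panel
    snps = _make_snp_records(config, snp_rng)
    ids = [f"study_{i:04d}" for i in range(n)]
    geno = GenotypeMatrix(sample_ids=ids, snps=snps, dosage=dosage)
    cov = CovariateTable(
        sample_ids=ids,
        age=rng.uniform(20.0, 80.0, size=n),
        sex=(rng.random(n) < 0.5).astype(float),
    )
    return AdmixedCohort(
        genotypes=geno,
        true_Q=Q,
        covariates=cov,
        reference=reference,
        ancestral_freqs=ancestral_freqs,
    )


def beta_for_r2(target_r2: float, noise_sd: float, dosage_sd: float) -> float:
    """Effect size giving expected variance-explained ``target_r2``.

    With y = beta * g + noise, r^2 = beta^2 var(g) / (beta^2 var(g) + noise^2),
    so beta = noise_sd * sqrt(r2 / (1 - r2)) / sd(g).
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0, 1)")
    if dosage_sd <= 0:
        raise ValueError("dosage_sd must be positive")
    return noise_sd * np.sqrt(target_r2 / (1.0 - target_r2)) / dosage_sd


def generate_expression(
    cohort: AdmixedCohort,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> tuple[ExpressionMatrix, TrueEqtlTable]:
    """Simulate expression traits with planted cis effects and ancestry shifts.

    Trait model (per sample):

        y = beta * dosage(causal SNP)            [cis traits only]
            + ancestry_effect * q_1
            + age_beta * age + sex_beta * sex
            + Normal(0, noise_sd)

    Each cis trait's gene is placed within the cis window of its causal SNP;
    null traits get uniformly random gene positions.  Samples are split into
    two collection batches; the second batch can carry a location/scale
    distortion (config.batch_shift / batch_scale) for the normalization step
    to undo.
    """
    master = config.seed if seed is None else seed
    rng = np.random.default_rng(master + _EXPRESSION_OFFSET)
    G = cohort.genotypes
    n, m = G.dosage.shape
    t = config.n_traits

    eligible = np.arange(m)
    if config.causal_min_freq_diff is not None:
        diffs = np.abs(
            cohort.ancestral_freqs.max(axis=0) - cohort.ancestral_freqs.min(axis=0)
        )
        eligible = np.where(diffs >= config.causal_min_freq_diff)[0]
        if eligible.size < config.n_cis_true:
            raise ValueError(
                "not enough SNPs pass causal_min_freq_diff for the requested "
                "number of cis traits"
            )
    causal_idx = rng.choice(eligible, size=config.n_cis_true, replace=False)

    positions = G.positions
    chroms = G.chroms
    genes: list[GeneRecord] = []
    rows = []
    values = np.empty((n, t))
    q1 = cohort.true_Q[:, 0]
    age, sex = cohort.covariates.age, cohort.covariates.sex
    chrom_names = sorted(config.chrom_lengths)

    for j in range(t):
        trait_id = f"trait{j:05d}"
        ancestry_effect = rng.normal(0.0, config.ancestry_effect_sd)
        y = (
            ancestry_effect * q1
            + config.age_beta * age
            + config.sex_beta * sex
            + rng.normal(0.0, config.noise_sd, size=n)
        )
        if j < config.n_cis_true:
            cj = int(causal_idx[j])
            snp = G.snps[cj]
            # gene sits within the cis window of its causal SNP
            lo = max(1, snp.pos - config.cis_window)
            hi = min(config.chrom_lengths.get(snp.chrom, snp.pos), snp.pos + config.cis_window)
            gpos = int(rng.integers(lo, hi + 1))
            genes.append(GeneRecord(trait_id, f"GENE{j}", snp.chrom, gpos))
            y = y + config.cis_beta * np.nan_to_num(G.dosage[:, cj])
            rows.append(
                {"trait_id": trait_id, "causal_snp_id": snp.id,
                 "beta": config.cis_beta, "ancestry_effect": ancestry_effect}
            )
        else:
            c = chrom_names[int(rng.integers(len(chrom_names)))]
            gpos = int(rng.integers(1, config.chrom_lengths[c] + 1))
            genes.append(GeneRecord(trait_id, f"GENE{j}", c, gpos))
            rows.append(
                {"trait_id": trait_id, "causal_snp_id": None,
                 "beta": 0.0, "ancestry_effect": ancestry_effect}
            )
        values[:, j] = y

    half = n // 2
    batches = ["site1"] * half + ["site2"] * (n - half)
    if config.batch_shift != 0.0 or config.batch_scale != 1.0:
        values[half:] = values[half:] * config.batch_scale + config.batch_shift

    expr = ExpressionMatrix(
        sample_ids=list(G.sample_ids),
        genes=genes,
        values=values,
        batch_labels=batches,
    )
    return expr, TrueEqtlTable(table=pd.DataFrame(rows))


def generate_study(
    config: SimulationConfig, seed: Optional[int] = None
) -> tuple[AdmixedCohort, ExpressionMatrix, TrueEqtlTable]:
    """One-call generator: reference panel, admixed cohort and expression."""
    master = config.seed if seed is None else seed
    panel, freqs = generate_reference_panel(config, seed=master)
    cohort = generate_admixed_cohort(config, freqs, seed=master, reference=panel)
    expr, truth = generate_expression(cohort, config, seed=master)
    return cohort, expr, truth
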