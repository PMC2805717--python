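import numpy as np
import pytest

from admixqtl import SimulationConfig, generate_study

VCF_SMALL = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=50000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\tsnpA\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t2000\tsnpB\tC\tT\t.\tPASS\t.\tGT\t0/1\t./.\t1/1
1\t3000\tindelX\tC\tCT\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1
1\t4000\tsnpC\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1
"""


@pytest.fixture
def vcf_path(tmp_path):
    p = tmp_path / "small.vcf"
    p.write_text(VCF_SMALL)
    return p


@pytest.fixture(scope="session")
def small_study():
    """A compact two-way admixed study with planted cis effects."""
    cfg = SimulationConfig(
        n_study=60, n_snps=400, n_traits=40, n_cis_true=15, seed=7
    )
    cohort, expr, truth = generate_study(cfg)
    return cfg, cohort, expr, truth


@pytest.fixture(scope="session")
def null_study():
    """Global-null cohort: no genetic effects, no ancestry expression shifts."""
    cfg = SimulationConfig(
        n_study=60, n_snps=300, n_traits=40, n_cis_true=0,
        ancestry_effect_sd=0.0, seed=13,
    )
    cohort, expr, truth = generate_study(cfg)
    return cfg, cohort, expr, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
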