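import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from exoqc import SimulationConfig, simulate_array, simulate_cohort, simulate_imputed
from exoqc.model import CohortDataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_small():
    """A compact cohort (80 samples x 2,500 variants) with ground truth."""
    cfg = SimulationConfig(n_samples=80, n_variants=2500, array_n_samples=8)
    return simulate_cohort(cfg, seed=13)


@pytest.fixture(scope="session")
def array_small(sim_small):
    """Error-free array gold standard for 8 samples of the small cohort."""
    dataset, truth = sim_small
    return simulate_array(truth, dataset.samples[:8], array_error_rate=0.0, seed=14)


@pytest.fixture(scope="session")
def sim_default():
    """The full-size study-condition cohort (200 samples x 20,000 variants)."""
    return simulate_cohort(SimulationConfig(), seed=11)


@pytest.fixture(scope="session")
def imputed_small():
    cfg = SimulationConfig(n_samples=120, imputed_n_variants=2500)
    return simulate_imputed(cfg, seed=17)


@pytest.fixture
def tiny_dataset():
    """Hand-built 4-sample, 3-variant dataset."""
    return CohortDataset.from_variant_records(
        samples=["A", "B", "C", "D"],
        records=[
            {"chrom": "1", "pos": 100, "ref": "A", "alt": "G", "vqsr_pass": True,
             "gt": [0, 1, 2, -1], "dp": [10, 9, 30, -1], "gq": [25, 50, 19, -1]},
            {"chrom": "1", "pos": 200, "ref": "C", "alt": "A", "vqsr_pass": False,
             "gt": [1, 1, 0, 0], "dp": [7, 50, 12, 15], "gq": [50, 99, 40, 41]},
            {"chrom": "2", "pos": 50, "ref": "T", "alt": "C", "vqsr_pass": True,
             "gt": [-1, -1, -1, -1]},
        ],
    )


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")


VCF_HEADER = [
    "##fileformat=VCFv4.2",
    '##FILTER=<ID=VQSRTrancheSNP99.90to100.00,Description="tranche">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Qual">',
    "##contig=<ID=1>",
]


@pytest.fixture
def fixture_vcf(tmp_path):
    """3 samples; 2 biallelic SNVs, 1 indel, 1 triallelic SNV, 1 tranche-failed."""
    lines = VCF_HEADER + [
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3",
        "1\t100\t.\tA\tG\t50\tPASS\t.\tGT:DP:GQ\t0/1:10:30\t1/1:.:20\t./.:.:.",
        "1\t200\t.\tC\tT\t50\t.\t.\tGT:DP:GQ\t0/.:5:10\t0/0:8:15\t1/0:9:40",
        "1\t300\t.\tG\tGA\t50\tPASS\t.\tGT:DP:GQ\t0/1:10:30\t0/0:4:5\t0/0:6:7",
        "1\t400\t.\tG\tA,T\t50\tVQSRTrancheSNP99.90to100.00\t.\tGT:DP:GQ\t1/2:10:30\t0/2:4:5\t0/0:6:7",
    ]
    path = tmp_path / "fixture.vcf"
    write_lines(path, lines)
    return path
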