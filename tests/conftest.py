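import numpy as np
import pytest

from aei.ingest import AllelicCount, Locus
from aei.simulate import SimulationConfig, simulate_cohort

LOCUS = Locus("3", 178936091, "G")


def make_count(sample, assay, wt, mut, mutation_class="missense", locus=LOCUS):
    return AllelicCount(sample, locus, assay, wt, mut, mutation_class)


@pytest.fixture(scope="session")
def small_cohort():
    """50-sample cohort with mixed copy-number and cis effects."""
    cfg = SimulationConfig(n_samples=50, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def counts_tsv(tmp_path):
    path = tmp_path / "counts.tsv"
    path.write_text(
        "sample_id\tchrom\tpos\tassay\twt_reads\tmut_reads\tmutation_class\n"
        "T01\t3\t178936091\tDNA\t50\t45\tmissense\n"
        "T01\t3\t178936091\tRNA\t30\t70\tmissense\n"
    )
    return path
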