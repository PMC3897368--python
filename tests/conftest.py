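import pytest
from hypothesis import settings

from h3k4diff import PeakCallParams, SimConfig, call_peaks, simulate

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_config():
    """The pinned study conditions: one 10-Mb chromosome, 300 genes,
    10/10/15/15 planted differences at fold 3, no amplitude jitter."""
    return SimConfig(seed=42, amplitude_jitter=0.0)


@pytest.fixture(scope="session")
def study_sim(study_config):
    return simulate(study_config)


@pytest.fixture(scope="session")
def called_peaks(study_sim):
    """Peaks re-called from the simulated coverage with default parameters."""
    out = {}
    for geno in ("wt", "ko"):
        treatment, control = study_sim.tracks[geno]
        out[geno] = call_peaks(treatment, control, PeakCallParams())
    return out


@pytest.fixture(scope="session")
def small_config():
    """A light configuration for tests that re-run the generator."""
    return SimConfig(n_chromosomes=2, chrom_length=2_000_000, n_genes=60,
                     n_unique_wt=3, n_unique_ko=3, n_preferential_wt=4,
                     n_preferential_ko=4, reads_per_condition=12_000, seed=7)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate(small_config)
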