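import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bimodalbind.genomic_io import Genome, Peak, PeakSet
from bimodalbind.synthetic import SyntheticSpec, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_genome() -> Genome:
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    return Genome({"chr1": seq})


@pytest.fixture
def tiny_peaks() -> PeakSet:
    peaks = [
        Peak("chr1", 1000, 1200, intensity=5.0, name="p1"),
        Peak("chr1", 2000, 2150, intensity=2.0, name="p2"),
        Peak("chr1", 3500, 3700, intensity=7.5, name="p3"),
    ]
    return PeakSet("toyTF", "ESC", peaks)


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced synthetic study shared across tests (read-only)."""
    spec = SyntheticSpec(seed=11, chrom_length=400_000, n_peaks=400, n_tss=100)
    return generate_dataset(spec)
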