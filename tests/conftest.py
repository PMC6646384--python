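import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from g4ori import GenomicInterval, OriginRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=200):
    """Small random interval sets for oracle comparisons."""
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, max_pos - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def make_origins(n, spacing=3000, chrom="chr1", halfwidth=150, first_is=2000):
    """Evenly spaced origins with an IS, no sequence attached."""
    out = []
    for i in range(n):
        p = first_is + i * spacing
        out.append(
            OriginRecord(
                GenomicInterval(chrom, p - halfwidth, p + halfwidth),
                p,
                frozenset(),
                f"origin_{i + 1}",
            )
        )
    return out


@pytest.fixture(scope="session")
def small_genome_sim():
    """One small simulated genome shared by read-only tests."""
    from g4ori import simulate_genome_with_g4

    return simulate_genome_with_g4(
        n_chrom=2, chrom_len=200_000, origin_count=40, seed=42
    )
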