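import numpy as np
import pytest

from epibridge.genomic_io import GeneModel, HotspotInterval, HotspotTrack
from epibridge.synthetic_data import SimConfig, simulate_epigenome


@pytest.fixture(scope="session")
def small_sim():
    """A 200-gene epigenome at default study conditions."""
    return simulate_epigenome(SimConfig(n_genes=200, seed=7))


@pytest.fixture(scope="session")
def recovery_sim():
    """Balanced classes (~300 genes each) for geometry-recovery checks."""
    config = SimConfig(
        n_genes=1200,
        n_chroms=4,
        chrom_length=8_000_000,
        response_class_probs={
            "up_strong": 0.25, "up_moderate": 0.25, "no_change": 0.25, "down": 0.25,
        },
        seed=2024,
    )
    return simulate_epigenome(config)


def random_track(rng: np.random.Generator, n: int, chrom: str = "chr1",
                 span: tuple[int, int] = (0, 5000), max_len: int = 400) -> HotspotTrack:
    """Small random hotspot track for oracle comparisons."""
    intervals = []
    for _ in range(n):
        start = int(rng.integers(span[0], span[1]))
        length = int(rng.integers(1, max_len))
        score = float(rng.uniform(0.1, 10.0))
        intervals.append(HotspotInterval(chrom, start, start + length, score))
    return HotspotTrack(intervals)


def random_gene(rng: np.random.Generator, chrom: str = "chr1",
                tss_span: tuple[int, int] = (1000, 4000)) -> GeneModel:
    tss = int(rng.integers(*tss_span))
    length = int(rng.integers(500, 3000))
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "+":
        return GeneModel(f"g{tss}", chrom, tss, tss + length, "+")
    return GeneModel(f"g{tss}", chrom, max(tss - length + 1, 0), tss + 1, "-")
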