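import numpy as np
import pytest

from hotspotcnv.core_io import (
    GenomicInterval,
    Probe,
    ProbeDesign,
    RegionClass,
)


def make_design(starts_by_chrom: dict[str, list[int]], probe_len: int = 50) -> ProbeDesign:
    """Build a design from probe start positions per chromosome."""
    probes = []
    i = 0
    for chrom, starts in starts_by_chrom.items():
        for s in starts:
            i += 1
            probes.append(
                Probe(
                    f"p{i:04d}",
                    GenomicInterval(chrom, s, s + probe_len - 1),
                    RegionClass.BACKBONE,
                )
            )
    return ProbeDesign(probes)


@pytest.fixture
def uniform_design():
    """200 probes per chromosome at regular 10-kbp spacing on two chromosomes."""
    return make_design(
        {
            "chr1": list(range(100_000, 100_000 + 200 * 10_000, 10_000)),
            "chr2": list(range(50_000, 50_000 + 200 * 10_000, 10_000)),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
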