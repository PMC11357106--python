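import numpy as np
import pytest

from chromfate.genomic_io import GenomicInterval, Peak


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_peaks(rng, n, chrom_lengths, width=200, prefix="p"):
    """Uniformly placed fixed-width peaks, summit at the midpoint."""
    out, chroms = [], list(chrom_lengths)
    for i in range(n):
        c = chroms[rng.integers(len(chroms))]
        s = int(rng.integers(0, chrom_lengths[c] - width))
        out.append(
            Peak(
                GenomicInterval(c, s, s + width),
                summit_offset=width // 2,
                fold_enrichment=float(rng.uniform(1, 20)),
                neg_log10_q=float(rng.uniform(2, 50)),
                name=f"{prefix}{i}",
            )
        )
    return out


@pytest.fixture
def peak_factory():
    return random_peaks
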