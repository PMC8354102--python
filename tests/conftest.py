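import numpy as np
import pandas as pd
import pytest

from polkin.windows import Coverage, TranscriptionUnit


@pytest.fixture
def plus_tu() -> TranscriptionUnit:
    """80 kb plus-strand TU with one 1.5 kb exon at +10,200."""
    return TranscriptionUnit(
        "tuA", "chr1", "+", tss=100_000, pas=180_000, exons=((110_200, 111_700),)
    )


@pytest.fixture
def minus_tu() -> TranscriptionUnit:
    return TranscriptionUnit("tuB", "chr1", "-", tss=500_000, pas=420_000)


@pytest.fixture
def uniform_coverage() -> Coverage:
    """Coverage of 1.0 over chr1:0-1,000,000."""
    return Coverage.from_intervals(
        pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000_000], "value": [1.0]})
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
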