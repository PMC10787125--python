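import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from circkit.io_formats import GenomicInterval, TranscriptModel


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_models():
    """Two-exon + transcript and a three-exon - transcript on chr1."""
    plus = TranscriptModel(
        "geneA",
        "txA",
        GenomicInterval("chr1", 100, 400, "+"),
        [
            GenomicInterval("chr1", 100, 200, "+"),
            GenomicInterval("chr1", 300, 400, "+"),
        ],
    )
    minus = TranscriptModel(
        "geneB",
        "txB",
        GenomicInterval("chr1", 1000, 1700, "-"),
        [
            GenomicInterval("chr1", 1000, 1100, "-"),
            GenomicInterval("chr1", 1200, 1400, "-"),
            GenomicInterval("chr1", 1600, 1700, "-"),
        ],
    )
    return [plus, minus]


@pytest.fixture
def toy_genome(rng, toy_models):
    bases = np.array(list("ACGT"))
    return {"chr1": "".join(bases[rng.integers(0, 4, 2000)])}
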