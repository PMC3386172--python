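import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/_printed.py

from msapkit import datasets
from msapkit.bisulfite import ReferenceSeq
from msapkit.pattern_dynamics import PATTERN_CLASSES, classify_pattern
from msapkit.simulate import simulate_band_matrix


@pytest.fixture(scope="session")
def ref300():
    """A 300 bp reference with all three cytosine contexts."""
    return ReferenceSeq("amplicon", "ACGTACAGTACAATGGATTCACG" * 13 + "T")


def expand_pattern_counts(genotype, tissue):
    """Per-locus PatternRecords reconstructed from bundled class counts."""
    counts = datasets.pattern_class_counts(genotype, tissue)
    return [classify_pattern(quad)
            for quad, klass in PATTERN_CLASSES.items()
            for _ in range(counts[klass])]


@pytest.fixture
def band_frame():
    """A small simulated band matrix in tidy long form."""
    from msapkit.simulate import default_band_config
    bands, _ = simulate_band_matrix(default_band_config(n_loci=40, seed=11))
    return bands
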