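import numpy as np
import pandas as pd
import pytest

from casnet.genes import GeneTable
from casnet.profiles import AbundanceMatrix, Label


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """4 families x 5 samples with 3 marker families appended."""
    values = np.array(
        [
            [10.0, 20.0, 5.0, 0.0, 1.0],
            [0.0, 3.0, 0.0, 0.0, 0.0],
            [1.0, 1.0, 1.0, 1.0, 1.0],
            [2.0, 4.0, 8.0, 16.0, 32.0],
        ]
    )
    markers = np.array(
        [
            [4.0, 1.0, 2.0, 1.0, 1.0],
            [5.0, 1.0, 2.0, 1.0, 1.0],
            [6.0, 1.0, 2.0, 1.0, 1.0],
        ]
    )
    return AbundanceMatrix(
        ["F1", "F2", "F3", "F4", "M1", "M2", "M3"],
        ["s1", "s2", "s3", "s4", "s5"],
        np.vstack([values, markers]),
    )


def make_gene_table(genome_id, rows):
    """rows: (contig, start, end, strand, family, is_cas) tuples."""
    return GeneTable(
        genome_id,
        pd.DataFrame(
            rows,
            columns=["contig_id", "start", "end", "strand", "family_id", "is_cas"],
        ),
    )


@pytest.fixture
def label_trio():
    return {"a": Label.POSITIVE, "b": Label.NEGATIVE, "c": Label.UNANNOTATED}
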