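import numpy as np
import pandas as pd
import pytest

from redc.genes import gene_frame
from redc.tracks import ChromatinStateTrack, GenomeSequence


@pytest.fixture(scope="session")
def crafted_genome() -> GenomeSequence:
    """30-kb single-chromosome genome with planted restriction motifs.

    The background is motif-free poly-A; one NlaIII site (CATG) sits at
    position 1000 and one forward MmeI recognition site (TCCAAC) at
    2000, so every restriction-zone boundary is known exactly.
    """
    seq = list("A" * 30_000)
    seq[1000:1004] = "CATG"
    seq[2000:2006] = "TCCAAC"
    return GenomeSequence({"chrT": "".join(seq)})


@pytest.fixture(scope="session")
def crafted_states() -> ChromatinStateTrack:
    return ChromatinStateTrack.from_frame(pd.DataFrame({
        "chrom": "chrT",
        "start": [0, 5000, 6000, 8000, 20000],
        "end": [5000, 6000, 7000, 20000, 21000],
        "state": [10, 14, 15, 5, 13],
        # 7000-8000 deliberately unannotated
    }))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_gene_set() -> pd.DataFrame:
    """Two-exon gene, a nested small RNA gene, and a minus-strand gene."""
    return gene_frame([
        {"gene_id": "big", "name": "BIG", "biotype": "protein_coding",
         "chrom": "chr1", "strand": "+", "start": 1000, "end": 21000,
         "exons": [(1000, 3000), (15000, 21000)]},
        {"gene_id": "small", "name": "U1", "biotype": "snRNA",
         "chrom": "chr1", "strand": "+", "start": 5000, "end": 5200,
         "exons": [(5000, 5200)]},
        {"gene_id": "minus", "name": "MIN", "biotype": "protein_coding",
         "chrom": "chr1", "strand": "-", "start": 40000, "end": 60000,
         "exons": [(40000, 45000), (50000, 60000)]},
    ])
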