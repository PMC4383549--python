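import numpy as np
import pytest

from chromadelta.core_io import Gene, GenomeTable, GenomicInterval, ReadSet


@pytest.fixture
def toy_genome() -> GenomeTable:
    return GenomeTable({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def toy_genes() -> list[Gene]:
    return [
        Gene("geneA", GenomicInterval("chr1", 10_000, 20_000, "+"), "+"),
        Gene("geneB", GenomicInterval("chr1", 40_000, 50_000, "-"), "-"),
        Gene("geneC", GenomicInterval("chr2", 5_000, 15_000, "+"), "+"),
    ]


def make_readset(condition: str, replicate: str, positions: dict) -> ReadSet:
    return ReadSet(condition, replicate,
                   {c: np.asarray(p, dtype=np.int64) for c, p in positions.items()})
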