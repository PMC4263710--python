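"""Shared fixtures: tiny hand-built gene sets and expression matrices."""

import numpy as np
import pandas as pd
import pytest

from ontomap.annotation import GeneModel, GeneSet
from ontomap.expression import ExpressionMatrix


def make_gene(gene_id, chrom="chr1", strand="+", start=0, end=1000,
              exons=None, biotype="protein_coding", klass=None):
    if exons is None:
        exons = ((start, end),)
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, start=start,
                     end=end, exons=tuple(exons), biotype=biotype, klass=klass)


def random_geneset(rng, n, chroms=("chr1", "chr2"), coding_fraction=0.6,
                   max_pos=1_000_000):
    """Random (possibly overlapping) genes with assigned classes."""
    genes = []
    for i in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(100, 20_000))
        coding = rng.random() < coding_fraction
        genes.append(
            make_gene(
                f"G{i:04d}",
                chrom=str(rng.choice(chroms)),
                strand="+" if rng.random() < 0.5 else "-",
                start=start, end=start + length,
                biotype="protein_coding" if coding else "lincRNA",
                klass="coding" if coding else "lncRNA",
            )
        )
    return GeneSet(genes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """4 genes x (3 ages x 2 replicates) with hand-chosen values."""
    samples = pd.DataFrame(
        {
            "sample_id": ["a0r1", "a0r2", "a5r1", "a5r2", "a10r1", "a10r2"],
            "age_day": [0, 0, 5, 5, 10, 10],
            "replicate": [1, 2, 1, 2, 1, 2],
        }
    )
    values = pd.DataFrame(
        {
            "a0r1": [1.0, 0.0, 2.0, 5.0],
            "a0r2": [3.0, 0.0, 2.0, 5.0],
            "a5r1": [1.0, 0.9, 4.0, 5.0],
            "a5r2": [1.0, 0.9, 4.0, 5.0],
            "a10r1": [2.0, 0.0, 8.0, 5.0],
            "a10r2": [4.0, 0.0, 8.0, 5.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    values.index.name = "gene_id"
    return ExpressionMatrix(values, samples)
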