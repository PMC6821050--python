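import numpy as np
import pytest

import eglink as eg
from eglink.core import Enhancer, Gene, GenomicInterval


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic draw at the standard study conditions."""
    return eg.generate(eg.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_table(default_dataset):
    """Balanced labeled feature table for the default draw."""
    return eg.prepare_dataset(default_dataset, seed=11, balanced=True)


@pytest.fixture(scope="session")
def independent_dataset():
    """A second draw at the same conditions, for cross-sample protocols."""
    return eg.generate(eg.SimulationConfig(seed=211))


@pytest.fixture(scope="session")
def independent_full_table(independent_dataset):
    return eg.prepare_dataset(independent_dataset, seed=211, balanced=False)


def make_enhancer(eid, chrom, start, end, activity):
    return Enhancer(eid, GenomicInterval(chrom, start, end), dict(activity))


def make_gene(gid, chrom, tss, strand="+", body=None, expression=None):
    if body is None:
        body = GenomicInterval(chrom, tss, tss + 10_000) if strand == "+" else GenomicInterval(chrom, max(0, tss - 10_000), tss)
    return Gene(gid, chrom, tss, strand, body, expression=dict(expression or {}))


@pytest.fixture
def tiny_panel():
    """Three cell types, two enhancers, two genes on one chromosome."""
    cells = ["A", "B", "C"]
    enhancers = [
        make_enhancer("E1", "chr1", 20_000, 21_000, {"A": 2.0, "B": 4.0, "C": 6.0}),
        make_enhancer("E2", "chr1", 300_000, 301_000, {"A": 1.0, "B": 1.0, "C": 1.0}),
    ]
    genes = [
        make_gene("G1", "chr1", 100_000, "+", expression={"A": 1.0, "B": 2.0, "C": 3.0}),
        make_gene("G2", "chr1", 400_000, "-",
                  body=GenomicInterval("chr1", 390_000, 400_000),
                  expression={"A": 5.0, "B": 0.0, "C": 2.5}),
    ]
    return cells, enhancers, genes
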