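"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from srnascape.io_coverage import AlignedRead, AnnotationSet, Feature, TrnaGene
from srnascape.synthetic import SyntheticConfig, generate

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_read(
    chrom="chr1", start=100, length=21, strand="+", sequence=None,
    multiplicity=1, library="NL",
) -> AlignedRead:
    return AlignedRead(
        chrom=chrom, start=start, end=start + length, strand=strand,
        sequence=sequence, multiplicity=multiplicity, library=library,
    )


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic study (seed 1), shared across tests."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def usable_reads(bundle):
    from srnascape.io_coverage import in_range

    return in_range(bundle.all_reads())


#: canonical test tRNA: 76 nt, plus strand, mature 3' end at 76
@pytest.fixture()
def trna():
    return TrnaGene(
        chrom="chr1", start=1000, end=1076, strand="+", name="tRNA_Glu_GAG",
        isotype="Glu", anticodon="GAG",
        arms={"acceptor_stem": (0, 7), "d_loop": (14, 21),
              "anticodon_loop": (30, 39), "t_loop": (53, 61)},
    )


@pytest.fixture()
def tiny_annotations():
    """Small hand-built annotation set on a 10 kb chromosome."""
    genes = [Feature("chr1", 2000, 3000, "+", "geneA", {"type": "gene"})]
    repeats = [
        Feature("chr1", 4000, 5000, "+", "TE1",
                {"type": "transposable_element", "family": "Copia"}),
        # a repeat that contains the tRNA below
        Feature("chr1", 900, 1200, "+", "TE2",
                {"type": "transposable_element", "family": "Copia"}),
    ]
    trnas = [
        TrnaGene(
            chrom="chr1", start=1000, end=1076, strand="+", name="tRNA_Glu_GAG",
            isotype="Glu", anticodon="GAG",
            arms={"acceptor_stem": (0, 7), "d_loop": (14, 21),
                  "anticodon_loop": (30, 39), "t_loop": (53, 61)},
        )
    ]
    ncrnas = [Feature("chr1", 6000, 6226, "+", "U2", {"type": "snRNA"}),
              Feature("chr1", 7000, 7600, "+", "rRNA1", {"type": "rRNA"})]
    probes = [
        Feature("chr1", 4100 + i * 100, 4102 + i * 100, ".", f"p{i}",
                {"methylated": 1 if i < 2 else 0})
        for i in range(3)
    ]
    return AnnotationSet(
        genes=genes, repeats=repeats, trnas=trnas, ncrnas=ncrnas,
        methylation=probes, chrom_sizes={"chr1": 10_000},
    )
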