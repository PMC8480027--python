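"""Shared fixtures: toy gene models and simulated panels."""

from __future__ import annotations

import numpy as np
import pytest

from proxyhap.variant_annotation import GeneModel

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def random_cds(n_codons: int, seed: int) -> str:
    """Random CDS starting ATG, length 3*n_codons."""
    rng = np.random.default_rng(seed)
    bases = "".join(rng.choice(list("ACGT"), size=3 * (n_codons - 1)))
    return "ATG" + bases


def make_gene(
    cds: str,
    strand: str = "+",
    chromosome: str = "Gm04",
    window_start: int = 1000,
    gene_id: str = "toy",
) -> tuple[GeneModel, str]:
    """Single-exon gene model plus its genomic (+ strand) sequence.

    For a − strand gene the genomic bases of the exon are the reverse
    complement of the CDS.
    """
    genomic = cds if strand == "+" else revcomp(cds)
    end = window_start + len(cds) - 1
    gene = GeneModel(
        gene_id=gene_id,
        chromosome=chromosome,
        window_start=window_start,
        window_end=end,
        strand=strand,
        cds_segments=((window_start, end),),
        cds_sequence=cds,
    )
    return gene, genomic


@pytest.fixture
def toy_gene():
    """100-codon + strand gene with codon 82 = AAG (lysine)."""
    cds = random_cds(100, seed=7)
    cds = cds[: 3 * 81] + "AAG" + cds[3 * 81 + 3 :]
    return make_gene(cds)
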