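"""Coding-effect classification of SNPs inside a gene window.

Implements the reverse-genetics step of the pipeline: given a small
gene model (window, strand, CDS segments, reference coding sequence)
and a single-nucleotide substitution, decide whether the change is
synonymous, missense or nonsense and name the protein change in the
conventional "K82E" style.  Positions inside the window but outside the
CDS segments are classified noncoding.

Only substitutions and the standard nuclear genetic code are handled;
that is all the intended analyses need.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from proxyhap.encoding import ALT_HOM, HET
from proxyhap.genotype_io import GenotypeMatrix

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

EFFECT_SYNONYMOUS = "synonymous"
EFFECT_MISSENSE = "missense"
EFFECT_NONSENSE = "nonsense"
EFFECT_NONCODING = "noncoding"


@dataclass(frozen=True)
class GeneModel:
    """A minimal gene model sufficient for substitution effects.

    `cds_segments` are 1-based inclusive genomic intervals, ordered by
    genomic position; `cds_sequence` is the reference coding sequence
    in translation order (already reverse-complemented for − strand).
    """

    gene_id: str
    chromosome: str
    window_start: int
    window_end: int
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        segs = self.cds_segments
        if any(s > e for s, e in segs):
            raise ValueError("segment start > end")
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if e1 >= s2:
                raise ValueError("CDS segments overlap or are unordered")
        if segs and (segs[0][0] < self.window_start or segs[-1][1] > self.window_end):
            raise ValueError("CDS segments outside gene window")
        total = sum(e - s + 1 for s, e in segs)
        if total != len(self.cds_sequence):
            raise ValueError(
                f"CDS length {total} != sequence length {len(self.cds_sequence)}"
            )
        if total % 3 != 0:
            raise ValueError("CDS length not divisible by 3")

    def cds_offset(self, genomic_pos: int) -> int | None:
        """0-based offset into the coding sequence, or None if noncoding.

        On the − strand the first coding base is the *last* genomic base
        of the last segment.
        """
        covered = 0
        if self.strand == "+":
            for s, e in self.cds_segments:
                if s <= genomic_pos <= e:
                    return covered + (genomic_pos - s)
                covered += e - s + 1
        else:
            for s, e in reversed(self.cds_segments):
                if s <= genomic_pos <= e:
                    return covered + (e - genomic_pos)
                covered += e - s + 1
        return None


@dataclass(frozen=True)
class VariantEffect:
    chromosome: str
    position: int
    ref: str
    alt: str
    effect: str
    aa_position: int | None = None
    aa_change: str | None = None


def classify_variant(
    gene: GeneModel, chromosome: str, position: int, ref: str, alt: str
) -> VariantEffect:
    """Classify a single-nucleotide substitution against a gene model.

    The variant alleles are given on the + (reference) strand, as in a
    VCF; for − strand genes they are complemented before editing the
    codon.  ``aa_position`` is the 1-based codon index
    (``floor(cds_offset / 3) + 1``).
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("only single-nucleotide substitutions are supported")
    if chromosome != gene.chromosome or not (
        gene.window_start <= position <= gene.window_end
    ):
        raise ValueError(
            f"variant {chromosome}:{position} outside gene window "
            f"{gene.chromosome}:{gene.window_start}-{gene.window_end}"
        )
    offset = gene.cds_offset(position)
    if offset is None:
        return VariantEffect(chromosome, position, ref, alt, EFFECT_NONCODING)

    ref_cds, alt_cds = ref.upper(), alt.upper()
    if gene.strand == "-":
        ref_cds = ref_cds.translate(_COMPLEMENT)
        alt_cds = alt_cds.translate(_COMPLEMENT)
    if gene.cds_sequence[offset].upper() != ref_cds:
        raise ValueError(
            f"reference allele {ref!r} does not match CDS base "
            f"{gene.cds_sequence[offset]!r} at offset {offset}"
        )
    codon_idx = offset // 3
    within = offset % 3
    codon = gene.cds_sequence[3 * codon_idx : 3 * codon_idx + 3].upper()
    mut_codon = codon[:within] + alt_cds + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate(table=standard_dna_table))
    aa_alt = str(Seq(mut_codon).translate(table=standard_dna_table))
    aa_pos = codon_idx + 1
    if aa_alt == aa_ref:
        return VariantEffect(chromosome, position, ref, alt, EFFECT_SYNONYMOUS, aa_pos)
    effect = EFFECT_NONSENSE if aa_alt == "*" else EFFECT_MISSENSE
    return VariantEffect(
        chromosome,
        position,
        ref,
        alt,
        effect,
        aa_position=aa_pos,
        aa_change=f"{aa_ref}{aa_pos}{aa_alt}",
    )


def scan_gene_window(panel: GenotypeMatrix, gene: GeneModel) -> pd.DataFrame:
    """Annotate every polymorphic panel site inside the gene window.

    Returns one row per marker in the window with its effect call and
    the ids of accessions carrying the alternate allele (homozygous and
    heterozygous carriers listed separately).  An empty window yields an
    empty table.
    """
    rows = []
    acc = pd.Index(panel.accession_ids)
    for col, marker in panel.markers.iterrows():
        if marker["chrom"] != gene.chromosome:
            continue
        if not gene.window_start <= marker["pos"] <= gene.window_end:
            continue
        calls = panel.calls[:, panel.markers.index.get_loc(col)]
        hom_carriers = acc[calls == ALT_HOM].tolist()
        het_carriers = acc[calls == HET].tolist()
        if not hom_carriers and not het_carriers:
            continue  # monomorphic in this panel
        eff = classify_variant(
            gene, marker["chrom"], int(marker["pos"]), marker["ref"], marker["alt"]
        )
        rows.append(
            {
                "marker_id": marker["marker_id"],
                "chrom": marker["chrom"],
                "pos": int(marker["pos"]),
                "ref": marker["ref"],
                "alt": marker["alt"],
                "effect": eff.effect,
                "aa_position": eff.aa_position,
                "aa_change": eff.aa_change,
                "n_hom_carriers": len(hom_carriers),
                "n_het_carriers": len(het_carriers),
                "hom_carriers": ",".join(hom_carriers),
                "het_carriers": ",".join(het_carriers),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "marker_id",
            "chrom",
            "pos",
            "ref",
            "alt",
            "effect",
            "aa_position",
            "aa_change",
            "n_hom_carriers",
            "n_het_carriers",
            "hom_carriers",
            "het_carriers",
        ],
    )
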