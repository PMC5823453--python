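"""Strand-aware classification of RNA–DNA mismatches.

Strand-specific libraries let a genomic T>C inside a minus-strand gene be
recognised as A>G on the transcribed strand. VCF records carry no read
orientation, so the strand is resolved from the gene annotation: an
overlapping gene wins, then a gene within the flank distance, else the
genomic plus-strand label is reported with ``strand_source='unknown'``.
"""

from __future__ import annotations

from typing import Optional

from .config import ThresholdConfig, DEFAULT_CONFIG
from .model import GeneModelSet, MismatchClass, VariantObservation, complement_base


def classify_mismatch(variant: VariantObservation,
                      gene_models: GeneModelSet,
                      provided_strand: Optional[str] = None,
                      config: ThresholdConfig = DEFAULT_CONFIG,
                      ) -> Optional[MismatchClass]:
    """Label the substitution on the transcribed strand.

    Returns ``None`` when the site overlaps genes on both strands
    (classification deferred; such sites are removed by the bidirectional-
    transcription filter).
    """
    if provided_strand is not None:
        if provided_strand not in "+-":
            raise ValueError("provided_strand must be '+' or '-'")
        return _label(variant, provided_strand, "provided")

    overlapping = gene_models.genes_at(variant.contig, variant.pos)
    strands = {g.strand for g in overlapping}
    if strands == {"+", "-"}:
        return None
    if len(strands) == 1:
        return _label(variant, strands.pop(), "gene")

    nearby = gene_models.genes_near(variant.contig, variant.pos, config.gene_flank)
    strands = {g.strand for g in nearby}
    if len(strands) == 1:
        return _label(variant, strands.pop(), "flank_gene")
    return _label(variant, "+", "unknown")


def _label(variant: VariantObservation, strand: str, source: str) -> MismatchClass:
    ref, alt = variant.ref, variant.alt
    if strand == "-":
        ref, alt = complement_base(ref), complement_base(alt)
    return MismatchClass(label=f"{ref}>{alt}", strand=strand, strand_source=source)


def transcribed_alleles(variant: VariantObservation, strand: str) -> tuple[str, str]:
    """(ref, alt) on the transcribed strand."""
    if strand == "-":
        return complement_base(variant.ref), complement_base(variant.alt)
    return variant.ref, variant.alt
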