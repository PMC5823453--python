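"""Genomic-region classification, coding consequence and repeat overlap.

Region precedence (highest wins across all genes touching the site):

    CDS > UTR5/UTR3 > intron > pseudogene > upstream (≤5 kb, strand-aware)
    > downstream (≤5 kb) > intergenic

Coding consequences are computed by rebuilding the codon on the coding
strand from the transcript's CDS intervals, substituting the edited base
and translating with the standard genetic code. Incomplete transcripts
(CDS length not divisible by 3) are excluded from consequence calls.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq3

from .config import ThresholdConfig, DEFAULT_CONFIG
from .model import (
    EditingSite,
    Gene,
    GeneModelSet,
    GenomeAssembly,
    RepeatSet,
    SiteAnnotation,
    Transcript,
    revcomp,
)

log = logging.getLogger("editome")

REGION_PRECEDENCE = ("CDS", "UTR5", "UTR3", "intron", "pseudogene",
                     "upstream", "downstream", "intergenic")
_RANK = {r: i for i, r in enumerate(REGION_PRECEDENCE)}


def _region_within_gene(gene: Gene, pos: int) -> Optional[str]:
    """Best region label for a position inside the gene span, or None."""
    best: Optional[str] = None

    def consider(region: str) -> None:
        nonlocal best
        if best is None or _RANK[region] < _RANK[best]:
            best = region

    span = gene.span
    if not (span[0] <= pos <= span[1]):
        return None
    if gene.biotype == "pseudogene":
        return "pseudogene"
    for tx in gene.transcripts:
        ts, te = tx.span
        if not (ts <= pos <= te):
            continue
        in_exon = False
        for s, e in tx.exons:
            if s <= pos <= e:
                in_exon = True
                break
        if any(s <= pos <= e for s, e, _ in tx.cds):
            consider("CDS")
        elif any(s <= pos <= e for s, e in tx.utr5):
            consider("UTR5")
        elif any(s <= pos <= e for s, e in tx.utr3):
            consider("UTR3")
        elif not in_exon:
            consider("intron")
        else:
            # exon of a non-coding transcript: treat as intragenic, lowest
            # exonic confidence → intron bucket
            consider("intron")
    return best


def annotate_region(site: EditingSite, gene_models: GeneModelSet,
                    config: ThresholdConfig = DEFAULT_CONFIG,
                    ) -> SiteAnnotation:
    """Assign the highest-precedence region and its providing gene."""
    contig, pos = site.contig, site.pos
    candidates: list[tuple[int, str, Gene]] = []
    for gene in gene_models.genes_at(contig, pos):
        region = _region_within_gene(gene, pos)
        if region is not None:
            candidates.append((_RANK[region], region, gene))
    for gene in gene_models.genes_near(contig, pos, config.gene_flank):
        gs, ge = gene.span
        if gene.strand == "+":
            region = "upstream" if pos < gs else "downstream"
        else:
            region = "downstream" if pos < gs else "upstream"
        candidates.append((_RANK[region], region, gene))
    if not candidates:
        return SiteAnnotation(region="intergenic")
    candidates.sort(key=lambda c: (c[0], c[2].id))
    _, region, gene = candidates[0]
    return SiteAnnotation(region=region, gene_id=gene.id, gene_symbol=gene.symbol)


def coding_consequence(site: EditingSite, gene_models: GeneModelSet,
                       genome: GenomeAssembly,
                       ) -> Optional[tuple[str, str]]:
    """(consequence, aa_change) for a CDS site, or None.

    The edited base is ``site.alt`` on the transcribed strand, which for a
    coding gene is the coding strand, so it substitutes directly into the
    codon. Multiple transcripts are tried in order; the first complete
    transcript whose CDS contains the site wins.
    """
    for gene in gene_models.genes_at(site.contig, site.pos):
        for tx in gene.transcripts:
            if not tx.cds or not any(s <= site.pos <= e for s, e, _ in tx.cds):
                continue
            if not tx.complete:
                log.warning("transcript %s incomplete; consequence omitted "
                            "for %s:%d", tx.id, site.contig, site.pos)
                continue
            return _consequence_in_transcript(site, tx, gene.strand, genome)
    return None


def _consequence_in_transcript(site: EditingSite, tx: Transcript, strand: str,
                               genome: GenomeAssembly) -> tuple[str, str]:
    pieces = [genome.slice(site.contig, s, e) for s, e, _ in tx.cds]
    cds_seq = "".join(pieces)
    # offset of the site within the genomic-order concatenation
    offset = 0
    for s, e, _ in tx.cds:
        if s <= site.pos <= e:
            offset += site.pos - s
            break
        offset += e - s + 1
    if strand == "-":
        cds_seq = revcomp(cds_seq)
        offset = len(cds_seq) - 1 - offset
    codon_idx, within = divmod(offset, 3)
    ref_codon = cds_seq[codon_idx * 3:codon_idx * 3 + 3]
    if ref_codon[within] != site.ref:
        raise ValueError(
            f"reference mismatch at {site.contig}:{site.pos}: codon "
            f"{ref_codon} vs site ref {site.ref}")
    alt_codon = ref_codon[:within] + site.alt + ref_codon[within + 1:]
    ref_aa = _translate(ref_codon)
    alt_aa = _translate(alt_codon)
    aa_change = f"{_aa_name(ref_aa)}→{_aa_name(alt_aa)}"
    if ref_aa == alt_aa:
        consequence = "synonymous"
    elif alt_aa == "*":
        consequence = "stop_gained"
    elif ref_aa == "*":
        consequence = "stop_lost"
    else:
        consequence = "non_synonymous"
    return consequence, aa_change


def _translate(codon: str) -> str:
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


def _aa_name(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def repeat_overlap(site: EditingSite, repeats: RepeatSet,
                   ) -> Optional[tuple[str, str]]:
    """(repeat_class, family) of the overlapping repeat, longest overlap
    first (for a point site: the longest interval), ties by coordinate."""
    hits = repeats.overlapping(site.contig, site.pos)
    if not hits:
        return None
    hits.sort(key=lambda r: (-(r.end - r.start + 1), r.start))
    best = hits[0]
    return best.repeat_class, best.family


def annotate_sites(sites: Sequence[EditingSite], gene_models: GeneModelSet,
                   genome: GenomeAssembly, repeats: RepeatSet,
                   config: ThresholdConfig = DEFAULT_CONFIG) -> None:
    """Fill the annotation of every site in place."""
    for site in sites:
        ann = annotate_region(site, gene_models, config)
        if ann.region == "CDS":
            result = coding_consequence(site, gene_models, genome)
            if result is not None:
                ann.consequence, ann.aa_change = result
        rep = repeat_overlap(site, repeats)
        if rep is not None:
            ann.repeat_class, ann.repeat_family = rep
        site.annotation = ann
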