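"""Readers and writers for the standard formats the pipeline consumes.

FASTA via Bio.SeqIO, GFF3/GTF via gffutils, VCF via pysam, repeats from
BED6 or RepeatMasker ``.out``. Internal coordinates are 1-based inclusive;
BED half-open intervals are converted here, at the boundary.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import gffutils
import pysam
from Bio import SeqIO

from .model import (
    Gene,
    GeneModelSet,
    GenomeAssembly,
    IUPAC,
    RepeatFeature,
    RepeatSet,
    Transcript,
    VariantObservation,
)

log = logging.getLogger("editome")

_REPEAT_CLASSES = ("SINE", "LINE", "DNA", "other")


def read_genome(path: str) -> GenomeAssembly:
    """Load a FASTA assembly, uppercasing and validating the alphabet."""
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(path, "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate contig name: {record.id}")
        seq = str(record.seq).upper()
        bad = set(seq) - IUPAC
        if bad:
            offset = next(i for i, b in enumerate(seq) if b in bad)
            raise ValueError(
                f"non-IUPAC character {seq[offset]!r} at {record.id}:{offset + 1}")
        contigs[record.id] = seq
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeAssembly(contigs)


def write_genome(assembly: GenomeAssembly, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in assembly.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene models


def _biotype(attrs) -> str:
    for key in ("biotype", "gene_biotype", "gene_type"):
        if key in attrs:
            value = attrs[key][0]
            if value == "protein_coding":
                return "protein_coding"
            if "pseudogene" in value:
                return "pseudogene"
            return "other"
    return "protein_coding"


def read_gene_models(path: str) -> GeneModelSet:
    """Parse GFF3 or GTF (auto-detected) into a gene→transcript hierarchy.

    Orphan transcripts (no gene parent) get a synthesized single-transcript
    gene with a warning. Transcripts whose total CDS length is not divisible
    by 3 are flagged incomplete and excluded from consequence calls.
    """
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique",
        keep_order=True, disable_infer_genes=True, disable_infer_transcripts=True)

    transcript_types = {"mRNA", "transcript", "pseudogenic_transcript"}
    genes: list[Gene] = []
    seen_transcripts: set[str] = set()

    def build_transcript(tfeat) -> Transcript:
        exons, cds, utr5, utr3 = [], [], [], []
        for child in db.children(tfeat, order_by="start"):
            iv = (child.start, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                frame = int(child.frame) if child.frame not in (None, ".") else 0
                cds.append((child.start, child.end, frame))
            elif child.featuretype in ("five_prime_UTR", "five_prime_utr", "5UTR"):
                utr5.append(iv)
            elif child.featuretype in ("three_prime_UTR", "three_prime_utr", "3UTR"):
                utr3.append(iv)
        if not exons:
            exons = [(tfeat.start, tfeat.end)]
        exons.sort()
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping exons in transcript {tfeat.id} at {s2}")
        tx = Transcript(id=tfeat.id, exons=exons, cds=sorted(cds),
                        utr5=sorted(utr5), utr3=sorted(utr3))
        if tx.cds and tx.cds_length() % 3 != 0:
            tx.complete = False
            log.warning("transcript %s: CDS length %d not divisible by 3; "
                        "flagged incomplete", tfeat.id, tx.cds_length())
        return tx

    for gfeat in db.features_of_type(("gene", "pseudogene"), order_by="start"):
        transcripts = []
        for tfeat in db.children(gfeat, level=1):
            if tfeat.featuretype in transcript_types:
                transcripts.append(build_transcript(tfeat))
                seen_transcripts.add(tfeat.id)
        if not transcripts:
            # gene with direct exon/CDS children (common in compact GTF)
            transcripts = [build_transcript(gfeat)]
        symbol = gfeat.attributes.get("Name", gfeat.attributes.get(
            "gene_name", [gfeat.id]))[0]
        biotype = ("pseudogene" if gfeat.featuretype == "pseudogene"
                   else _biotype(gfeat.attributes))
        genes.append(Gene(id=gfeat.id, symbol=symbol, biotype=biotype,
                          contig=gfeat.seqid, strand=gfeat.strand,
                          transcripts=transcripts))

    # orphan transcripts: synthesize a single-transcript gene
    for tfeat in db.features_of_type(tuple(transcript_types), order_by="start"):
        if tfeat.id in seen_transcripts:
            continue
        parents = [p for p in db.parents(tfeat, level=1)]
        if parents:
            continue
        log.warning("orphan transcript %s: synthesizing gene", tfeat.id)
        tx = build_transcript(tfeat)
        genes.append(Gene(id=f"gene_{tfeat.id}", symbol=tfeat.id,
                          biotype=_biotype(tfeat.attributes),
                          contig=tfeat.seqid, strand=tfeat.strand,
                          transcripts=[tx]))
    return GeneModelSet(genes)


# ---------------------------------------------------------------------------
# Repeats


def read_repeats(path: str) -> RepeatSet:
    """Read repeat annotation from BED6 (name = class/family) or
    RepeatMasker ``.out``, selected by extension."""
    if path.endswith(".out"):
        return _read_repeatmasker_out(path)
    return _read_repeat_bed(path)


def _normalise_class(raw: str) -> str:
    head = raw.split("/")[0].split("?")[0]
    return head if head in _REPEAT_CLASSES else "other"


def _read_repeat_bed(path: str) -> RepeatSet:
    repeats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs >=4 columns")
            contig, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) > 5 else "+"
            if "/" in name:
                klass, family = name.split("/", 1)
            else:
                klass, family = name, name
            repeats.append(RepeatFeature(
                contig=contig, start=start + 1, end=end, strand=strand,
                repeat_class=_normalise_class(klass), family=family))
    return RepeatSet(repeats)


def _read_repeatmasker_out(path: str) -> RepeatSet:
    repeats = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 11 or not parts[0].isdigit():
                continue
            contig, start, end = parts[4], int(parts[5]), int(parts[6])
            strand = "-" if parts[8] == "C" else "+"
            family, class_family = parts[9], parts[10]
            repeats.append(RepeatFeature(
                contig=contig, start=start, end=end, strand=strand,
                repeat_class=_normalise_class(class_family), family=family))
    return RepeatSet(repeats)


def write_repeats_bed(repeats: RepeatSet, path: str) -> None:
    with open(path, "w") as fh:
        for rep in repeats.repeats:
            name = f"{rep.repeat_class}/{rep.family}"
            fh.write(f"{rep.contig}\t{rep.start - 1}\t{rep.end}\t{name}\t0\t{rep.strand}\n")


# ---------------------------------------------------------------------------
# Variants


@dataclass
class VcfReadStats:
    records: int = 0
    observations: int = 0
    skipped_indel: int = 0
    skipped_no_depth: int = 0


def read_variants(path: str, individual: str, tissue: str,
                  stats: Optional[VcfReadStats] = None) -> list[VariantObservation]:
    """Read per-sample SNV observations from a VCF.

    Emits one observation per ALT allele per record; indels/MNVs are skipped
    with a counter, as are records lacking both AD and DP.
    """
    stats = stats if stats is not None else VcfReadStats()
    out: list[VariantObservation] = []
    info_keys = ("HRun", "MQ", "QD", "MQRankSum", "ReadPosRankSum")
    with pysam.VariantFile(path) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            stats.records += 1
            alts = [a for a in (rec.alts or ()) if a is not None]
            if not alts:
                continue
            if len(rec.ref) != 1 or any(len(a) != 1 or a not in "ACGT" for a in alts):
                stats.skipped_indel += 1
                continue
            ad = dp = gt = None
            if sample_names:
                fmt = rec.samples[sample_names[0]]
                ad = fmt.get("AD")
                dp = fmt.get("DP")
                gt = fmt.get("GT")
            if ad is None and dp is None:
                stats.skipped_no_depth += 1
                log.warning("%s:%s missing AD and DP; skipped", rec.contig, rec.pos)
                continue
            if ad is not None and any(x is None for x in ad):
                ad = None
            total = int(dp) if dp is not None else int(sum(ad))
            if gt is None or None in gt:
                genotype = "het"
            elif all(g == 0 for g in gt):
                genotype = "hom_ref"
            elif 0 in gt:
                genotype = "het"
            else:
                genotype = "hom_alt"
            annotations = {}
            for key in info_keys:
                if key in rec.info:
                    value = rec.info[key]
                    if isinstance(value, tuple):
                        value = value[0]
                    annotations[key] = float(value)
            for i, alt in enumerate(alts):
                if ad is not None and len(ad) > i + 1:
                    alt_depth = int(ad[i + 1])
                elif ad is None:
                    alt_depth = 0  # DP only: ratio unusable, caught downstream
                else:
                    alt_depth = 0
                alt_depth = min(alt_depth, total)
                out.append(VariantObservation(
                    contig=rec.contig, pos=rec.pos, ref=rec.ref, alt=alt,
                    total_depth=total, alt_depth=alt_depth, genotype=genotype,
                    individual=individual, tissue=tissue,
                    annotations=dict(annotations),
                    multi_allelic=len(alts) > 1, all_alts=tuple(alts)))
                stats.observations += 1
    return out


def read_known_snps(path: str) -> set:
    """Positions (contig, pos) — and alleles — of known SNPs from a VCF."""
    positions = set()
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            for alt in (rec.alts or (None,)):
                positions.add((rec.contig, rec.pos, rec.ref, alt))
    return positions


def subtract_known_snps(variants: Iterable[VariantObservation],
                        known: set,
                        allele_aware: bool = False) -> list[VariantObservation]:
    """Drop observations at known-SNP positions.

    Matching is by position by default (a known SNP at the site disqualifies
    it regardless of allele); set ``allele_aware`` to require the same
    ref/alt pair.
    """
    by_pos = {(c, p) for (c, p, _r, _a) in known}
    out = []
    for v in variants:
        if allele_aware:
            if (v.contig, v.pos, v.ref, v.alt) in known:
                continue
        elif (v.contig, v.pos) in by_pos:
            continue
        out.append(v)
    return out


# ---------------------------------------------------------------------------
# Sample metadata


@dataclass
class SampleRecord:
    individual: str
    tissue: str
    vcf_path: str


def read_sample_metadata(path: str) -> list[SampleRecord]:
    """TSV with header columns individual_id, tissue, vcf_path."""
    records = []
    base = os.path.dirname(os.path.abspath(path))
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for need in ("individual_id", "tissue", "vcf_path"):
            if need not in idx:
                raise ValueError(f"sample metadata missing column {need!r}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            vcf = parts[idx["vcf_path"]]
            if not os.path.isabs(vcf):
                vcf = os.path.join(base, vcf)
            records.append(SampleRecord(parts[idx["individual_id"]],
                                        parts[idx["tissue"]], vcf))
    return records
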