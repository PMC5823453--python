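"""Core data model: assemblies, gene models, repeats, variants and sites.

Coordinates are 1-based inclusive throughout (VCF-native); BED input is
converted at the reading boundary. All sequence is uppercase A/C/G/T/N
(other IUPAC ambiguity codes are tolerated in assemblies but never inside
SSRs or planted sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

#: The twelve ordered substitution labels, genomic or transcribed strand.
MISMATCH_LABELS = (
    "A>C", "A>G", "A>T",
    "C>A", "C>G", "C>T",
    "G>A", "G>C", "G>T",
    "T>A", "T>C", "T>G",
)

IUPAC = set("ACGTNRYSWKMBDHV")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(COMPLEMENT)


class GenomeAssembly:
    """A set of named contigs with 1-based inclusive random access."""

    def __init__(self, contigs: dict[str, str]):
        self.contigs: dict[str, str] = {}
        for name, seq in contigs.items():
            if name in self.contigs:
                raise ValueError(f"duplicate contig name: {name}")
            if not seq:
                raise ValueError(f"empty sequence for contig {name}")
            self.contigs[name] = seq.upper()

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __iter__(self) -> Iterator[str]:
        return iter(self.contigs)

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def slice(self, contig: str, start: int, end: int) -> str:
        """Return bases ``start..end`` (1-based, inclusive)."""
        if start < 1 or end > len(self.contigs[contig]) or start > end:
            raise IndexError(f"slice {contig}:{start}-{end} out of bounds")
        return self.contigs[contig][start - 1:end]

    def base(self, contig: str, pos: int) -> str:
        return self.slice(contig, pos, pos)


@dataclass
class Transcript:
    id: str
    exons: list[tuple[int, int]]          # sorted by coordinate
    cds: list[tuple[int, int, int]] = field(default_factory=list)  # (start, end, frame)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    complete: bool = True                 # CDS length divisible by 3

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)


@dataclass
class Gene:
    id: str
    symbol: str
    biotype: str                          # protein_coding | pseudogene | other
    contig: str
    strand: str                           # '+' | '-'
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return min(starts), max(ends)


class GeneModelSet:
    """Genes with interval-indexed lookup by position."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: list[Gene] = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for gene in self.genes:
            if gene.strand not in "+-":
                raise ValueError(f"gene {gene.id}: strand must be + or -")
            s, e = gene.span
            self._trees.setdefault(gene.contig, IntervalTree()).addi(s, e + 1, gene)

    def __len__(self) -> int:
        return len(self.genes)

    def genes_at(self, contig: str, pos: int) -> list[Gene]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree[pos]), key=lambda g: g.id)

    def genes_near(self, contig: str, pos: int, flank: int) -> list[Gene]:
        """Genes whose span lies within ``flank`` bp of ``pos`` (no overlap)."""
        tree = self._trees.get(contig)
        if tree is None:
            return []
        hits = {iv.data.id: iv.data for iv in tree[max(1, pos - flank):pos + flank + 1]}
        at = {g.id for g in self.genes_at(contig, pos)}
        return sorted((g for gid, g in hits.items() if gid not in at),
                      key=lambda g: g.id)


@dataclass
class RepeatFeature:
    contig: str
    start: int
    end: int
    strand: str
    repeat_class: str                     # SINE | LINE | DNA | other
    family: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("invalid repeat interval")
        if self.repeat_class not in ("SINE", "LINE", "DNA", "other"):
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")


class RepeatSet:
    def __init__(self, repeats: Iterable[RepeatFeature]):
        self.repeats: list[RepeatFeature] = list(repeats)
        self._trees: dict[str, IntervalTree] = {}
        for rep in self.repeats:
            self._trees.setdefault(rep.contig, IntervalTree()).addi(
                rep.start, rep.end + 1, rep)

    def __len__(self) -> int:
        return len(self.repeats)

    def overlapping(self, contig: str, pos: int) -> list[RepeatFeature]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree[pos]),
                      key=lambda r: (r.start, r.end))


@dataclass
class VariantObservation:
    """One called SNV in one sample, with depths and site annotations."""

    contig: str
    pos: int
    ref: str
    alt: str
    total_depth: int
    alt_depth: int
    genotype: str                          # het | hom_alt | hom_ref
    individual: str
    tissue: str
    annotations: dict = field(default_factory=dict)
    multi_allelic: bool = False
    all_alts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref equals alt")
        if not (0 <= self.alt_depth <= self.total_depth):
            raise ValueError("alt_depth outside [0, total_depth]")

    @property
    def sample(self) -> tuple[str, str]:
        return (self.individual, self.tissue)


@dataclass(frozen=True)
class MismatchClass:
    """A substitution label on the transcribed strand where resolvable.

    ``strand_source`` records how the strand was determined: from an
    overlapping gene, from a gene within the flank distance, supplied by the
    caller, or unresolvable (genomic plus-strand label reported).
    """

    label: str
    strand: str                            # '+' | '-'
    strand_source: str                     # gene | flank_gene | provided | unknown

    def __post_init__(self) -> None:
        if self.label not in MISMATCH_LABELS:
            raise ValueError(f"bad mismatch label {self.label!r}")
        if self.strand_source not in ("gene", "flank_gene", "provided", "unknown"):
            raise ValueError(f"bad strand_source {self.strand_source!r}")

    @property
    def is_a_to_i(self) -> bool:
        return self.label == "A>G"

    @property
    def is_c_to_u(self) -> bool:
        return self.label == "C>T"


@dataclass
class SampleSupport:
    individual: str
    tissue: str
    editing_ratio: float
    alt_depth: int
    total_depth: int


@dataclass
class SiteAnnotation:
    region: str = "intergenic"             # CDS|UTR5|UTR3|intron|pseudogene|upstream|downstream|intergenic
    gene_id: Optional[str] = None
    gene_symbol: Optional[str] = None
    consequence: Optional[str] = None      # synonymous|non_synonymous|stop_gained|stop_lost
    aa_change: Optional[str] = None
    repeat_class: Optional[str] = None
    repeat_family: Optional[str] = None


@dataclass
class EditingSite:
    """A strand-resolved candidate editing site with its per-sample support."""

    contig: str
    pos: int
    ref: str                               # transcribed strand
    alt: str
    mismatch: MismatchClass
    supports: list[SampleSupport] = field(default_factory=list)
    origin: str = "high_confidence"        # high_confidence | extended
    annotation: SiteAnnotation = field(default_factory=SiteAnnotation)
    cluster_id: Optional[str] = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def individuals(self) -> set[str]:
        return {s.individual for s in self.supports}

    @property
    def tissues(self) -> set[str]:
        return {s.tissue for s in self.supports}

    def tissue_ratio(self, tissue: str) -> float:
        ratios = [s.editing_ratio for s in self.supports if s.tissue == tissue]
        if not ratios:
            raise KeyError(f"no support in tissue {tissue}")
        return sum(ratios) / len(ratios)

    def mean_ratio(self) -> float:
        return sum(s.editing_ratio for s in self.supports) / len(self.supports)


@dataclass
class Cluster:
    id: str
    contig: str
    sites: list[EditingSite]               # sorted by pos

    @property
    def span(self) -> tuple[int, int]:
        return self.sites[0].pos, self.sites[-1].pos

    def __len__(self) -> int:
        return len(self.sites)
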