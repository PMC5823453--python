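"""Sequence- and structure-context checks behind the filter cascade.

Covers: maximal perfect tandem repeats (SSRs / microsatellites) with the
±3 bp exclusion zone, GATK-convention homopolymer runs, the 5 bp intronic
splice-junction margin, bidirectional (sense/antisense) transcription, and
the 101-bp flank self-uniqueness scan that removes sites whose flanking
sequence maps to more than one locus (paralogs, recent repeats).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from intervaltree import IntervalTree

from .align import KmerIndex, encode, smith_waterman
from .config import ThresholdConfig, DEFAULT_CONFIG
from .model import GeneModelSet, GenomeAssembly, RepeatSet, revcomp

log = logging.getLogger("editome")


# ---------------------------------------------------------------------------
# Simple sequence repeats


@dataclass(frozen=True)
class SSRInterval:
    """A maximal perfect tandem repeat (1-based inclusive interval).

    ``motif`` is the lexicographically minimal rotation of the repeat unit;
    ``copies`` counts full units within the span (partial trailing copies
    extend the span but not the count).
    """

    contig: str
    start: int
    end: int
    motif: str
    copies: int

    @property
    def total_len(self) -> int:
        return self.end - self.start + 1


def _is_primitive(motif: str) -> bool:
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def _min_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def find_ssrs(sequence: str, config: ThresholdConfig = DEFAULT_CONFIG,
              contig: str = "seq") -> list[SSRInterval]:
    """All maximal perfect tandem repeats with motif length 1–8 and span ≥ 6.

    A span must hold at least two full copies of its unit; units that are
    themselves periodic (e.g. ``AA``) are suppressed — the run is reported
    once under its primitive motif. N never participates in an SSR.
    """
    sequence = sequence.upper()
    codes = encode(sequence)
    n = codes.size
    lo, hi = config.ssr_motif_len_range
    out: list[SSRInterval] = []
    for m in range(lo, hi + 1):
        min_span = max(config.ssr_min_total_len, 2 * m)
        if n < min_span:
            continue
        eq = (codes[:-m] == codes[m:]) & (codes[:-m] != 255)
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)          # exclusive
        lengths = ends - starts
        keep = lengths >= (min_span - m)
        for j0, l in zip(starts[keep], lengths[keep]):
            motif = sequence[j0:j0 + m]
            if not _is_primitive(motif):
                continue
            span = int(l) + m
            out.append(SSRInterval(contig=contig, start=int(j0) + 1,
                                   end=int(j0) + span,
                                   motif=_min_rotation(motif),
                                   copies=span // m))
    out.sort(key=lambda r: (r.start, r.end, len(r.motif)))
    return out


def write_ssr_tsv(ssrs: list[SSRInterval], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tmotif\tcopies\n")
        for s in ssrs:
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.motif}\t{s.copies}\n")


def in_ssr_zone(pos: int, ssrs: list[SSRInterval],
                config: ThresholdConfig = DEFAULT_CONFIG) -> bool:
    """True iff ``pos`` falls within ±ssr_offset bases of any SSR interval."""
    off = config.ssr_offset
    return any(s.start - off <= pos <= s.end + off for s in ssrs)


# ---------------------------------------------------------------------------
# Homopolymer runs


def homopolymer_run(genome: GenomeAssembly, contig: str, pos: int,
                    alt_base: str) -> int:
    """Longest run of reference bases equal to ``alt_base`` immediately
    adjacent to ``pos`` (max of the left and right runs; GATK HRun
    convention)."""
    seq = genome.contigs[contig]
    i = pos - 1
    left = 0
    j = i - 1
    while j >= 0 and seq[j] == alt_base:
        left += 1
        j -= 1
    right = 0
    j = i + 1
    while j < len(seq) and seq[j] == alt_base:
        right += 1
        j += 1
    return max(left, right)


# ---------------------------------------------------------------------------
# Gene-structure context


def near_splice_junction(gene_models: GeneModelSet, contig: str, pos: int,
                         config: ThresholdConfig = DEFAULT_CONFIG) -> bool:
    """True iff ``pos`` is intronic and within ``splice_flank`` bases of an
    exon boundary (misalignment around junctions mimics editing)."""
    flank = config.splice_flank
    for gene in gene_models.genes_at(contig, pos):
        for tx in gene.transcripts:
            for istart, iend in tx.introns():
                if istart <= pos <= iend:
                    if pos - istart < flank or iend - pos < flank:
                        return True
    return False


def bidirectional_overlap(gene_models: GeneModelSet, contig: str, pos: int) -> bool:
    """True iff the position is covered by genes on both strands."""
    strands = {g.strand for g in gene_models.genes_at(contig, pos)}
    return strands == {"+", "-"}


# ---------------------------------------------------------------------------
# Flank uniqueness


@dataclass
class UniquenessResult:
    unique: bool
    n_hits: int
    clipped: bool = False

    def __bool__(self) -> bool:
        return self.unique


def flank_uniqueness(genome: GenomeAssembly, contig: str, pos: int,
                     config: ThresholdConfig = DEFAULT_CONFIG,
                     index: Optional[KmerIndex] = None,
                     max_candidates: int = 200) -> UniquenessResult:
    """Is the 101-bp window around ``pos`` unique in the assembly?

    The window (50 bp each side, clipped at contig bounds) is searched
    against the whole assembly, both strands, with 16-mer seeds grouped by
    diagonal and verified by local alignment. The site is unique iff exactly
    one locus — the self-hit — aligns at ≥90% identity over ≥90% of the
    window. An all-N window is conservatively non-unique.
    """
    flank = config.uniq_flank
    clen = genome.length(contig)
    start = max(1, pos - flank)
    end = min(clen, pos + flank)
    clipped = (start != pos - flank) or (end != pos + flank)
    window = genome.slice(contig, start, end)
    if set(window) <= {"N"}:
        return UniquenessResult(False, 0, clipped)
    if index is None:
        index = KmerIndex(genome.contigs)

    k = index.k
    min_cols = int(np.ceil(config.uniq_min_coverage * len(window)))
    loci: list[tuple[int, int]] = []     # merged global intervals of hits

    def add_locus(gs: int, ge: int) -> None:
        for i, (s, e) in enumerate(loci):
            if gs <= e and ge >= s:      # overlap → same locus
                loci[i] = (min(s, gs), max(e, ge))
                return
        loci.append((gs, ge))

    for q in (window, revcomp(window)):
        diags: dict[int, list[int]] = {}
        for off in range(0, len(q) - k + 1):
            for hit in index.query(q[off:off + k]):
                d = int(hit) - off
                diags.setdefault(d // 16, []).append(d)
        # merge neighbouring diagonal bins into candidate segments
        bins = sorted(diags)
        groups: list[list[int]] = []
        for b in bins:
            if groups and b - groups[-1][-1] <= 1:
                groups[-1].append(b)
            else:
                groups.append([b])
        if len(groups) > max_candidates:
            return UniquenessResult(False, len(groups), clipped)
        for grp in groups:
            ds = [d for b in grp for d in diags[b]]
            seg_start = min(ds) - 8
            seg_end = max(ds) + len(q) + 8
            tcontig, tlocal = index.locate(max(0, min(ds)))
            coff = index.offsets[index.contig_names.index(tcontig)]
            s0 = max(0, seg_start - coff)
            e0 = min(genome.length(tcontig), seg_end - coff)
            segment = genome.contigs[tcontig][s0:e0]
            if q in segment:
                t0 = segment.index(q)
                add_locus(coff + s0 + t0, coff + s0 + t0 + len(q))
                continue
            aln = smith_waterman(q, segment)
            if aln.columns >= min_cols and aln.identity >= config.uniq_min_identity:
                add_locus(coff + s0 + aln.target_start, coff + s0 + aln.target_end)
        if len(loci) > 1:
            return UniquenessResult(False, len(loci), clipped)
    return UniquenessResult(len(loci) == 1, len(loci), clipped)


def unique_from_psl(psl_path: str, query_name: str, query_len: int,
                    config: ThresholdConfig = DEFAULT_CONFIG) -> bool:
    """Ingest external aligner PSL output: unique iff exactly one hit covers
    ≥90% of the query at ≥90% identity."""
    hits = 0
    with open(psl_path) as fh:
        for line in fh:
            parts = line.split("\t")
            if len(parts) < 17 or not parts[0].isdigit():
                continue
            matches, mismatches = int(parts[0]), int(parts[1])
            qname = parts[9]
            if qname != query_name:
                continue
            cols = matches + mismatches + int(parts[5]) + int(parts[7])
            if cols >= config.uniq_min_coverage * query_len and \
                    matches / max(cols, 1) >= config.uniq_min_identity:
                hits += 1
    return hits == 1


# ---------------------------------------------------------------------------
# Memoising context for the cascade


class StudyContext:
    """Genome + annotation context with per-position memoisation.

    Bundles everything the positional filters need so the cascade can be run
    per-sample while context checks (which depend only on the position) are
    computed once per locus.
    """

    def __init__(self, genome: GenomeAssembly, gene_models: GeneModelSet,
                 repeats: Optional[RepeatSet] = None,
                 config: ThresholdConfig = DEFAULT_CONFIG):
        self.genome = genome
        self.gene_models = gene_models
        self.repeats = repeats if repeats is not None else RepeatSet([])
        self.config = config
        self._ssr_trees: dict[str, IntervalTree] = {}
        self._kmer_index: Optional[KmerIndex] = None
        self._memo: dict[str, dict] = {"splice": {}, "bidir": {}, "unique": {}}
        off = config.ssr_offset
        for name, seq in genome.contigs.items():
            tree = IntervalTree()
            for ssr in find_ssrs(seq, config, contig=name):
                tree.addi(ssr.start - off, ssr.end + off + 1, ssr)
            self._ssr_trees[name] = tree

    @property
    def kmer_index(self) -> KmerIndex:
        if self._kmer_index is None:
            self._kmer_index = KmerIndex(self.genome.contigs)
        return self._kmer_index

    def in_ssr_zone(self, contig: str, pos: int) -> bool:
        tree = self._ssr_trees.get(contig)
        return bool(tree is not None and tree[pos])

    def near_splice(self, contig: str, pos: int) -> bool:
        key = (contig, pos)
        memo = self._memo["splice"]
        if key not in memo:
            memo[key] = near_splice_junction(self.gene_models, contig, pos,
                                             self.config)
        return memo[key]

    def bidirectional(self, contig: str, pos: int) -> bool:
        key = (contig, pos)
        memo = self._memo["bidir"]
        if key not in memo:
            memo[key] = bidirectional_overlap(self.gene_models, contig, pos)
        return memo[key]

    def flank_unique(self, contig: str, pos: int) -> bool:
        key = (contig, pos)
        memo = self._memo["unique"]
        if key not in memo:
            memo[key] = flank_uniqueness(self.genome, contig, pos, self.config,
                                         index=self.kmer_index).unique
        return memo[key]
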