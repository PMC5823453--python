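"""Flank-alignment validation against EST or known-editome sequence sets.

Each 101-nt flank is aligned locally against every reference sequence
(k-mer prefilter, then affine-gap Smith–Waterman at +1/−2, gap open 5,
extend 2). Significance uses Karlin–Altschul statistics with a database-
size correction: E = K·m·n·e^(−λS). λ is solved numerically for the score
scheme under uniform base composition; K is taken from the standard
ungapped nucleotide table for +1/−2. Exact replication of a full search
engine's statistics is a non-goal — the thresholds dominate the decision.

Two published operating profiles are provided: EST support (E ≤ 1e−5) and
cross-species conservation (E ≤ 1e−3, identity ≥ 0.85, alignment ≥ 50 nt).
An external tabular (BLAST outfmt-6) ingest is available for real-scale
searches.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio import SeqIO
from scipy.optimize import brentq

from .align import LocalAlignment, smith_waterman
from .config import ThresholdConfig, DEFAULT_CONFIG
from .model import revcomp

log = logging.getLogger("editome")


@dataclass(frozen=True)
class ValidationProfile:
    name: str
    max_evalue: float
    min_identity: Optional[float] = None
    min_alnlen: Optional[int] = None

    @classmethod
    def est(cls, config: ThresholdConfig = DEFAULT_CONFIG) -> "ValidationProfile":
        return cls("est", config.est_evalue)

    @classmethod
    def conservation(cls, config: ThresholdConfig = DEFAULT_CONFIG,
                     ) -> "ValidationProfile":
        return cls("conservation", config.cons_evalue,
                   config.cons_min_identity, config.cons_min_alnlen)


def karlin_altschul_lambda(match: float = 1.0, mismatch: float = -2.0,
                           p_match: float = 0.25) -> float:
    """Solve Σ pᵢ e^{λsᵢ} = 1 for the positive root λ."""

    def f(lam: float) -> float:
        return (p_match * math.exp(lam * match)
                + (1 - p_match) * math.exp(lam * mismatch) - 1.0)

    return float(brentq(f, 1e-6, 10.0))


#: Ungapped K for the +1/−2 nucleotide scheme (standard tabulated value).
KA_K = 0.621


def evalue(score: float, query_len: int, db_len: int,
           lam: Optional[float] = None, k: float = KA_K) -> float:
    if lam is None:
        lam = karlin_altschul_lambda()
    return k * query_len * db_len * math.exp(-lam * score)


@dataclass
class HitStats:
    n_hits: int
    best_evalue: float
    best_identity: float
    best_alnlen: int
    best_score: float


def _shared_kmer(a: str, b: str, k: int = 11) -> bool:
    if len(a) < k or len(b) < k:
        return a in b or b in a
    kmers = {a[i:i + k] for i in range(len(a) - k + 1)}
    return any(b[i:i + k] in kmers for i in range(len(b) - k + 1))


def match_reference(flanks: Sequence[str],
                    reference: "str | Sequence[str]",
                    profile: ValidationProfile,
                    search_both_strands: bool = True) -> list[HitStats]:
    """Count supporting reference sequences per flank.

    ``reference`` is a FASTA path or an in-memory list of sequences. A
    reference record supports a flank iff its best local alignment passes
    the profile's e-value (database-size corrected) and, where the profile
    sets them, the identity and alignment-length floors. Absent criteria
    are skipped. Counts do not depend on record order.
    """
    if isinstance(reference, str):
        ref_seqs = [str(r.seq).upper() for r in SeqIO.parse(reference, "fasta")]
    else:
        ref_seqs = [s.upper() for s in reference]
    if not ref_seqs:
        log.warning("empty reference set: all support counts are zero")
        return [HitStats(0, math.inf, 0.0, 0, 0.0) for _ in flanks]

    db_len = sum(len(s) for s in ref_seqs)
    lam = karlin_altschul_lambda()
    out: list[HitStats] = []
    for flank in flanks:
        flank = flank.upper()
        n_hits = 0
        best = HitStats(0, math.inf, 0.0, 0, 0.0)
        for ref in ref_seqs:
            candidates = [ref, revcomp(ref)] if search_both_strands else [ref]
            top: Optional[LocalAlignment] = None
            for oriented in candidates:
                if not _shared_kmer(flank, oriented):
                    continue
                aln = smith_waterman(flank, oriented)
                if top is None or aln.score > top.score:
                    top = aln
            if top is None or top.columns == 0:
                continue
            e = evalue(top.score, len(flank), db_len, lam)
            if e > profile.max_evalue:
                continue
            if profile.min_identity is not None and top.identity < profile.min_identity:
                continue
            if profile.min_alnlen is not None and top.columns < profile.min_alnlen:
                continue
            n_hits += 1
            if e < best.best_evalue:
                best = HitStats(0, e, top.identity, top.columns, top.score)
        out.append(HitStats(n_hits, best.best_evalue, best.best_identity,
                            best.best_alnlen, best.best_score))
    return out


def hits_from_tabular(path: str, profile: ValidationProfile,
                      ) -> dict[str, int]:
    """Ingest BLAST outfmt-6 results: query → number of qualifying hits.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. ``pident`` is a percentage.
    """
    counts: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            qseqid, pident, length, e = (parts[0], float(parts[2]),
                                         int(parts[3]), float(parts[10]))
            if e > profile.max_evalue:
                continue
            if profile.min_identity is not None and pident / 100.0 < profile.min_identity:
                continue
            if profile.min_alnlen is not None and length < profile.min_alnlen:
                continue
            counts[qseqid] = counts.get(qseqid, 0) + 1
    return counts
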