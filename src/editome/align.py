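"""Seeded local alignment primitives.

A small Gotoh (affine-gap) Smith–Waterman and a numpy k-mer index over an
assembly. The scoring scheme follows common nucleotide-search practice:
match +1, mismatch −2, gap open 5, gap extend 2 (a gap of length L costs
open + L·extend). These primitives back the 101-bp flank-uniqueness filter
and the EST/conservation matcher; they are deliberately desk-scale, with a
pluggable ingest for external aligner output on real genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NEG = float("-inf")


@dataclass
class LocalAlignment:
    score: float
    matches: int
    columns: int                 # aligned columns, gaps included
    query_start: int             # 0-based, half-open spans
    query_end: int
    target_start: int
    target_end: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def smith_waterman(query: str, target: str,
                   match: float = 1.0, mismatch: float = -2.0,
                   gap_open: float = 5.0, gap_extend: float = 2.0,
                   ) -> LocalAlignment:
    """Best local alignment of ``query`` vs ``target`` (Gotoh affine gaps)."""
    m, n = len(query), len(target)
    if m == 0 or n == 0:
        return LocalAlignment(0.0, 0, 0, 0, 0, 0, 0)
    open_cost = gap_open + gap_extend

    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]   # gap in query (move in target)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]   # gap in target
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        qi = query[i - 1]
        Hi, Hp = H[i], H[i - 1]
        Ei, Fi, Fp = E[i], F[i], F[i - 1]
        for j in range(1, n + 1):
            e = max(Hi[j - 1] - open_cost, Ei[j - 1] - gap_extend)
            f = max(Hp[j] - open_cost, Fp[j] - gap_extend)
            diag = Hp[j - 1] + (match if qi == target[j - 1] else mismatch)
            h = max(0.0, diag, e, f)
            Ei[j], Fi[j], Hi[j] = e, f, h
            if h > best:
                best, bi, bj = h, i, j
    if best == 0.0:
        return LocalAlignment(0.0, 0, 0, 0, 0, 0, 0)

    # traceback from (bi, bj)
    i, j, state = bi, bj, "H"
    matches = columns = 0
    while i > 0 and j > 0:
        h = H[i][j]
        if state == "H" and h == 0.0:
            break
        if state == "E" or (state == "H" and h == E[i][j]):
            # gap in query: decide whether the gap extends left
            columns += 1
            if E[i][j] == E[i][j - 1] - gap_extend and E[i][j] != H[i][j - 1] - open_cost:
                state = "E"
            else:
                state = "H"
            j -= 1
            continue
        if state == "F" or (state == "H" and h == F[i][j]):
            columns += 1
            if F[i][j] == F[i - 1][j] - gap_extend and F[i][j] != H[i - 1][j] - open_cost:
                state = "F"
            else:
                state = "H"
            i -= 1
            continue
        # diagonal
        columns += 1
        if query[i - 1] == target[j - 1]:
            matches += 1
        i -= 1
        j -= 1
        state = "H"
    return LocalAlignment(best, matches, columns, i, bi, j, bj)


# ---------------------------------------------------------------------------
# k-mer index

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(values, valid_mask) of all k-mers; windows containing non-ACGT are invalid."""
    n = codes.size
    if n < k:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool))
    m = n - k + 1
    vals = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        vals = (vals << np.uint64(2)) | codes[j:j + m].astype(np.uint64)
    bad = (codes == 255).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[k:] - cum[:-k]) == 0
    return vals, valid


class KmerIndex:
    """Sorted-array index of every valid k-mer position in an assembly."""

    def __init__(self, contigs: dict[str, str], k: int = 16):
        self.k = k
        self.contig_names: list[str] = []
        self.offsets: list[int] = []
        values_parts, pos_parts = [], []
        offset = 0
        for name, seq in contigs.items():
            codes = encode(seq)
            vals, valid = kmer_values(codes, k)
            idx = np.nonzero(valid)[0]
            values_parts.append(vals[idx])
            pos_parts.append(idx.astype(np.int64) + offset)
            self.contig_names.append(name)
            self.offsets.append(offset)
            offset += len(seq)
        self.total_len = offset
        values = np.concatenate(values_parts) if values_parts else np.empty(0, np.uint64)
        positions = np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64)
        order = np.argsort(values, kind="stable")
        self._values = values[order]
        self._positions = positions[order]

    def locate(self, global_pos: int) -> tuple[str, int]:
        """Map a global 0-based offset to (contig, 0-based local offset)."""
        import bisect
        i = bisect.bisect_right(self.offsets, global_pos) - 1
        return self.contig_names[i], global_pos - self.offsets[i]

    def query(self, kmer: str) -> np.ndarray:
        """Global 0-based start positions of exact occurrences of ``kmer``."""
        codes = encode(kmer)
        if codes.size != self.k or (codes == 255).any():
            return np.empty(0, dtype=np.int64)
        val = np.uint64(0)
        for c in codes:
            val = (val << np.uint64(2)) | np.uint64(c)
        lo = np.searchsorted(self._values, val, side="left")
        hi = np.searchsorted(self._values, val, side="right")
        return self._positions[lo:hi]
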