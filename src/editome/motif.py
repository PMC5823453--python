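"""Neighbor-preference matrices around edited adenosines.

ADARs show strong local sequence preferences — depletion of G immediately
5′ of the edited A and enrichment of G immediately 3′ — so the position
frequency matrix over ±10 bp of the candidate set is a cheap fingerprint of
genuine A-to-I editing. All windows are taken on the transcribed strand,
with the edited A at position 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ThresholdConfig, DEFAULT_CONFIG
from .model import EditingSite, GenomeAssembly, revcomp

BASES = "ACGT"


class StrandResolutionError(ValueError):
    """The extracted window is not centred on an A: upstream classification bug."""


@dataclass
class FlankWindow:
    seq: str                  # transcribed strand
    center: int               # 0-based index of the edited base within seq
    clipped: bool


def extract_flanks(site: EditingSite, genome: GenomeAssembly,
                   flank: int = 50, require_a: bool = True) -> FlankWindow:
    """Window of ``flank`` bases each side of the site, transcribed strand.

    Minus-strand sites are reverse-complemented so the edited base reads A.
    Windows truncated by a contig edge are flagged clipped.
    """
    clen = genome.length(site.contig)
    start = max(1, site.pos - flank)
    end = min(clen, site.pos + flank)
    clipped = (start != site.pos - flank) or (end != site.pos + flank)
    seq = genome.slice(site.contig, start, end)
    center = site.pos - start
    if site.mismatch.strand == "-":
        seq = revcomp(seq)
        center = len(seq) - 1 - center
    if require_a and seq[center] != "A":
        raise StrandResolutionError(
            f"window center at {site.contig}:{site.pos} is {seq[center]}, "
            "expected A on the transcribed strand")
    return FlankWindow(seq=seq, center=center, clipped=clipped)


@dataclass
class PositionFrequencyMatrix:
    """Per-position base counts over −flank..+flank (0 = edited A)."""

    counts: pd.DataFrame              # index: positions, columns: A C G T

    @property
    def positions(self) -> list[int]:
        return list(self.counts.index)

    def column_total(self, position: int) -> int:
        return int(self.counts.loc[position].sum())

    def base_fraction(self, position: int, base: str) -> float:
        total = self.column_total(position)
        return self.counts.loc[position, base] / total if total else 0.0

    def information_content(self) -> pd.Series:
        """2 − Shannon entropy per position, in bits (no small-sample
        correction)."""
        out = {}
        for position in self.positions:
            total = self.column_total(position)
            if total == 0:
                out[position] = 0.0
                continue
            p = self.counts.loc[position].to_numpy(dtype=float) / total
            nz = p[p > 0]
            out[position] = 2.0 + float(np.sum(nz * np.log2(nz)))
        return pd.Series(out)

    def to_tsv(self, path: str) -> None:
        frame = self.counts.copy()
        frame["bits"] = self.information_content()
        frame.to_csv(path, sep="\t", index_label="position")


def neighbor_pfm(sites: Sequence[EditingSite], genome: GenomeAssembly,
                 config: ThresholdConfig = DEFAULT_CONFIG,
                 ) -> PositionFrequencyMatrix:
    """Base counts per position around the edited A (A-to-I sites only).

    Edge-clipped sites contribute only the columns they cover, so column
    totals equal the number of contributing sites per column.
    """
    flank = config.motif_flank
    positions = list(range(-flank, flank + 1))
    counts = pd.DataFrame(0, index=positions, columns=list(BASES))
    contributed = False
    for site in sites:
        if not site.mismatch.is_a_to_i:
            continue
        window = extract_flanks(site, genome, flank=flank)
        for offset in positions:
            idx = window.center + offset
            if 0 <= idx < len(window.seq):
                base = window.seq[idx]
                if base in BASES:
                    counts.loc[offset, base] += 1
        contributed = True
    if not contributed:
        raise ValueError("no A-to-I sites to build a matrix from")
    return PositionFrequencyMatrix(counts=counts)
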