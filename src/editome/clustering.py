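"""Hyper-editing clusters and the 100 bp extension step.

ADARs edit promiscuously along a double-stranded region, so true A-to-I
sites aggregate in short runs. Two sites on the same contig belong to one
cluster when their positions differ by at most the cluster window (100 bp,
inclusive), chained transitively (single linkage). The extension step uses
this property to recruit additional SNVs — those surviving only the basic
quality filters and known-SNP subtraction — that lie within the window of a
high-confidence A-to-I site.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from typing import Iterable, Optional, Sequence

from .config import ThresholdConfig, DEFAULT_CONFIG
from .filters import editing_ratio
from .mismatch import classify_mismatch, transcribed_alleles
from .model import (
    Cluster,
    EditingSite,
    GeneModelSet,
    MismatchClass,
    SampleSupport,
    VariantObservation,
)


def detect_clusters(sites: Sequence[EditingSite],
                    config: ThresholdConfig = DEFAULT_CONFIG,
                    ) -> tuple[list[Cluster], list[EditingSite]]:
    """Partition sites into maximal ≤window-gap chains and singletons."""
    window = config.cluster_window
    by_contig: dict[str, list[EditingSite]] = defaultdict(list)
    for site in sites:
        by_contig[site.contig].append(site)

    clusters: list[Cluster] = []
    singletons: list[EditingSite] = []
    serial = 0
    for contig in sorted(by_contig):
        members = sorted(by_contig[contig], key=lambda s: s.pos)
        chain = [members[0]]
        for site in members[1:]:
            if site.pos - chain[-1].pos <= window:
                chain.append(site)
            else:
                serial = _flush(chain, contig, serial, clusters, singletons)
                chain = [site]
        serial = _flush(chain, contig, serial, clusters, singletons)
    return clusters, singletons


def _flush(chain: list[EditingSite], contig: str, serial: int,
           clusters: list[Cluster], singletons: list[EditingSite]) -> int:
    if len(chain) >= 2:
        serial += 1
        cluster = Cluster(id=f"cluster_{serial:04d}", contig=contig,
                          sites=list(chain))
        for site in chain:
            site.cluster_id = cluster.id
        clusters.append(cluster)
    else:
        singletons.extend(chain)
    return serial


def extend_sites(high_conf: Sequence[EditingSite],
                 pool: Iterable[VariantObservation],
                 gene_models: GeneModelSet,
                 config: ThresholdConfig = DEFAULT_CONFIG,
                 ) -> list[EditingSite]:
    """Recruit pool SNVs within the cluster window of a high-confidence
    A-to-I site.

    The pool is the pre-cascade set (quality filters + known-SNP subtraction
    only) and is not restricted to A>G: recruited sites keep their own
    mismatch class, which is how the A-to-I fraction of the added set stays
    a meaningful read-out. Recruitment is single-pass — newly added sites do
    not themselves anchor further recruitment — unless the transitive switch
    is set. Output excludes sites already in the high-confidence set.
    """
    window = config.cluster_window
    hc_keys = {(s.contig, s.pos) for s in high_conf}
    anchors: dict[str, list[int]] = defaultdict(list)
    for site in high_conf:
        if site.mismatch.is_a_to_i:
            anchors[site.contig].append(site.pos)
    for positions in anchors.values():
        positions.sort()

    # deduplicate pool observations into candidate sites with support lists
    grouped: dict[tuple, list[VariantObservation]] = defaultdict(list)
    for obs in pool:
        grouped[(obs.contig, obs.pos, obs.ref, obs.alt)].append(obs)

    def near_anchor(contig: str, pos: int, extra: dict | None = None) -> bool:
        for source in (anchors, extra or {}):
            positions = source.get(contig)
            if not positions:
                continue
            i = bisect.bisect_left(positions, pos)
            for j in (i - 1, i):
                if 0 <= j < len(positions) and abs(positions[j] - pos) <= window:
                    return True
        return False

    added: list[EditingSite] = []
    added_positions: dict[str, list[int]] = defaultdict(list)
    pending = sorted(grouped.items())
    changed = True
    first_pass = True
    while changed:
        changed = False
        remaining = []
        for key, observations in pending:
            contig, pos, ref, alt = key
            if (contig, pos) in hc_keys or not near_anchor(
                    contig, pos, added_positions if config.transitive_extension else None):
                remaining.append((key, observations))
                continue
            klass = classify_mismatch(observations[0], gene_models, config=config)
            if klass is None:       # bidirectional region: strand ambiguous
                remaining.append((key, observations))
                continue
            t_ref, t_alt = transcribed_alleles(observations[0], klass.strand)
            supports = [SampleSupport(o.individual, o.tissue,
                                      editing_ratio(o) if o.total_depth else 0.0,
                                      o.alt_depth, o.total_depth)
                        for o in observations]
            site = EditingSite(contig=contig, pos=pos, ref=t_ref, alt=t_alt,
                               mismatch=klass, supports=supports,
                               origin="extended")
            added.append(site)
            bisect.insort(added_positions[contig], pos)
            changed = True
        pending = remaining
        first_pass = False
        if not config.transitive_extension:
            break
    # a recruited A>G position must not duplicate another recruit
    seen = set()
    deduped = []
    for site in added:
        if (site.contig, site.pos) not in seen:
            seen.add((site.contig, site.pos))
            deduped.append(site)
    return deduped


def a_to_i_fraction(sites: Sequence[EditingSite]) -> float:
    """Percent of sites whose transcribed-strand class is A>G."""
    if not sites:
        return 0.0
    return 100.0 * sum(1 for s in sites if s.mismatch.is_a_to_i) / len(sites)
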