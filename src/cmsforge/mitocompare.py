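"""Detection of CMS-specific mitogenome regions by k-mer anchor coverage.

Plant mitochondrial genomes of close relatives are largely colinear at the
nucleotide level but CMS cytoplasms carry rearrangement-born novel regions.
We operationalize "specific / highly diverged" as: not covered by any chain
of exact shared k-mers against any genome of a non-CMS reference panel.
Isolated substitutions only break individual k-mers inside a chain and do
not interrupt coverage; a novel insert breaks the anchor diagonal and leaves
an uncovered gap.

Anchors between two genomes are exact shared k-mers (both strands; circular
genomes are virtually extended by k-1 bases). Colinear anchors on a common
diagonal, with query gaps no larger than ``max_gap``, are merged into an
AnchorChain; chain spans define coverage. Per-reference uncovered intervals
are intersected across the panel, merged across small gaps, and filtered by
a minimum length to yield SpecificRegions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from ._io import (
    Genome,
    Gff3Feature,
    complement_intervals,
    intersect_intervals,
    merge_intervals,
    revcomp,
)

DEFAULT_K = 15
DEFAULT_MAX_GAP = 2_000
DEFAULT_MIN_REGION_LENGTH = 500
DEFAULT_MERGE_GAP = 1_000


@dataclass
class AnchorChain:
    """A colinear run of exact k-mer matches between query and reference.

    Coordinates are 0-based half-open on the linear sequences (positions on a
    circular query may exceed the sequence length by < k-1 where a window
    spans the origin).
    """

    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    n_anchors: int
    orientation: str  # "+" or "-"

    def __post_init__(self):
        assert self.query_end > self.query_start and self.ref_end > self.ref_start


@dataclass
class SpecificRegion:
    """A query interval uncovered by every reference in the panel."""

    start: int
    end: int
    uncovered_by: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_feature(self, seqid: str) -> Gff3Feature:
        return Gff3Feature(
            seqid,
            "cmsforge",
            "cms_specific_region",
            self.start,
            self.end,
            None,
            ".",
            ".",
            {"uncovered_by": ",".join(self.uncovered_by)},
        )


def _kmer_index(seq: str, k: int, circular: bool) -> dict[str, list[int]]:
    if circular:
        seq = seq + seq[: k - 1]
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def anchor_map(
    query: Genome, reference: Genome, k: int = DEFAULT_K, max_gap: int = DEFAULT_MAX_GAP
) -> list[AnchorChain]:
    """Find all exact shared k-mers and chain them into colinear runs.

    Returns chains sorted by query_start. Forward anchors share the diagonal
    ``qpos - rpos``; reverse anchors (query k-mer equals the reverse
    complement of a reference k-mer) share ``qpos + rpos``. A chain breaks
    when the query gap to the next anchor on its diagonal exceeds
    ``max_gap``.
    """
    if min(len(query), len(reference)) == 0:
        raise ValueError("genomes must be non-empty")
    if k < 11:
        raise ValueError("k must be >= 11")
    if k > len(query.seq) or k > len(reference.seq):
        warnings.warn("k exceeds a genome length; no anchors possible")
        return []

    ref_index = _kmer_index(reference.seq, k, reference.circular)
    qseq = query.seq + query.seq[: k - 1] if query.circular else query.seq

    # anchors grouped by (orientation, diagonal)
    groups: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for i in range(len(qseq) - k + 1):
        kmer = qseq[i : i + k]
        for rpos in ref_index.get(kmer, ()):
            groups.setdefault(("+", i - rpos), []).append((i, rpos))
        for rpos in ref_index.get(revcomp(kmer), ()):
            groups.setdefault(("-", i + rpos), []).append((i, rpos))

    chains: list[AnchorChain] = []
    for (orient, _diag), anchors in groups.items():
        anchors.sort()
        run_start = 0
        for idx in range(1, len(anchors) + 1):
            if idx == len(anchors) or anchors[idx][0] - anchors[idx - 1][0] > max_gap:
                run = anchors[run_start:idx]
                qpos = [a[0] for a in run]
                rpos = [a[1] for a in run]
                chains.append(
                    AnchorChain(
                        query_start=qpos[0],
                        query_end=qpos[-1] + k,
                        ref_start=min(rpos),
                        ref_end=max(rpos) + k,
                        n_anchors=len(run),
                        orientation=orient,
                    )
                )
                run_start = idx
    chains.sort(key=lambda c: (c.query_start, c.query_end, c.ref_start))
    return chains


def chain_coverage(chains: list[AnchorChain], query_length: int) -> list[tuple[int, int]]:
    """Union of chain query spans, clipped/wrapped to [0, query_length)."""
    intervals = []
    for chain in chains:
        start, end = chain.query_start, chain.query_end
        if start >= query_length:
            start, end = start - query_length, end - query_length
        if end > query_length:
            intervals.append((start, query_length))
            intervals.append((0, end - query_length))
        else:
            intervals.append((start, end))
    return merge_intervals(intervals)


def specific_regions(
    query: Genome,
    references: list[Genome],
    k: int = DEFAULT_K,
    min_region_length: int = DEFAULT_MIN_REGION_LENGTH,
    merge_gap: int = DEFAULT_MERGE_GAP,
    max_gap: int = DEFAULT_MAX_GAP,
    min_anchors: int = 2,
) -> list[SpecificRegion]:
    """Query intervals uncovered by anchor chains against every reference.

    Chains with fewer than ``min_anchors`` anchors are treated as chance
    k-mer collisions (a few hundred are expected between ~450 kb random
    sequences at k=15) and do not count as coverage; any genuinely conserved
    block of appreciable length yields densely anchored chains.
    """
    if not references:
        raise ValueError("need at least one reference genome")
    L = len(query.seq)
    uncovered_by_ref: dict[str, list[tuple[int, int]]] = {}
    common: list[tuple[int, int]] | None = None
    for ref in references:
        chains = anchor_map(query, ref, k=k, max_gap=max_gap)
        chains = [c for c in chains if c.n_anchors >= min_anchors]
        uncovered = complement_intervals(chain_coverage(chains, L), L)
        uncovered_by_ref[ref.id] = uncovered
        common = uncovered if common is None else intersect_intervals(common, uncovered)

    merged = merge_intervals(common, gap=merge_gap)
    regions = []
    for start, end in merged:
        if end - start < min_region_length:
            continue
        missing = [
            ref_id
            for ref_id, uncov in uncovered_by_ref.items()
            if any(s < end and start < e for s, e in uncov)
        ]
        regions.append(SpecificRegion(start, end, uncovered_by=missing))
    return regions
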