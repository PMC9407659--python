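"""ORF calling in candidate regions and decomposition into donor segments.

Chimeric mitochondrial ORFs — the classic molecular signature of CMS
determinants — are fusions of fragments from distinct origins. Given an ORF
and a panel of candidate donor genomes, ``decompose_orf`` finds local donor
matches (exact seed words chained on a diagonal, ends refined by ungapped
X-drop extension trimmed back to the best score) and selects the
non-overlapping tiling of the ORF that maximizes total donor-assigned
length. Stretches no donor explains become "unknown" segments. An ORF whose
tiling mixes distinct sources is classified chimeric.

The donor model is substitution-only (identity = matches / alignment
columns, and no gaps arise under that model); indel-divergent donors would
need a banded gapped extension, which is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from Bio.Seq import Seq

from ._io import Genome, revcomp

DEFAULT_MIN_AA = 50
DEFAULT_SEED_LEN = 12
DEFAULT_MIN_IDENTITY = 0.70
DEFAULT_MIN_SEGMENT = 30
# seeds on one (donor, strand, diagonal) can span at most the ORF length, so
# same-diagonal runs are merged across wide gaps; the identity floor, not the
# gap, is what rejects bad chains
DEFAULT_CHAIN_GAP = 10_000
XDROP = 4

STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class OrfCall:
    """An ATG-initiated open reading frame, 0-based half-open on the region."""

    start: int
    end: int
    strand: str
    frame: int
    sequence: str

    @property
    def aa_length(self) -> int:
        return (self.end - self.start) // 3 - 1

    def translate(self) -> str:
        return str(Seq(self.sequence[:-3]).translate())


def call_orfs(region: str, min_aa: int = DEFAULT_MIN_AA) -> list[OrfCall]:
    """Six-frame ATG-to-stop ORF scan under the standard genetic code.

    Among nested ORFs sharing a stop codon only the longest is reported.
    Ambiguous bases never act as start or stop codons (their codons simply
    fail to match). Results are sorted by start coordinate.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    region = region.upper()
    n = len(region)
    orfs: list[OrfCall] = []
    for strand, seq in (("+", region), ("-", revcomp(region))):
        for frame in range(3):
            start_codon: int | None = None
            for i in range(frame, n - 2, 3):
                codon = seq[i : i + 3]
                if start_codon is None and codon == "ATG":
                    start_codon = i
                elif start_codon is not None and codon in STOPS:
                    s, e = start_codon, i + 3
                    if (e - s) // 3 - 1 >= min_aa:
                        if strand == "+":
                            orfs.append(OrfCall(s, e, "+", frame, seq[s:e]))
                        else:
                            orfs.append(OrfCall(n - e, n - s, "-", frame, seq[s:e]))
                    start_codon = None
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


# ---------------------------------------------------------------------------
# donor decomposition


@dataclass
class DonorHit:
    """A local match between an ORF interval and a donor interval."""

    orf_start: int
    orf_end: int
    donor_id: str
    donor_start: int
    donor_end: int
    strand: str
    identity: float

    @property
    def length(self) -> int:
        return self.orf_end - self.orf_start


@dataclass
class Segment:
    orf_start: int
    orf_end: int
    donor_id: str  # donor id or "unknown"
    donor_start: int | None = None
    donor_end: int | None = None
    identity: float | None = None

    @property
    def length(self) -> int:
        return self.orf_end - self.orf_start


@dataclass
class SegmentDecomposition:
    orf_id: str
    orf_length: int
    segments: list[Segment] = field(default_factory=list)
    origin_class: str = "unknown"


def _seed_hits(orf: str, donor: Genome, seed_len: int, chain_gap: int) -> list[DonorHit]:
    """Exact seed matches grouped into diagonal runs (both donor strands)."""
    index: dict[str, list[tuple[str, int]]] = {}
    dseq = donor.seq
    rseq = revcomp(dseq)
    for strand, seq in (("+", dseq), ("-", rseq)):
        for i in range(len(seq) - seed_len + 1):
            index.setdefault(seq[i : i + seed_len], []).append((strand, i))

    groups: dict[tuple[str, int], list[int]] = {}
    for i in range(len(orf) - seed_len + 1):
        for strand, dpos in index.get(orf[i : i + seed_len], ()):
            groups.setdefault((strand, i - dpos), []).append(i)

    hits = []
    for (strand, diag), qpos in groups.items():
        qpos.sort()
        run_start = 0
        for idx in range(1, len(qpos) + 1):
            if idx == len(qpos) or qpos[idx] - qpos[idx - 1] > chain_gap:
                q0, q1 = qpos[run_start], qpos[idx - 1] + seed_len
                hits.append(_refine_hit(orf, donor, strand, diag, q0, q1, seed_len))
                run_start = idx
    return hits


def _refine_hit(
    orf: str, donor: Genome, strand: str, diag: int, q0: int, q1: int, seed_len: int
) -> DonorHit:
    """Extend a seed chain outward by ungapped X-drop, trimmed to the
    maximum-scoring endpoint (match +1, mismatch -1)."""
    dseq = donor.seq if strand == "+" else revcomp(donor.seq)

    def extend(direction: int, qpos: int) -> int:
        score = best = 0
        best_steps = 0
        steps = 0
        q, d = qpos, qpos - diag
        while True:
            q += direction
            d += direction
            if not (0 <= q < len(orf) and 0 <= d < len(dseq)):
                break
            steps += 1
            score += 1 if orf[q] == dseq[d] else -1
            if score > best:
                best, best_steps = score, steps
            if score <= best - XDROP:
                break
        return best_steps if best > 0 else 0

    q0 -= extend(-1, q0)
    q1 += extend(+1, q1 - 1)
    aligned = dseq[q0 - diag : q1 - diag]
    matches = sum(1 for a, b in zip(orf[q0:q1], aligned) if a == b)
    identity = matches / (q1 - q0)
    if strand == "+":
        d0, d1 = q0 - diag, q1 - diag
    else:  # map back to forward donor coordinates
        d0, d1 = len(dseq) - (q1 - diag), len(dseq) - (q0 - diag)
    return DonorHit(q0, q1, donor.id, d0, d1, strand, identity)


def _best_tiling(hits: list[DonorHit]) -> list[DonorHit]:
    """Non-overlapping subset maximizing total covered length; ties broken by
    fewer segments, then leftmost start coordinates.

    O(n^2) dynamic program over hits sorted by end coordinate; hit counts per
    ORF are small. Solutions are compared as (total length, -count,
    leftmost-preferred start tuple)."""
    if not hits:
        return []
    order = sorted(range(len(hits)), key=lambda i: (hits[i].orf_end, hits[i].orf_start))

    def key(total: int, sel: list[int]) -> tuple:
        return (total, -len(sel), tuple(-hits[x].orf_start for x in sel))

    # partial[oi] = best solution whose rightmost hit is order[oi]
    partial: list[tuple[int, list[int]]] = []
    for oi, i in enumerate(order):
        best = (hits[i].length, [i])
        for oj in range(oi):
            j = order[oj]
            if hits[j].orf_end <= hits[i].orf_start:
                total, sel = partial[oj]
                cand = (total + hits[i].length, sel + [i])
                if key(*cand) > key(*best):
                    best = cand
        partial.append(best)
    total, sel = max(partial, key=lambda t: key(*t))
    return [hits[i] for i in sorted(sel, key=lambda i: hits[i].orf_start)]


def brute_force_tiling(hits: list[DonorHit]) -> int:
    """Exhaustive-enumeration oracle: maximum total non-overlapping hit
    length over all hit subsets. Exponential; for tests on tiny inputs."""
    best = 0
    for r in range(len(hits) + 1):
        for subset in combinations(hits, r):
            ordered = sorted(subset, key=lambda h: h.orf_start)
            if all(a.orf_end <= b.orf_start for a, b in zip(ordered, ordered[1:])):
                best = max(best, sum(h.length for h in ordered))
    return best


def decompose_orf(
    orf: str,
    donors: list[Genome],
    orf_id: str = "orf",
    seed_len: int = DEFAULT_SEED_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_segment: int = DEFAULT_MIN_SEGMENT,
    chain_gap: int = DEFAULT_CHAIN_GAP,
    self_donor_ids: set[str] | None = None,
) -> SegmentDecomposition:
    """Tile ``orf`` with donor-assigned segments and classify its origin.

    Hits shorter than ``min_segment`` or below ``min_identity`` are noise and
    discarded. Uncovered stretches >= ``min_segment`` become "unknown"
    segments; shorter gaps are absorbed into the neighboring segments, split
    at the gap midpoint (edge gaps go entirely to their single neighbor).
    """
    if not donors:
        raise ValueError("donor panel must be non-empty")
    orf = orf.upper()
    hits: list[DonorHit] = []
    for donor in donors:
        hits.extend(_seed_hits(orf, donor, seed_len, chain_gap))
    hits = [h for h in hits if h.identity >= min_identity and h.length >= min_segment]
    chosen = _best_tiling(hits)

    segments: list[Segment] = []
    if not chosen:
        segments.append(Segment(0, len(orf), "unknown"))
    else:
        # place assigned segments, then resolve gaps
        assigned = [
            Segment(h.orf_start, h.orf_end, h.donor_id, h.donor_start, h.donor_end, h.identity)
            for h in chosen
        ]
        # leading gap
        first = assigned[0]
        if first.orf_start > 0:
            if first.orf_start >= min_segment:
                segments.append(Segment(0, first.orf_start, "unknown"))
            else:
                first.orf_start = 0
        for left, right in zip(assigned, assigned[1:]):
            segments.append(left)
            gap = right.orf_start - left.orf_end
            if gap >= min_segment:
                segments.append(Segment(left.orf_end, right.orf_start, "unknown"))
            elif gap > 0:
                mid = left.orf_end + gap // 2
                left.orf_end = mid
                right.orf_start = mid
        last = assigned[-1]
        segments.append(last)
        if last.orf_end < len(orf):
            gap = len(orf) - last.orf_end
            if gap >= min_segment:
                segments.append(Segment(last.orf_end, len(orf), "unknown"))
            else:
                last.orf_end = len(orf)

    deco = SegmentDecomposition(orf_id=orf_id, orf_length=len(orf), segments=segments)
    deco.origin_class = classify_origin(deco, self_donor_ids or set())
    return deco


def classify_origin(deco: SegmentDecomposition, self_donor_ids: set[str]) -> str:
    """Classify an ORF by the distinct sources in its tiling.

    Distinct sources are the assigned donor ids, plus one pseudo-source per
    unknown segment flanked by assigned segments (an interior unassigned
    stretch is evidence of a third fragment; an edge stretch is merely
    unaligned). >= 2 distinct sources -> chimeric; a single assigned source
    -> native (self-species donor) or foreign; nothing assigned -> unknown.
    """
    assigned = {seg.donor_id for seg in deco.segments if seg.donor_id != "unknown"}
    if not assigned:
        return "unknown"
    n_sources = len(assigned)
    for i, seg in enumerate(deco.segments):
        if seg.donor_id == "unknown" and 0 < i < len(deco.segments) - 1:
            n_sources += 1
    if n_sources >= 2:
        return "chimeric"
    return "native" if assigned <= self_donor_ids else "foreign"
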