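"""Small shared I/O helpers: FASTA round-trips and GFF3 writing.

FASTA goes through Biopython; GFF3 is emitted as plain nine-column lines
(1-based inclusive coordinates, the GFF3 convention). All in-memory
coordinates in this package are 0-based half-open; conversion happens only
here, at serialization time.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class Genome:
    """A named nucleotide sequence, optionally circular."""

    id: str
    seq: str
    circular: bool = False

    def __len__(self) -> int:
        return len(self.seq)


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def write_fasta(path: str | os.PathLike, genomes: list[Genome]) -> None:
    records = [
        SeqRecord(Seq(g.seq), id=g.id, description="circular" if g.circular else "")
        for g in genomes
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | os.PathLike) -> list[Genome]:
    genomes = []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        genomes.append(
            Genome(rec.id, str(rec.seq).upper(), circular="circular" in rec.description)
        )
    return genomes


@dataclass
class Gff3Feature:
    """One GFF3 row; start/end are 0-based half-open and converted on write."""

    seqid: str
    source: str
    type: str
    start: int
    end: int
    score: float | None = None
    strand: str = "."
    phase: str = "."
    attributes: dict = field(default_factory=dict)

    def to_line(self) -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes.items()) or "."
        score = "." if self.score is None else f"{self.score:.4g}"
        return "\t".join(
            [
                self.seqid,
                self.source,
                self.type,
                str(self.start + 1),
                str(self.end),
                score,
                self.strand,
                self.phase,
                attrs,
            ]
        )


def write_gff3(path: str | os.PathLike, features: list[Gff3Feature]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            fh.write(feat.to_line() + "\n")


def read_gff3(path: str | os.PathLike) -> list[Gff3Feature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            seqid, source, ftype, start, end, score, strand, phase, attrs = line.split("\t")
            attributes = {}
            if attrs != ".":
                for item in attrs.split(";"):
                    k, _, v = item.partition("=")
                    attributes[k] = v
            feats.append(
                Gff3Feature(
                    seqid,
                    source,
                    ftype,
                    int(start) - 1,
                    int(end),
                    None if score == "." else float(score),
                    strand,
                    phase,
                    attributes,
                )
            )
    return feats


def merge_intervals(intervals: list[tuple[int, int]], gap: int = 0) -> list[tuple[int, int]]:
    """Union of half-open intervals, merging any separated by < gap."""
    if not intervals:
        return []
    merged = []
    for start, end in sorted(intervals):
        if merged and start - merged[-1][1] < gap:
            merged[-1][1] = max(merged[-1][1], end)
        elif merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged if e > s]


def complement_intervals(
    intervals: list[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    """Complement of a merged interval set within [0, length)."""
    out = []
    cursor = 0
    for start, end in merge_intervals(intervals):
        if start > cursor:
            out.append((cursor, start))
        cursor = max(cursor, end)
    if cursor < length:
        out.append((cursor, length))
    return out


def intersect_intervals(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    a = merge_intervals(a)
    b = merge_intervals(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        start = max(a[i][0], b[j][0])
        end = min(a[i][1], b[j][1])
        if end > start:
            out.append((start, end))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out
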