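"""C-to-U RNA editing quantification and 5' RLM-RACE cleavage-site calling.

Editing is read out of sequenced cDNA clones: each clone is globally aligned
to the reference ORF (edlib), per-position base counts are accumulated, and
sites where the reference C shows a sufficient T fraction are called as
editing sites with a Wilson 95% confidence interval and the codon-level
amino-acid consequence under the standard genetic code.

Cleavage is read out of RLM-RACE clones: the 5' adapter ligates only to
uncapped (processed) transcript ends, so the 5'-most aligned position of
each clone marks a putative cut. A dominant modal start position p is
interpreted as a cut between nucleotides p-1 and p; absence of a dominant
position (e.g. no restorer present, hence no cleavage product) yields
detected=False.

Transcript coordinates are 1-based from the A of the ATG.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np
from Bio.Seq import Seq
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

DEFAULT_MIN_RATE = 0.05
DEFAULT_MIN_DEPTH = 20
DEFAULT_MIN_SUPPORT_FRACTION = 0.5
DEFAULT_MIN_ENDS = 10
MIN_CLONE_IDENTITY = 0.90

BASE_ORDER = ("A", "C", "G", "T", "other")


@dataclass
class EditingSite:
    position: int  # 1-based nt from ATG
    ref_base: str
    edited_count: int
    depth: int
    rate: float
    ci_low: float
    ci_high: float
    codon_index: int
    codon_position: int
    aa_ref: str
    aa_edited: str


@dataclass
class CleavageCall:
    detected: bool
    cut_after: int | None = None  # upstream nucleotide, 1-based
    cut_before: int | None = None  # downstream nucleotide = cut_after + 1
    support_count: int = 0
    total_ends: int = 0

    @property
    def support_fraction(self) -> float:
        return self.support_count / self.total_ends if self.total_ends else 0.0


def _cigar_walk(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def align_clones(
    clones: list[tuple[str, str]], reference_orf: str
) -> dict[int, Counter]:
    """Globally align each clone to the reference ORF and accumulate
    per-reference-position base counts.

    Returns a dict mapping 0-based reference position to a Counter over
    A/C/G/T/other (deletions count as "other"; insertions have no reference
    position and are skipped). Clones below 90% alignment identity are
    discarded and logged.
    """
    if not clones:
        raise ValueError("empty clone set")
    reference_orf = reference_orf.upper()
    matrix: dict[int, Counter] = {i: Counter() for i in range(len(reference_orf))}
    n_discarded = 0
    for name, seq in clones:
        seq = seq.upper()
        aln = edlib.align(seq, reference_orf, mode="NW", task="path")
        columns = sum(n for n, _ in _cigar_walk(aln["cigar"]))
        identity = 1.0 - aln["editDistance"] / columns
        if identity < MIN_CLONE_IDENTITY:
            n_discarded += 1
            logger.warning("discarding clone %s at identity %.3f", name, identity)
            continue
        ref_pos = 0
        query_pos = 0
        for n, op in _cigar_walk(aln["cigar"]):
            if op in ("=", "X"):
                for i in range(n):
                    base = seq[query_pos + i]
                    matrix[ref_pos + i][base if base in "ACGT" else "other"] += 1
                ref_pos += n
                query_pos += n
            elif op == "D":  # reference base absent from the clone
                for i in range(n):
                    matrix[ref_pos + i]["other"] += 1
                ref_pos += n
            elif op == "I":  # clone base with no reference position
                query_pos += n
    if n_discarded:
        warnings.warn(f"discarded {n_discarded} clone(s) below {MIN_CLONE_IDENTITY:.0%} identity")
    return matrix


def _codon_effect(reference_orf: str, position: int) -> tuple[int, int, str, str]:
    codon_index = (position + 2) // 3  # ceil(position / 3)
    codon_position = position - 3 * (codon_index - 1)
    codon_start = 3 * (codon_index - 1)
    codon = reference_orf[codon_start : codon_start + 3]
    edited = codon[: codon_position - 1] + "T" + codon[codon_position:]
    aa_ref = str(Seq(codon).translate())
    aa_edited = str(Seq(edited).translate())
    return codon_index, codon_position, aa_ref, aa_edited


def call_editing_sites(
    matrix: dict[int, Counter],
    reference_orf: str,
    min_rate: float = DEFAULT_MIN_RATE,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[EditingSite]:
    """Call C-to-U editing sites from a per-position base-count matrix.

    A site is called where the reference base is C, informative depth
    (C + T) >= min_depth, and the T fraction among informative clones
    >= min_rate. The rate is T/(C+T) with a Wilson 95% CI.
    """
    reference_orf = reference_orf.upper()
    sites = []
    for pos0 in sorted(matrix):
        if reference_orf[pos0] != "C":
            continue
        counts = matrix[pos0]
        depth = counts["C"] + counts["T"]
        if depth < min_depth:
            continue
        rate = counts["T"] / depth
        if rate < min_rate:
            continue
        ci_low, ci_high = proportion_confint(counts["T"], depth, alpha=0.05, method="wilson")
        position = pos0 + 1
        codon_index, codon_position, aa_ref, aa_edited = _codon_effect(reference_orf, position)
        sites.append(
            EditingSite(
                position=position,
                ref_base="C",
                edited_count=counts["T"],
                depth=depth,
                rate=rate,
                ci_low=float(ci_low),
                ci_high=float(ci_high),
                codon_index=codon_index,
                codon_position=codon_position,
                aa_ref=aa_ref,
                aa_edited=aa_edited,
            )
        )
    return sites


def map_race_starts(race_ends: list[tuple[str, str]], transcript: str) -> list[int]:
    """Map each RACE clone to its 1-based 5' start position on the
    transcript (best infix alignment of the clone's 5' portion)."""
    transcript = transcript.upper()
    starts = []
    for _name, seq in race_ends:
        seq = seq.upper()
        probe = seq[: min(len(seq), 40)]  # the 5' end defines the start
        aln = edlib.align(probe, transcript, mode="HW", task="locations")
        loc = aln["locations"][0]
        starts.append(loc[0] + 1)
    return starts


def call_cleavage(
    race_ends: list[tuple[str, str]],
    transcript: str,
    min_support_fraction: float = DEFAULT_MIN_SUPPORT_FRACTION,
    min_ends: int = DEFAULT_MIN_ENDS,
) -> CleavageCall:
    """Call a cleavage site from the histogram of RACE 5'-start positions.

    The modal start p is accepted when its support fraction and count clear
    the thresholds, giving a cut between nucleotides p-1 and p. A tie at the
    mode is ambiguous and reported as not detected.
    """
    starts = map_race_starts(race_ends, transcript)
    total = len(starts)
    if total == 0:
        return CleavageCall(detected=False, total_ends=0)
    hist = Counter(starts)
    (mode, count), *rest = hist.most_common()
    if rest and rest[0][1] == count:
        warnings.warn("ambiguous cleavage call: tied modal 5' positions")
        return CleavageCall(detected=False, total_ends=total)
    if count < min_ends or count / total < min_support_fraction or mode < 2:
        return CleavageCall(detected=False, support_count=count, total_ends=total)
    return CleavageCall(
        detected=True,
        cut_after=mode - 1,
        cut_before=mode,
        support_count=count,
        total_ends=total,
    )
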