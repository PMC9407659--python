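"""Segregation tests, bulked-segregant scans, and recombinant fine-mapping.

A single dominant restorer locus (sporophytic restoration) predicts 1:1
segregation in a testcross and 3:1 after selfing; observed counts are tested
by Pearson chi-square goodness of fit (df 1, no continuity correction — all
counts of interest are large). The bulked-segregant scan slides windows of
SNPs over pooled allele-frequency differences between phenotypic extremes
and reports the longest super-threshold run as the candidate region.
Fine-mapping intersects, over all recombinants, the marker segments where a
locus placement is consistent with each plant's marker genotypes and its
progeny-tested locus genotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05
DEFAULT_BSA_WINDOW = 10  # SNPs per window
DEFAULT_BSA_THRESHOLD = 0.3  # allele-frequency difference


@dataclass
class SegregationResult:
    observed: tuple[int, int]
    expected_ratio: tuple[int, int]
    chi2: float
    df: int
    p_value: float
    alpha: float

    @property
    def consistent(self) -> bool:
        return self.p_value > self.alpha


def segregation_test(
    n_a: int, n_b: int, ratio: tuple[int, int] = (1, 1), alpha: float = DEFAULT_ALPHA
) -> SegregationResult:
    """Pearson chi-square goodness-of-fit of observed (n_a, n_b) counts
    against an expected a:b ratio."""
    total = n_a + n_b
    if total <= 0:
        raise ValueError("need at least one observation")
    a, b = ratio
    expected = [total * a / (a + b), total * b / (a + b)]
    if min(expected) <= 0:
        raise ValueError("expected count of zero under the given ratio")
    chi2, p = stats.chisquare([n_a, n_b], f_exp=expected)
    return SegregationResult(
        observed=(n_a, n_b),
        expected_ratio=ratio,
        chi2=float(chi2),
        df=1,
        p_value=float(p),
        alpha=alpha,
    )


@dataclass
class BsaScan:
    windows: pd.DataFrame  # chrom, start, end, n_snps, freq_diff
    candidate_region: tuple[str, int, int] | None


def bsa_scan(
    snp_table: pd.DataFrame,
    window_size: int = DEFAULT_BSA_WINDOW,
    threshold: float = DEFAULT_BSA_THRESHOLD,
) -> BsaScan:
    """Window-mean |freq_pool1 - freq_pool2| scan.

    ``snp_table`` columns: chrom, pos, freq_pool1, freq_pool2. Windows are
    consecutive non-overlapping runs of ``window_size`` SNPs per chromosome.
    The candidate region is the longest contiguous run (in bp) of windows
    whose mean absolute difference exceeds ``threshold``.
    """
    required = {"chrom", "pos", "freq_pool1", "freq_pool2"}
    if missing := required - set(snp_table.columns):
        raise ValueError(f"snp_table missing columns: {sorted(missing)}")
    rows = []
    for chrom, sub in snp_table.sort_values(["chrom", "pos"]).groupby("chrom", sort=False):
        diffs = (sub["freq_pool1"] - sub["freq_pool2"]).abs().to_numpy()
        pos = sub["pos"].to_numpy()
        for i in range(0, len(sub) - window_size + 1, window_size):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[i]),
                    "end": int(pos[i + window_size - 1]) + 1,
                    "n_snps": window_size,
                    "freq_diff": float(diffs[i : i + window_size].mean()),
                }
            )
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "freq_diff"])

    best: tuple[str, int, int] | None = None
    best_span = 0
    for chrom, sub in windows.groupby("chrom", sort=False):
        above = sub["freq_diff"].to_numpy() > threshold
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        i = 0
        while i < len(above):
            if above[i]:
                j = i
                while j + 1 < len(above) and above[j + 1]:
                    j += 1
                span = int(ends[j] - starts[i])
                if span > best_span:
                    best_span = span
                    best = (str(chrom), int(starts[i]), int(ends[j]))
                i = j + 1
            else:
                i += 1
    if best is None:
        warnings.warn("no window exceeds the BSA threshold; empty candidate region")
    return BsaScan(windows=windows, candidate_region=best)


@dataclass
class MappingInterval:
    left_marker: str
    right_marker: str
    start: int
    end: int
    n_recombinants_used: int
    chrom: str = "."


def _consistent_segments(genotypes: list[str], locus_genotype: str) -> np.ndarray:
    """Boolean consistency of placing the locus in each inter-marker segment.

    A placement between markers i and i+1 is consistent when the locus
    genotype could equal the genotype of either flanking marker (the
    crossover may fall on either side of the locus within the segment).
    """
    n_seg = len(genotypes) - 1
    out = np.zeros(n_seg, dtype=bool)
    for i in range(n_seg):
        out[i] = locus_genotype in (genotypes[i], genotypes[i + 1])
    return out


def delimit_interval(
    recombinant_table: pd.DataFrame,
    marker_positions: dict[str, int],
    phenotype_model: str = "testcross_dominant",
) -> MappingInterval:
    """Delimit the locus to the marker interval consistent with every
    recombinant's marker genotypes and inferred locus genotype.

    ``recombinant_table`` columns: plant_id, one column per marker (calls
    A/H/B in map order given by ``marker_positions``), phenotype
    (fertile/sterile). Under ``testcross_dominant`` a fertile plant carries
    the restorer (locus genotype H), a sterile one does not (A).
    """
    markers = sorted(marker_positions, key=marker_positions.get)
    if len(markers) < 2:
        raise ValueError("need at least two markers")
    n_seg = len(markers) - 1
    consistent = np.ones(n_seg, dtype=bool)
    n_recomb = 0
    offenders = []
    for _, row in recombinant_table.iterrows():
        genotypes = [str(row[m]) for m in markers]
        if phenotype_model == "testcross_dominant":
            locus_genotype = "H" if str(row["phenotype"]) == "fertile" else "A"
        else:
            raise ValueError(f"unknown phenotype_model {phenotype_model!r}")
        if len(set(genotypes)) > 1:
            n_recomb += 1
        seg = _consistent_segments(genotypes, locus_genotype)
        if not seg.any():
            offenders.append(str(row["plant_id"]))
            continue
        consistent &= seg
    if offenders or not consistent.any():
        raise ValueError(
            "contradictory recombinants: no locus placement fits "
            + (", ".join(offenders) if offenders else "the full panel")
        )
    left = int(np.argmax(consistent))
    right = n_seg - 1 - int(np.argmax(consistent[::-1]))
    return MappingInterval(
        left_marker=markers[left],
        right_marker=markers[right + 1],
        start=marker_positions[markers[left]],
        end=marker_positions[markers[right + 1]],
        n_recombinants_used=n_recomb,
    )
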