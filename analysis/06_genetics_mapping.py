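#!/usr/bin/env python
"""Segregation tests, a bulked-segregant scan, and recombinant fine-mapping.

Tests the fixture testcross against 1:1 and the selfed F2 against 3:1 (plus
the study's printed transgenic counts 172:56 and 139:45 against 3:1),
scans a synthetic pooled-SNP table for the restorer region, and delimits
the locus from the recombinant panel. Writes results/genetics.json."""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cmsforge import simulate
from cmsforge.genetics import bsa_scan, delimit_interval, segregation_test

ROOT = Path(__file__).resolve().parents[1]
FIXTURE = ROOT / "scratch" / "fixture"
RESULTS = ROOT / "results"


def _seg(n_a, n_b, ratio):
    res = segregation_test(n_a, n_b, ratio)
    verdict = "consistent" if res.consistent else "inconsistent"
    print(f"  {n_a}:{n_b} vs {ratio[0]}:{ratio[1]} -> chi2={res.chi2:.4f}, "
          f"p={res.p_value:.4f} ({verdict})")
    return {"observed": [n_a, n_b], "ratio": list(ratio), "chi2": round(res.chi2, 4),
            "p_value": round(res.p_value, 4), "consistent": res.consistent}


def main() -> None:
    out = {}
    print("segregation:")
    testcross = pd.read_csv(FIXTURE / "testcross.tsv", sep="\t")
    fertile = int((testcross["phenotype"] == "fertile").sum())
    out["testcross_1to1"] = _seg(fertile, len(testcross) - fertile, (1, 1))
    selfed = pd.read_csv(FIXTURE / "self_f2.tsv", sep="\t")
    fertile = int((selfed["phenotype"] == "fertile").sum())
    out["self_3to1"] = _seg(fertile, len(selfed) - fertile, (3, 1))
    out["transgenic_T1_families"] = [_seg(172, 56, (3, 1)), _seg(139, 45, (3, 1))]

    # pooled-SNP scan over a synthetic chromosome 10 with a diverged block
    rng = np.random.default_rng(0)
    pos = np.arange(1, 2301) * 10_000  # 23 Mb, one SNP per 10 kb
    diff = np.where((pos >= 17_160_000) & (pos <= 19_900_000), 0.8, 0.0)
    noise = rng.normal(0, 0.03, size=pos.size)
    snps = pd.DataFrame({
        "chrom": "chr10", "pos": pos,
        "freq_pool1": 0.5 + (diff + noise) / 2, "freq_pool2": 0.5 - (diff + noise) / 2,
    })
    scan = bsa_scan(snps)
    chrom, start, end = scan.candidate_region
    out["bsa_candidate"] = {"chrom": chrom, "start": int(start), "end": int(end)}
    print(f"BSA candidate region: {chrom}:{start / 1e6:.2f}-{end / 1e6:.2f} Mb")

    panel = pd.read_csv(FIXTURE / "recombinant_panel.tsv", sep="\t")
    markers = {f"m{i+1}": p for i, p in enumerate(simulate.CrossSimParams().marker_positions)}
    iv = delimit_interval(panel, markers)
    out["mapping_interval"] = {
        "left_marker": iv.left_marker, "right_marker": iv.right_marker,
        "start": iv.start, "end": iv.end, "n_recombinants": iv.n_recombinants_used,
    }
    print(f"locus delimited to {iv.left_marker}({iv.start:,})..{iv.right_marker}({iv.end:,}) "
          f"using {iv.n_recombinants_used} recombinants "
          f"(planted locus at {simulate.CrossSimParams().locus_position:,})")

    (RESULTS / "genetics.json").write_text(json.dumps(out, indent=1) + "\n")


if __name__ == "__main__":
    main()
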