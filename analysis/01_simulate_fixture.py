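#!/usr/bin/env python
"""Generate the default synthetic study fixture with planted ground truth.

Writes the full input set — the 457,380 bp CMS mitogenome with its planted
549 bp chimeric ORF, the reference and donor panels, 500 cDNA clones, 200
RACE ends, the Ct table, and three cross tables — under scratch/fixture/
(large FASTA files), and copies the small manifest to results/.
"""

import json
import shutil
from pathlib import Path

from cmsforge import simulate

ROOT = Path(__file__).resolve().parents[1]
FIXTURE = ROOT / "scratch" / "fixture"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    manifest = simulate.write_fixture(FIXTURE)
    shutil.copy(FIXTURE / "manifest.json", RESULTS / "fixture_manifest.json")
    truth = manifest["truth"]
    print(f"fixture written to {FIXTURE}")
    print(f"planted insert: {truth['insert_start']:,}-{truth['insert_end']:,} "
          f"({truth['insert_end'] - truth['insert_start']} bp)")
    print("planted segments:",
          [(s['donor_id'], s['orf_end'] - s['orf_start']) for s in truth['segments']])
    print("realized edited clone counts:", truth["edited_counts"])
    print(f"RACE ends at the cut: {truth['race_n_at_cut']}/200")


if __name__ == "__main__":
    main()
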