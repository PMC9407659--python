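"""Field-trial table parsing and per-system summarization.

Trial tables report agronomic traits of paired testcross F1 hybrids — the
same restorer background crossed into a WA-cytoplasm line and into an
FA-cytoplasm line — as "mean ± sd" cells. Paired rows share a base cross id
(1.1 / 1.2 etc.); summarization reports per-system ranges and means of the
trait means plus paired WA - FA differences.
"""

from __future__ import annotations

import logging
import re
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

TRAITS = [
    "days_to_heading",
    "plant_height",
    "tillers",
    "grains_per_panicle",
    "spikelet_fertility",
    "thousand_grain_weight",
    "yield_per_plant",
]

_MEAN_SD = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(?:±|\+-)\s*(\d+(?:\.\d+)?)\s*$")


def parse_mean_sd(cell: str) -> tuple[float, float]:
    """Parse a "mean ± sd" cell (ASCII "+-" accepted; decimal point only)."""
    m = _MEAN_SD.match(str(cell))
    if not m:
        raise ValueError(f"malformed mean ± sd cell: {cell!r}")
    return float(m.group(1)), float(m.group(2))


def load_trial_table(path=None) -> pd.DataFrame:
    """Load a trial TSV (hybrid_id, system, then one ``mean ± sd`` column per
    trait). Without a path, the packaged table ships with the module."""
    if path is None:
        with resources.as_file(
            resources.files("cmsforge").joinpath("data/table1.tsv")
        ) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["hybrid_id", "system"] + TRAITS
    if list(df.columns) != expected:
        raise ValueError(f"trial table columns must be {expected}")
    return df


def summarize_trial(table: pd.DataFrame, group_by: str = "system") -> dict:
    """Summarize a trial table.

    Returns ``{"groups": {group: {trait: {min, max, mean}}}, "paired":
    {trait: {base_id: wa_minus_fa}}}``. Ranges and means are computed on the
    cell means; malformed cells raise with their row number; hybrids without
    a partner are excluded from the paired differences and logged.
    """
    means = pd.DataFrame(index=table.index, columns=TRAITS, dtype=float)
    for trait in TRAITS:
        for idx, cell in table[trait].items():
            try:
                means.loc[idx, trait] = parse_mean_sd(cell)[0]
            except ValueError as err:
                raise ValueError(f"row {idx + 1}: {err}") from err

    groups: dict = {}
    for group, sub in table.groupby(group_by, sort=False):
        if len(sub) < 1:
            continue
        groups[group] = {
            trait: {
                "min": float(means.loc[sub.index, trait].min()),
                "max": float(means.loc[sub.index, trait].max()),
                "mean": float(means.loc[sub.index, trait].mean()),
            }
            for trait in TRAITS
        }

    paired: dict = {trait: {} for trait in TRAITS}
    base = table["hybrid_id"].str.split(".").str[0]
    for base_id, sub in table.groupby(base, sort=False):
        systems = set(sub["system"])
        if systems != {"WA", "FA"} or len(sub) != 2:
            logger.warning("hybrid base %s is unpaired; excluded from paired stats", base_id)
            continue
        wa_idx = sub.index[sub["system"] == "WA"][0]
        fa_idx = sub.index[sub["system"] == "FA"][0]
        for trait in TRAITS:
            paired[trait][str(base_id)] = float(
                means.loc[wa_idx, trait] - means.loc[fa_idx, trait]
            )
    return {"groups": groups, "paired": paired}
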