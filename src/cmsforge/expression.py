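"""Relative transcript quantification by the 2^(-ddCt) method.

Per tissue and group, replicate Ct values of the target and the reference
gene are averaged; dCt = Ct_target - Ct_reference; ddCt = dCt_sample -
dCt_calibrator; fold = 2^(-ddCt) gives the target abundance in the sample
group relative to the calibrator group, assuming ideal amplification
efficiency (exactly 2 per cycle). Replicate SDs are propagated to a standard
error on the fold via the log2 scale.

For a transcript destabilized in the calibrator (e.g. a restorer line
cleaving a CMS transcript), fold >= 1 and 1 - 1/fold is the fraction of the
transcript degraded in the calibrator relative to the sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FoldChange:
    tissue: str
    target_gene: str
    fold: float
    dct_sample: float
    dct_calibrator: float
    se: float  # standard error on the fold scale

    @property
    def ddct(self) -> float:
        return self.dct_sample - self.dct_calibrator

    @property
    def degraded_fraction(self) -> float:
        return degraded_fraction(self.fold)


def delta_delta_ct(
    ct_table: pd.DataFrame,
    target: str,
    reference_gene: str,
    sample_group: str,
    calibrator_group: str,
) -> list[FoldChange]:
    """Compute per-tissue 2^(-ddCt) folds of ``target`` in ``sample_group``
    relative to ``calibrator_group``.

    ``ct_table`` is long-format with columns sample, tissue, gene,
    replicate, ct. Tissues missing the reference gene (or either group) are
    skipped with a warning.
    """
    required = {"sample", "tissue", "gene", "replicate", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"ct_table missing columns: {sorted(missing)}")

    results = []
    for tissue, sub in ct_table.groupby("tissue", sort=False):
        stats = {}
        ok = True
        for group in (sample_group, calibrator_group):
            for gene in (target, reference_gene):
                vals = sub.loc[(sub["sample"] == group) & (sub["gene"] == gene), "ct"]
                if len(vals) < 2:
                    warnings.warn(
                        f"tissue {tissue!r}: missing {gene!r} Ct values for group "
                        f"{group!r}; tissue skipped"
                    )
                    ok = False
                else:
                    stats[(group, gene)] = (vals.mean(), vals.std(ddof=1), len(vals))
        if not ok:
            continue
        dct = {}
        var = {}
        for group in (sample_group, calibrator_group):
            mt, st, nt = stats[(group, target)]
            mr, sr, nr = stats[(group, reference_gene)]
            dct[group] = mt - mr
            var[group] = st**2 / nt + sr**2 / nr
        ddct = dct[sample_group] - dct[calibrator_group]
        fold = float(2.0 ** (-ddct))
        se_ddct = float(np.sqrt(var[sample_group] + var[calibrator_group]))
        se_fold = fold * np.log(2.0) * se_ddct
        results.append(
            FoldChange(
                tissue=tissue,
                target_gene=target,
                fold=fold,
                dct_sample=float(dct[sample_group]),
                dct_calibrator=float(dct[calibrator_group]),
                se=float(se_fold),
            )
        )
    return results


def degraded_fraction(fold: float) -> float:
    """Fraction of the transcript degraded in the calibrator: 1 - 1/fold,
    clamped at 0 for fold < 1."""
    if fold <= 0:
        raise ValueError("fold must be positive")
    return max(0.0, 1.0 - 1.0 / fold)
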