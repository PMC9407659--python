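"""End-to-end pipeline: generate or load the fixture, run every stage in
dependency order, and write a machine-readable summary.

Stage order: mitogenome comparison -> ORF calling and chimera decomposition
(dependent); editing/cleavage assays, ddCt expression, mapping genetics and
PPR duplication ordering are independent and run afterward. The summary
lists the candidate CMS ORFs with their decomposition, the editing sites,
the cleavage call, per-tissue folds, segregation tests, the mapping
interval, and the PPR event order. Identical config and seeds give a
byte-identical summary.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import expression, genetics, mitocompare, orfs, ppr, simulate, transcripts
from ._io import read_fasta


@dataclass
class PipelineConfig:
    """Resolved stage parameters; defaults are the package defaults."""

    seed: int = 0
    fixture_dir: str | None = None  # None: generate under the run directory
    mito: simulate.MitoSimParams = field(default_factory=simulate.MitoSimParams)
    transcript: simulate.TranscriptSimParams = field(default_factory=simulate.TranscriptSimParams)
    ct: simulate.CtSimParams = field(default_factory=simulate.CtSimParams)
    k: int = mitocompare.DEFAULT_K
    min_region_length: int = mitocompare.DEFAULT_MIN_REGION_LENGTH
    merge_gap: int = mitocompare.DEFAULT_MERGE_GAP
    min_aa: int = orfs.DEFAULT_MIN_AA
    seed_len: int = orfs.DEFAULT_SEED_LEN
    min_identity: float = orfs.DEFAULT_MIN_IDENTITY
    min_segment: int = orfs.DEFAULT_MIN_SEGMENT
    self_donor_ids: list[str] = field(default_factory=lambda: ["donorB"])
    min_rate: float = transcripts.DEFAULT_MIN_RATE
    min_depth: int = transcripts.DEFAULT_MIN_DEPTH
    min_support_fraction: float = transcripts.DEFAULT_MIN_SUPPORT_FRACTION
    min_ends: int = transcripts.DEFAULT_MIN_ENDS
    target_gene: str = "FA182-1"
    reference_gene: str = "Ubiquitin"
    sample_group: str = "sterile"
    calibrator_group: str = "restorer"
    alpha: float = genetics.DEFAULT_ALPHA

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        nested = {
            "mito": simulate.MitoSimParams,
            "transcript": simulate.TranscriptSimParams,
            "ct": simulate.CtSimParams,
        }
        kwargs = {}
        for key, value in raw.items():
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
            if key in nested and isinstance(value, dict):
                sub_known = {f.name for f in dataclasses.fields(nested[key])}
                if unknown := set(value) - sub_known:
                    raise ValueError(f"unknown config keys under {key!r}: {sorted(unknown)}")
                value = nested[key](**{
                    k: ([tuple(x) for x in v] if k in ("chimera_spec", "edit_sites") else v)
                    for k, v in value.items()
                })
            kwargs[key] = value
        cfg = cls(**kwargs)
        # keep per-stage seeds in lockstep with the run seed unless set
        if "mito" not in raw:
            cfg.mito = dataclasses.replace(cfg.mito, seed=cfg.seed)
        if "transcript" not in raw:
            cfg.transcript = dataclasses.replace(cfg.transcript, seed=cfg.seed)
        if "ct" not in raw:
            cfg.ct = dataclasses.replace(cfg.ct, seed=cfg.seed)
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig, run_dir: str) -> dict:
    """Run every stage and write ``summary.json`` (plus the fixture, if
    generated) under ``run_dir``. Returns the summary dict."""
    os.makedirs(run_dir, exist_ok=True)
    summary: dict = {"config_seed": config.seed}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as err:  # noqa: BLE001 - abort with stage name
                raise StageError(name, err) from err

        return wrap

    # --- fixture
    def _fixture():
        fixture_dir = config.fixture_dir or os.path.join(run_dir, "fixture")
        if not os.path.exists(os.path.join(fixture_dir, "manifest.json")):
            simulate.write_fixture(
                fixture_dir,
                mito_params=config.mito,
                transcript_params=config.transcript,
                ct_params=config.ct,
            )
        return fixture_dir

    fixture_dir = stage("fixture")(_fixture)

    # --- mitogenome comparison
    def _regions():
        cms = read_fasta(os.path.join(fixture_dir, "cms_genome.fasta"))[0]
        refs = read_fasta(os.path.join(fixture_dir, "reference_panel.fasta"))
        regions = mitocompare.specific_regions(
            cms,
            refs,
            k=config.k,
            min_region_length=config.min_region_length,
            merge_gap=config.merge_gap,
        )
        return cms, regions

    cms, regions = stage("mitocompare")(_regions)
    summary["specific_regions"] = [
        {"start": r.start, "end": r.end, "length": r.length} for r in regions
    ]

    # --- ORF calling + decomposition
    def _candidates():
        donors = read_fasta(os.path.join(fixture_dir, "donor_panel.fasta"))
        out = []
        for ri, region in enumerate(regions):
            seq = cms.seq[region.start : region.end]
            for oi, orf in enumerate(orfs.call_orfs(seq, min_aa=config.min_aa)):
                deco = orfs.decompose_orf(
                    orf.sequence,
                    donors,
                    orf_id=f"region{ri + 1}_orf{oi + 1}",
                    seed_len=config.seed_len,
                    min_identity=config.min_identity,
                    min_segment=config.min_segment,
                    self_donor_ids=set(config.self_donor_ids),
                )
                out.append(
                    {
                        "orf_id": deco.orf_id,
                        "region": [region.start, region.end],
                        "start": region.start + orf.start,
                        "end": region.start + orf.end,
                        "strand": orf.strand,
                        "aa_length": orf.aa_length,
                        "origin_class": deco.origin_class,
                        "segments": [
                            {
                                "orf_start": s.orf_start,
                                "orf_end": s.orf_end,
                                "length": s.length,
                                "donor": s.donor_id,
                                "identity": s.identity,
                            }
                            for s in deco.segments
                        ],
                    }
                )
        return out

    all_orfs = stage("orf_chimera")(_candidates)
    summary["orfs"] = all_orfs
    summary["chimeric_candidates"] = [o for o in all_orfs if o["origin_class"] == "chimeric"]

    # --- transcript assays
    def _assays():
        orf_seq = read_fasta(os.path.join(fixture_dir, "orf.fasta"))[0].seq
        clones = [(g.id, g.seq) for g in read_fasta(os.path.join(fixture_dir, "cdna_clones.fasta"))]
        matrix = transcripts.align_clones(clones, orf_seq)
        sites = transcripts.call_editing_sites(
            matrix, orf_seq, min_rate=config.min_rate, min_depth=config.min_depth
        )
        race = [(g.id, g.seq) for g in read_fasta(os.path.join(fixture_dir, "race_ends.fasta"))]
        cleavage = transcripts.call_cleavage(
            race,
            orf_seq,
            min_support_fraction=config.min_support_fraction,
            min_ends=config.min_ends,
        )
        return sites, cleavage

    sites, cleavage = stage("transcript_assays")(_assays)
    summary["editing_sites"] = [
        {
            "position": s.position,
            "rate": s.rate,
            "ci": [s.ci_low, s.ci_high],
            "depth": s.depth,
            "codon_index": s.codon_index,
            "codon_position": s.codon_position,
            "aa_change": f"{s.aa_ref}->{s.aa_edited}",
        }
        for s in sites
    ]
    summary["cleavage"] = {
        "detected": cleavage.detected,
        "cut_after": cleavage.cut_after,
        "cut_before": cleavage.cut_before,
        "support_fraction": cleavage.support_fraction,
    }

    # --- expression
    def _folds():
        table = pd.read_csv(os.path.join(fixture_dir, "ct_table.tsv"), sep="\t")
        return expression.delta_delta_ct(
            table,
            target=config.target_gene,
            reference_gene=config.reference_gene,
            sample_group=config.sample_group,
            calibrator_group=config.calibrator_group,
        )

    folds = stage("expression")(_folds)
    summary["fold_changes"] = {
        fc.tissue: {"fold": fc.fold, "degraded_fraction": fc.degraded_fraction}
        for fc in folds
    }

    # --- genetics
    def _genetics():
        out = {}
        testcross = pd.read_csv(os.path.join(fixture_dir, "testcross.tsv"), sep="\t")
        counts = testcross["phenotype"].value_counts()
        res = genetics.segregation_test(
            int(counts.get("fertile", 0)), int(counts.get("sterile", 0)), (1, 1), config.alpha
        )
        out["testcross_1to1"] = {
            "observed": list(res.observed), "chi2": res.chi2,
            "p_value": res.p_value, "consistent": res.consistent,
        }
        selfed = pd.read_csv(os.path.join(fixture_dir, "self_f2.tsv"), sep="\t")
        counts = selfed["phenotype"].value_counts()
        res = genetics.segregation_test(
            int(counts.get("fertile", 0)), int(counts.get("sterile", 0)), (3, 1), config.alpha
        )
        out["self_3to1"] = {
            "observed": list(res.observed), "chi2": res.chi2,
            "p_value": res.p_value, "consistent": res.consistent,
        }
        panel = pd.read_csv(os.path.join(fixture_dir, "recombinant_panel.tsv"), sep="\t")
        cross_params = simulate.CrossSimParams(design="recombinant_panel")
        marker_positions = {
            f"m{i + 1}": pos for i, pos in enumerate(cross_params.marker_positions)
        }
        interval = genetics.delimit_interval(panel, marker_positions)
        out["mapping_interval"] = {
            "left_marker": interval.left_marker,
            "right_marker": interval.right_marker,
            "start": interval.start,
            "end": interval.end,
            "n_recombinants_used": interval.n_recombinants_used,
        }
        return out

    summary["genetics"] = stage("genetics")(_genetics)

    # --- PPR duplication ordering
    def _ppr():
        family, events = simulate.generate_ppr_family(
            simulate.PprFamilyParams(seed=config.seed)
        )
        matrix = ppr.identity_matrix(family)
        tree = ppr.duplication_order(matrix)
        youngest_truth = tuple(sorted(events[-1]))
        youngest_called = tuple(sorted(tree.event_order[-1][1] + tree.event_order[-1][2]))
        return {
            "newick": tree.newick(),
            "event_order": [
                {"height": h, "join": [list(a), list(b)]} for h, a, b in tree.event_order
            ],
            "youngest_truth": list(youngest_truth),
            "youngest_called_pair": list(youngest_called),
        }

    summary["ppr"] = stage("ppr_evolution")(_ppr)

    summary = _round_floats(summary)
    with open(os.path.join(run_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
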