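"""Generator properties: determinism, planted-truth bookkeeping, and the
statistical behavior of the simulated assays."""

import dataclasses
import filecmp
import math
import os

import numpy as np
import pytest

from cmsforge import simulate
from cmsforge._io import read_gff3
from conftest import scaled_mito_params


class TestMitogenomes:
    def test_default_cms_genome_length_and_gc(self, default_fixture):
        cms = default_fixture.cms
        assert len(cms) == 457_380
        gc = (cms.seq.count("G") + cms.seq.count("C")) / len(cms)
        p = default_fixture.params.gc_prob
        assert abs(gc - p) < 3 * math.sqrt(p * (1 - p) / len(cms))

    def test_insert_is_backbone_plus_chimera(self, default_fixture):
        truth = default_fixture.truth
        assert truth.insert_end - truth.insert_start == 421 + 71 + 57 == 549
        assert [s["orf_end"] - s["orf_start"] for s in truth.segments] == [421, 71, 57]
        cms = default_fixture.cms.seq
        assert cms[truth.insert_start : truth.insert_end] == truth.orf_seq

    def test_empty_chimera_is_identity_case(self):
        params = scaled_mito_params()
        empty = dataclasses.replace(params, chimera_spec=[])
        cms_a, _, donors, truth = simulate.generate_mitogenomes(empty)
        assert len(cms_a) == empty.genome_length
        assert truth.segments == [] and donors == []
        assert truth.insert_end == truth.insert_start

    def test_donor_source_identity_matches_spec(self, default_fixture):
        # the 421 bp segment diverged to ~0.79 identity from its donor source
        truth = default_fixture.truth
        donors = {d.id: d for d in default_fixture.donors}
        seg = truth.segments[0]
        source = donors["donorA"].seq[seg["donor_start"] : seg["donor_end"]]
        planted = truth.orf_seq[seg["orf_start"] : seg["orf_end"]]
        matches = sum(a == b for a, b in zip(source, planted))
        assert matches / len(planted) == pytest.approx(0.79, abs=0.005)
        # boundary windows are mutation-free
        assert source[:20] == planted[:20] and source[-20:] == planted[-20:]

    def test_segment_longer_than_donor_rejected(self):
        params = dataclasses.replace(
            scaled_mito_params(), chimera_spec=[("donorA", 20_001, 0.9), ("unknown", 54, None)],
            donor_length=20_000,
        )
        with pytest.raises(ValueError, match="longer than donor"):
            simulate.generate_mitogenomes(params)

    def test_gc_convergence(self):
        rng = np.random.default_rng(7)
        seq = simulate.random_sequence(rng, 100_000, 0.4383)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.4383) < 3 * math.sqrt(0.4383 * (1 - 0.4383) / len(seq))


class TestCdnaClones:
    def test_zero_rate_gives_identical_clones(self, default_fixture):
        params = simulate.TranscriptSimParams(edit_sites=[(62, 0.0), (65, 0.0)], n_clones=20)
        clones, truth = simulate.generate_cdna_clones(params, default_fixture.truth.orf_seq)
        assert all(seq == default_fixture.truth.orf_seq for _, seq in clones)
        assert set(truth["edited_counts"].values()) == {0}

    def test_full_rate_single_clone(self, default_fixture):
        params = simulate.TranscriptSimParams(edit_sites=[(62, 1.0)], n_clones=1, seed=5)
        clones, _ = simulate.generate_cdna_clones(params, default_fixture.truth.orf_seq)
        assert clones[0][1][61] == "T"

    def test_realized_counts_are_binomial(self, default_clones):
        # realized edits ~ Binomial(500, rate); allow 4 SE
        for pos, rate in default_clones.params.edit_sites:
            count = default_clones.truth["edited_counts"][pos]
            se = math.sqrt(500 * rate * (1 - rate))
            assert abs(count - 500 * rate) < 4 * se

    def test_non_c_edit_position_rejected(self, default_fixture):
        orf = default_fixture.truth.orf_seq
        pos = orf.index("A") + 1
        params = simulate.TranscriptSimParams(edit_sites=[(pos, 0.5)])
        with pytest.raises(ValueError, match="not a C"):
            simulate.generate_cdna_clones(params, orf)


class TestRaceEnds:
    def test_no_background_all_starts_at_cut(self, default_fixture):
        params = simulate.TranscriptSimParams(background_end_fraction=0.0, n_clones=200)
        _, truth = simulate.generate_race_ends(params, default_fixture.truth.orf_seq)
        assert set(truth["starts"]) == {415}

    def test_full_background_has_no_dominant_position(self, default_fixture):
        params = simulate.TranscriptSimParams(background_end_fraction=1.0, n_clones=200, seed=2)
        _, truth = simulate.generate_race_ends(params, default_fixture.truth.orf_seq)
        counts = np.bincount(truth["starts"])
        assert counts.max() / 200 < 0.5

    def test_default_background_keeps_modal_support(self, default_race):
        # with 10% background the cut position retains ~90% support
        truth = default_race.truth
        assert truth["n_at_cut"] / 200 >= 0.85


class TestCrossAndCt:
    def test_self_3to1_expectation(self):
        table = simulate.generate_cross(
            simulate.CrossSimParams(design="self_3to1", n_plants=228, seed=0)
        )
        fertile = (table["phenotype"] == "fertile").sum()
        se = math.sqrt(228 * 0.75 * 0.25)
        assert abs(fertile - 171) < 4 * se

    def test_testcross_phenotype_tracks_genotype(self):
        table = simulate.generate_cross(simulate.CrossSimParams(seed=1))
        assert ((table["locus_genotype"] == "H") == (table["phenotype"] == "fertile")).all()

    def test_recombinant_panel_locus_inside_span_required(self):
        with pytest.raises(ValueError, match="outside marker span"):
            simulate.generate_cross(
                simulate.CrossSimParams(design="recombinant_panel", locus_position=999_999_999)
            )

    def test_noise_free_unit_folds_give_flat_ct(self):
        params = simulate.CtSimParams(
            true_folds={t: 1.0 for t in ["root", "stem", "leaf", "panicle", "anther"]},
            ct_noise_sd=0.0,
        )
        table = simulate.generate_ct_table(params)
        for gene, sub in table.groupby("gene"):
            assert sub["ct"].nunique() == 1


class TestFixtureDeterminism:
    def test_write_fixture_twice_is_byte_identical(self, tmp_path):
        params = scaled_mito_params(seed=3)
        kwargs = dict(
            mito_params=params,
            transcript_params=simulate.TranscriptSimParams(n_clones=40, seed=3),
            ct_params=simulate.CtSimParams(seed=3),
            n_race_clones=30,
        )
        m1 = simulate.write_fixture(tmp_path / "a", **kwargs)
        m2 = simulate.write_fixture(tmp_path / "b", **kwargs)
        for name in m1["files"] + ["manifest.json"]:
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False), name

    def test_truth_round_trips_through_gff3(self, tmp_path):
        params = scaled_mito_params(seed=4)
        simulate.write_fixture(
            tmp_path / "fx",
            mito_params=params,
            transcript_params=simulate.TranscriptSimParams(n_clones=5, seed=4),
            ct_params=simulate.CtSimParams(seed=4),
            n_race_clones=5,
        )
        _, _, _, truth = simulate.generate_mitogenomes(params)
        feats = read_gff3(tmp_path / "fx" / "truth.gff3")
        insert = [f for f in feats if f.type == "planted_insert"][0]
        assert (insert.start, insert.end) == (truth.insert_start, truth.insert_end)
        segs = [f for f in feats if f.type == "planted_segment"]
        assert [(f.start, f.end) for f in segs] == [
            (truth.insert_start + s["orf_start"], truth.insert_start + s["orf_end"])
            for s in truth.segments
        ]


class TestPprFamily:
    def test_events_are_sequential_and_deterministic(self):
        params = simulate.PprFamilyParams(seed=9)
        seqs1, events1 = simulate.generate_ppr_family(params)
        seqs2, events2 = simulate.generate_ppr_family(params)
        assert seqs1 == seqs2 and events1 == events2
        assert len(events1) == params.n_genes - 1
        assert all(parent in seqs1 and child in seqs1 for parent, child in events1)
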