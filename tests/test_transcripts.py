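"""Editing quantification and cleavage calling: counting oracles, estimator
calibration, and degenerate inputs."""

import math

import numpy as np
import pytest

from cmsforge import simulate
from cmsforge.transcripts import (
    align_clones,
    call_cleavage,
    call_editing_sites,
    map_race_starts,
)

REF = "ATG" + "GA" * 28 + "C" + "AG" * 5 + "TAA"  # C at position 60


def _short_ref(c_positions, length=80):
    seq = ["A"] * length
    seq[0:3] = list("ATG")
    for pos in c_positions:
        seq[pos - 1] = "C"
    return "".join(seq)


class TestAlignClones:
    def test_identical_clone_counts_reference_bases(self):
        ref = _short_ref([62, 65])
        matrix = align_clones([("c1", ref)], ref)
        for pos0, base in enumerate(ref):
            assert matrix[pos0][base] == 1 and sum(matrix[pos0].values()) == 1

    def test_single_substitution_counting_oracle(self):
        ref = _short_ref([62])
        clones = [("c" + str(i), ref) for i in range(19)]
        edited = ref[:61] + "T" + ref[62:]
        clones.append(("edited", edited))
        matrix = align_clones(clones, ref)
        assert matrix[61]["C"] == 19 and matrix[61]["T"] == 1

    def test_indel_tolerant_counting(self):
        ref = _short_ref([62])
        deleted = ref[:30] + ref[31:]  # clone lost one base
        matrix = align_clones([("c1", deleted)], ref)
        assert sum(matrix[30].values()) == 1  # ref position still accounted
        assert matrix[61]["C"] == 1  # downstream positions still line up

    def test_low_identity_clone_discarded(self):
        ref = _short_ref([62])
        junk = "T" * len(ref)
        with pytest.warns(UserWarning, match="discarded 1"):
            matrix = align_clones([("c1", ref), ("junk", junk)], ref)
        assert sum(matrix[0].values()) == 1

    def test_empty_clone_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            align_clones([], "ATGTAA")

    def test_fixture_depth_is_500_everywhere(self, default_fixture, default_clones):
        matrix = align_clones(default_clones.clones, default_fixture.truth.orf_seq)
        depths = {sum(c.values()) for c in matrix.values()}
        assert depths == {500}


class TestCallEditing:
    def test_fixture_sites_and_codon_effects(self, default_fixture, default_clones):
        orf = default_fixture.truth.orf_seq
        matrix = align_clones(default_clones.clones, orf)
        sites = call_editing_sites(matrix, orf)
        assert [s.position for s in sites] == [62, 65]
        by_pos = {s.position: s for s in sites}
        assert (by_pos[62].codon_index, by_pos[62].codon_position) == (21, 2)
        assert (by_pos[62].aa_ref, by_pos[62].aa_edited) == ("P", "L")
        assert (by_pos[65].codon_index, by_pos[65].codon_position) == (22, 2)
        assert (by_pos[65].aa_ref, by_pos[65].aa_edited) == ("S", "F")
        # rates equal the realized edited fractions exactly
        for pos in (62, 65):
            assert by_pos[pos].rate == default_clones.truth["edited_counts"][pos] / 500
            assert by_pos[pos].ci_low <= by_pos[pos].rate <= by_pos[pos].ci_high

    def test_rates_invariant_to_clone_order(self, default_fixture, default_clones):
        orf = default_fixture.truth.orf_seq
        fwd = call_editing_sites(align_clones(default_clones.clones, orf), orf)
        rev = call_editing_sites(align_clones(default_clones.clones[::-1], orf), orf)
        assert [(s.position, s.rate) for s in fwd] == [(s.position, s.rate) for s in rev]

    def test_estimator_unbiased_and_ci_calibrated(self):
        # 200 replicate simulations at n=500, true rate 0.762
        ref = _short_ref([62])
        true_rate = 0.762
        estimates, covered = [], 0
        for seed in range(200):
            params = simulate.TranscriptSimParams(
                transcript_length=len(ref),
                edit_sites=[(62, true_rate)],
                cleavage_position=40,
                seed=seed,
            )
            clones, _ = simulate.generate_cdna_clones(params, ref)
            sites = call_editing_sites(align_clones(clones, ref), ref)
            (site,) = sites
            estimates.append(site.rate)
            covered += site.ci_low <= true_rate <= site.ci_high
        assert abs(np.mean(estimates) - true_rate) < 0.01
        assert covered / 200 >= 0.90


class TestCallCleavage:
    def test_all_ends_at_cut(self, default_fixture):
        orf = default_fixture.truth.orf_seq
        ends = [(f"r{i}", orf[414:]) for i in range(50)]
        call = call_cleavage(ends, orf)
        assert call.detected and (call.cut_after, call.cut_before) == (414, 415)
        assert call.support_fraction == 1.0

    def test_uniform_background_not_detected(self, default_fixture):
        orf = default_fixture.truth.orf_seq
        params = simulate.TranscriptSimParams(background_end_fraction=1.0, n_clones=100, seed=8)
        ends, _ = simulate.generate_race_ends(params, orf)
        assert not call_cleavage(ends, orf).detected

    @pytest.mark.parametrize("seed", range(5))
    def test_background_only_never_detected_at_majority_threshold(self, default_fixture, seed):
        orf = default_fixture.truth.orf_seq
        params = simulate.TranscriptSimParams(
            background_end_fraction=1.0, n_clones=150, seed=seed
        )
        ends, _ = simulate.generate_race_ends(params, orf)
        assert not call_cleavage(ends, orf, min_support_fraction=0.5).detected

    def test_dominant_mode_with_background(self, default_fixture, default_race):
        orf = default_fixture.truth.orf_seq
        call = call_cleavage(default_race.clones, orf, min_support_fraction=0.5)
        assert call.detected and (call.cut_after, call.cut_before) == (414, 415)
        assert call.support_fraction >= 0.85

    def test_tied_mode_is_ambiguous(self, default_fixture):
        orf = default_fixture.truth.orf_seq
        ends = [("a", orf[414:]), ("b", orf[414:]), ("c", orf[99:]), ("d", orf[99:])]
        with pytest.warns(UserWarning, match="ambiguous"):
            call = call_cleavage(ends, orf, min_ends=1)
        assert not call.detected

    def test_map_race_starts_exact(self, default_fixture):
        orf = default_fixture.truth.orf_seq
        assert map_race_starts([("x", orf[414:]), ("y", orf)], orf) == [415, 1]
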