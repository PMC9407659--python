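"""Pairwise identity, UPGMA agglomeration, and duplication-order recovery."""

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from cmsforge import simulate
from cmsforge.ppr import (
    IdentityMatrix,
    duplication_order,
    global_identity,
    identity_matrix,
    nearest_relative,
    pairwise_identity,
)


class TestGlobalIdentity:
    def test_identical_pair(self):
        assert global_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_hand_alignment(self):
        assert global_identity("ACGT", "ACGA") == 0.75

    def test_disjoint_alphabets(self):
        assert global_identity("AAAA", "TTTT") == 0.0

    def test_symmetry(self):
        a, b = "ACGTTGCAACGT", "ACGTGCAACGGT"
        assert global_identity(a, b) == global_identity(b, a)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_identity("", "ACGT")


class TestIdentityMatrix:
    def test_matrix_is_symmetric_unit_diagonal(self):
        seqs, _ = simulate.generate_ppr_family(simulate.PprFamilyParams(seed=0, seq_length=200))
        m = identity_matrix(seqs)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)
        assert ((m.values >= 0) & (m.values <= 1)).all()

    def test_permutation_invariance(self):
        seqs, _ = simulate.generate_ppr_family(simulate.PprFamilyParams(seed=1, seq_length=200))
        m1 = identity_matrix(seqs)
        rev = dict(reversed(list(seqs.items())))
        m2 = identity_matrix(rev)
        for a in seqs:
            for b in seqs:
                assert m1.identity(a, b) == m2.identity(a, b)

    def test_per_region_matrices(self):
        regions = {
            "coding": {"a": "ACGTACGTAC", "b": "ACGTACGTAC"},
            "downstream": {"a": "AAAA", "b": "TTTT"},
        }
        out = pairwise_identity(regions)
        assert out["coding"].identity("a", "b") == 1.0
        assert out["downstream"].identity("a", "b") == 0.0


def _matrix(ids, pairs):
    n = len(ids)
    values = np.eye(n)
    for (a, b), v in pairs.items():
        i, j = ids.index(a), ids.index(b)
        values[i, j] = values[j, i] = v
    return IdentityMatrix(ids=list(ids), values=values)


class TestDuplicationOrder:
    def test_two_genes_single_join(self):
        tree = duplication_order(_matrix(["a", "b"], {("a", "b"): 0.9}))
        assert len(tree.event_order) == 1
        assert tree.event_order[0][0] == pytest.approx(0.05)  # height = dist/2

    def test_hand_matrix_joins_closest_first(self):
        m = _matrix(["A", "B", "C"], {("A", "B"): 0.99, ("A", "C"): 0.95, ("B", "C"): 0.95})
        tree = duplication_order(m)
        youngest = tree.event_order[-1]
        assert set(youngest[1] + youngest[2]) == {"A", "B"}
        assert nearest_relative(m, "A") == [("B", 0.99), ("C", 0.95)]

    def test_missing_entries_rejected(self):
        m = _matrix(["a", "b"], {("a", "b"): np.nan})
        with pytest.raises(ValueError, match="missing"):
            duplication_order(m)

    def test_unknown_focal_rejected(self):
        with pytest.raises(ValueError, match="unknown focal"):
            nearest_relative(_matrix(["a", "b"], {("a", "b"): 0.9}), "z")

    @pytest.mark.parametrize("seed", range(10))
    def test_upgma_heights_match_scipy_average_linkage(self, seed):
        # independent implementation check on random matrices (<= 6 leaves)
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        ids = [f"g{i}" for i in range(n)]
        values = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = rng.uniform(0.5, 0.99)
        m = IdentityMatrix(ids=ids, values=values)
        tree = duplication_order(m)
        link = hierarchy.average(squareform(1.0 - values, checks=False))
        ours = sorted(h for h, _, _ in tree.event_order)
        scipys = sorted(link[:, 2] / 2.0)
        assert np.allclose(ours, scipys)

    @pytest.mark.parametrize("seed", range(10))
    def test_upgma_matches_brute_force_agglomeration(self, seed):
        # naive oracle: repeatedly join the closest cluster pair, recomputing
        # average distances from the original matrix each round
        rng = np.random.default_rng(100 + seed)
        n = 5
        ids = [f"g{i}" for i in range(n)]
        values = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = rng.uniform(0.5, 0.99)
        m = IdentityMatrix(ids=ids, values=values)
        dist = 1.0 - values

        clusters = [(i,) for i in range(n)]
        oracle_joins = []
        while len(clusters) > 1:
            best = None
            for x in range(len(clusters)):
                for y in range(x + 1, len(clusters)):
                    d = np.mean([dist[i, j] for i in clusters[x] for j in clusters[y]])
                    if best is None or d < best[0]:
                        best = (d, x, y)
            d, x, y = best
            merged = tuple(sorted(clusters[x] + clusters[y]))
            oracle_joins.append((round(d / 2, 12), frozenset(ids[i] for i in merged)))
            clusters = [c for k, c in enumerate(clusters) if k not in (x, y)] + [merged]

        tree = duplication_order(m)
        ours = sorted(
            (round(h, 12), frozenset(a + b)) for h, a, b in tree.event_order
        )
        assert ours == sorted(oracle_joins)

    def test_youngest_duplication_is_lowest_node(self):
        hits = 0
        for seed in range(100):
            seqs, events = simulate.generate_ppr_family(
                simulate.PprFamilyParams(seed=seed)
            )
            tree = duplication_order(identity_matrix(seqs))
            _, a, b = tree.event_order[-1]
            if set(a + b) == set(events[-1]):
                hits += 1
        assert hits >= 95

    def test_newick_is_deterministic_and_parseable(self):
        seqs, _ = simulate.generate_ppr_family(simulate.PprFamilyParams(seed=2, seq_length=200))
        tree1 = duplication_order(identity_matrix(seqs))
        tree2 = duplication_order(identity_matrix(seqs))
        assert tree1.newick() == tree2.newick()
        from io import StringIO

        from Bio import Phylo

        parsed = Phylo.read(StringIO(tree1.newick()), "newick")
        assert parsed.count_terminals() == len(seqs)
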