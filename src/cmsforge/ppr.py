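"""Pairwise identity and duplication ordering for clustered PPR gene families.

Restorer-of-fertility genes are typically members of tandemly duplicated
pentatricopeptide-repeat (PPR) clusters; which paralog a focal gene most
resembles — in the coding sequence and in the flanking regions — reveals the
order in which the cluster grew. We compute end-to-end pairwise identities
(global alignment, identity = matches / alignment columns) per annotated
region and agglomerate the distance 1 - identity by UPGMA; internal node
heights order the duplication events oldest -> youngest.

The UPGMA here keeps explicit lexicographic tie-breaking (ties join the
alphabetically first cluster pair) so trees are reproducible; average
linkage from scipy serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

ALIGN_MATCH = 1.0
ALIGN_MISMATCH = -1.0
ALIGN_GAP_OPEN = -2.0
ALIGN_GAP_EXTEND = -0.5


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = ALIGN_MATCH
    aligner.mismatch_score = ALIGN_MISMATCH
    aligner.open_gap_score = ALIGN_GAP_OPEN
    aligner.extend_gap_score = ALIGN_GAP_EXTEND
    return aligner


def global_identity(a: str, b: str) -> float:
    """Identity of the best global alignment: matches / alignment columns
    (gap columns count)."""
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _aligner().align(a.upper(), b.upper())[0]
    counts = aln.counts()
    return counts.identities / aln.length


@dataclass
class IdentityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, diagonal 1
    region: str = "coding"

    def identity(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def identity_matrix(seqs: dict[str, str], region: str = "coding") -> IdentityMatrix:
    """All-vs-all global-alignment identities for one region."""
    ids = list(seqs)
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    n = len(ids)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = global_identity(seqs[ids[i]], seqs[ids[j]])
    return IdentityMatrix(ids=ids, values=values, region=region)


def pairwise_identity(
    seqs_by_region: dict[str, dict[str, str]]
) -> dict[str, IdentityMatrix]:
    """One IdentityMatrix per annotated region (coding/upstream/downstream)."""
    return {region: identity_matrix(seqs, region) for region, seqs in seqs_by_region.items()}


@dataclass
class TreeNode:
    """Node of an ultrametric (UPGMA) tree; height in distance units."""

    name: str
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    leaves: tuple[str, ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def newick(self, parent_height: float | None = None) -> str:
        if self.is_leaf:
            label = self.name
        else:
            label = "(" + ",".join(
                sorted(c.newick(self.height) for c in self.children)
            ) + ")"
        if parent_height is None:
            return label + ";"
        return f"{label}:{parent_height - self.height:.6g}"


@dataclass
class DuplicationTree:
    root: TreeNode
    # internal nodes sorted oldest -> youngest (descending height); each entry
    # is (height, leaf set A, leaf set B) for the two clades the event joins
    event_order: list[tuple[float, tuple[str, ...], tuple[str, ...]]] = field(
        default_factory=list
    )

    def newick(self) -> str:
        return self.root.newick()


def duplication_order(matrix: IdentityMatrix) -> DuplicationTree:
    """UPGMA on distance 1 - identity with lexicographic tie-breaking.

    The node height of each join is half the average pairwise distance
    between the two clusters; sorted descending, joins order the duplication
    events oldest -> youngest (the lowest node is the most recent
    duplication).
    """
    if np.isnan(matrix.values).any():
        raise ValueError("identity matrix has missing entries")
    dist = 1.0 - matrix.values.astype(float)
    clusters: dict[tuple[str, ...], TreeNode] = {
        (name,): TreeNode(name=name, leaves=(name,)) for name in matrix.ids
    }
    index = {name: i for i, name in enumerate(matrix.ids)}

    def cluster_distance(a: tuple[str, ...], b: tuple[str, ...]) -> float:
        return float(
            np.mean([dist[index[x], index[y]] for x in a for y in b])
        )

    events = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                d = cluster_distance(keys[i], keys[j])
                cand = (d, keys[i], keys[j])
                if best is None or cand < best:
                    best = cand
        d, ka, kb = best
        height = d / 2.0
        node = TreeNode(
            name="",
            height=height,
            children=[clusters.pop(ka), clusters.pop(kb)],
            leaves=tuple(sorted(ka + kb)),
        )
        clusters[node.leaves] = node
        events.append((height, ka, kb))
    root = next(iter(clusters.values()))
    events.sort(key=lambda e: -e[0])
    return DuplicationTree(root=root, event_order=events)


def nearest_relative(matrix: IdentityMatrix, focal_id: str) -> list[tuple[str, float]]:
    """Other genes ranked by descending identity to ``focal_id``
    (ties broken lexicographically)."""
    if focal_id not in matrix.ids:
        raise ValueError(f"unknown focal gene {focal_id!r}")
    i = matrix.ids.index(focal_id)
    others = [
        (name, float(matrix.values[i, j]))
        for j, name in enumerate(matrix.ids)
        if name != focal_id
    ]
    others.sort(key=lambda t: (-t[1], t[0]))
    return others
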