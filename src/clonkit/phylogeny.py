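"""Mutation-presence phylogeny for the lesions of one case.

The tree is built from the binary mutation x sample presence matrix, rooted
at the germline.  Each edge carries the set of mutations gained on it, so
branch lengths (mutation counts) directly reflect trunk/branch/private
structure: the trunk holds mutations present in every lesion, internal
branches hold mutations shared by a lesion subset, and leaf edges hold
private mutations.

When the presence patterns are pairwise nested or disjoint they form a
laminar family and admit a unique perfect phylogeny, which is returned
directly.  Otherwise all rooted binary leaf-labeled topologies are
enumerated (practical for the <= 8 samples of a multi-lesion case) and
scored by small parsimony per mutation — a presence state may be gained once
and lost on any number of branches, gains and losses at equal cost — and a
minimum-score tree is returned, with ties broken by lexicographic Newick
string.  Each mutation is then assigned to the edge above the most recent
common ancestor of the samples carrying it, so every mutation sits on
exactly one edge and branch lengths sum to the number of distinct mutations.

This is a deliberately transparent maximum-parsimony construction: the tree
is used descriptively (shared trunk and branch mutation counts), not for
statistical inference of ancestral genotypes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_model import MutationCall, VariantKey

__all__ = [
    "PresenceMatrix",
    "TreeNode",
    "CaseTree",
    "build_presence_matrix",
    "infer_tree",
    "parsimony_score",
    "write_newick",
    "newick_string",
    "write_edge_assignments",
]

MAX_SAMPLES = 8


@dataclass
class PresenceMatrix:
    """Binary mutation x sample matrix; rows are variant keys, columns samples."""

    keys: list[VariantKey]
    samples: list[str]
    present: np.ndarray  # bool, shape (n_keys, n_samples)
    weights: np.ndarray | None = None  # optional per-row CCF values

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.keys), len(self.samples)):
            raise ValueError("presence matrix shape mismatch")
        if len(self.keys) and not self.present.any(axis=1).all():
            raise ValueError("presence matrix must not contain all-zero rows")

    def pattern_of(self, i: int) -> frozenset[str]:
        return frozenset(
            s for j, s in enumerate(self.samples) if self.present[i, j]
        )

    def patterns(self) -> dict[frozenset[str], list[VariantKey]]:
        """Group variant keys by their sample-presence pattern."""
        out: dict[frozenset[str], list[VariantKey]] = {}
        for i, key in enumerate(self.keys):
            out.setdefault(self.pattern_of(i), []).append(key)
        return out


def build_presence_matrix(
    calls_by_sample: Mapping[str, Sequence[MutationCall]],
    ccf: Mapping[tuple[str, VariantKey], float] | None = None,
    min_ccf: float = 0.0,
) -> PresenceMatrix:
    """Presence matrix over the union of each sample's retained variant keys.

    By default presence means the call survived filtering in that sample.
    Passing a CCF lookup with ``min_ccf > 0`` additionally requires the
    estimated CCF to exceed the threshold, guarding against false presence
    from stray reads.
    """
    samples = list(calls_by_sample)
    keyset: set[VariantKey] = set()
    present_pairs: set[tuple[str, VariantKey]] = set()
    for s, calls in calls_by_sample.items():
        for c in calls:
            if ccf is not None and min_ccf > 0:
                if ccf.get((s, c.key), 0.0) <= min_ccf:
                    continue
            keyset.add(c.key)
            present_pairs.add((s, c.key))
    keys = sorted(keyset)
    mat = np.zeros((len(keys), len(samples)), dtype=bool)
    for i, k in enumerate(keys):
        for j, s in enumerate(samples):
            mat[i, j] = (s, k) in present_pairs
    weights = None
    if ccf is not None:
        weights = np.array(
            [
                np.mean([ccf[(s, k)] for s in samples if (s, k) in ccf] or [0.0])
                for k in keys
            ]
        )
    return PresenceMatrix(keys, samples, mat, weights)


@dataclass
class TreeNode:
    """Node of a case tree; the edge above it carries ``edge_keys``."""

    label: str | None = None  # sample id for leaves
    children: list["TreeNode"] = field(default_factory=list)
    edge_keys: list[VariantKey] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def branch_length(self) -> int:
        return len(self.edge_keys)

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label or ""]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class CaseTree:
    """Rooted tree of one case's lesions; ``root`` is the germline.

    The germline root has a single child (the founding clone) whose edge is
    the trunk; every input mutation is assigned to exactly one edge.
    """

    root: TreeNode
    samples: list[str]
    parsimony: int = 0

    def edges(self) -> list[tuple[frozenset[str], list[VariantKey]]]:
        """(clade, mutations) for every edge below the germline root."""
        out: list[tuple[frozenset[str], list[VariantKey]]] = []

        def walk(node: TreeNode) -> None:
            out.append((frozenset(node.leaves()), node.edge_keys))
            for c in node.children:
                walk(c)

        for c in self.root.children:
            walk(c)
        return out

    def total_mutations(self) -> int:
        return sum(len(keys) for _, keys in self.edges())

    @property
    def trunk(self) -> TreeNode:
        return self.root.children[0]


def _is_laminar(patterns: Sequence[frozenset[str]]) -> bool:
    for a, b in combinations(patterns, 2):
        inter = a & b
        if inter and not (a <= b or b <= a):
            return False
    return True


def _laminar_tree(
    pattern_keys: dict[frozenset[str], list[VariantKey]], samples: list[str]
) -> CaseTree:
    full = frozenset(samples)
    clades = set(pattern_keys) | {full} | {frozenset([s]) for s in samples}
    nodes = {c: TreeNode(label=next(iter(c)) if len(c) == 1 else None) for c in clades}
    for c in clades:
        nodes[c].edge_keys = sorted(pattern_keys.get(c, []))
    # parent of clade X = smallest clade strictly containing X
    ordered = sorted(clades, key=len)
    for c in ordered:
        if c == full:
            continue
        parent = min(
            (d for d in clades if c < d), key=len, default=full
        )
        nodes[parent].children.append(nodes[c])
    for node in nodes.values():
        node.children.sort(key=lambda n: sorted(n.leaves()))
    germline = TreeNode(children=[nodes[full]])
    return CaseTree(germline, list(samples), parsimony=sum(map(len, pattern_keys.values())))


# -- exhaustive parsimony over rooted binary topologies ----------------------


def _enumerate_topologies(samples: Sequence[str]):
    """All rooted binary leaf-labeled topologies as nested tuples."""
    if len(samples) == 1:
        yield samples[0]
        return

    def insert(tree, leaf):
        # replace the whole subtree by (subtree, leaf)
        yield (tree, leaf)
        if isinstance(tree, tuple):
            left, right = tree
            for t in insert(left, leaf):
                yield (t, right)
            for t in insert(right, leaf):
                yield (left, t)

    def build(leaves):
        if len(leaves) == 1:
            yield leaves[0]
            return
        for sub in build(leaves[:-1]):
            yield from insert(sub, leaves[-1])

    yield from build(list(samples))


def _pattern_changes(topology, pattern: frozenset[str]) -> int:
    """Minimum state changes for a binary presence character, germline state 0."""
    INF = 10**9

    def cost(node) -> tuple[int, int]:
        if not isinstance(node, tuple):
            state = 1 if node in pattern else 0
            return (0, INF) if state == 0 else (INF, 0)
        (l0, l1), (r0, r1) = cost(node[0]), cost(node[1])
        c0 = min(l0, l1 + 1) + min(r0, r1 + 1)
        c1 = min(l0 + 1, l1) + min(r0 + 1, r1)
        return c0, c1

    c0, c1 = cost(topology)
    return min(c0, c1 + 1)  # germline above the root is state 0


def _topology_newick(topology) -> str:
    if not isinstance(topology, tuple):
        return topology
    parts = sorted(_topology_newick(t) for t in topology)
    return "(" + ",".join(parts) + ")"


def _tree_from_topology(
    topology, pattern_keys: dict[frozenset[str], list[VariantKey]], samples: list[str]
) -> CaseTree:
    def build(node) -> TreeNode:
        if not isinstance(node, tuple):
            return TreeNode(label=node)
        children = sorted(
            (build(c) for c in node), key=lambda n: sorted(n.leaves())
        )
        return TreeNode(children=list(children))

    top = build(topology)
    germline = TreeNode(children=[top])
    tree = CaseTree(germline, list(samples))
    # assign each mutation to the edge above the MRCA of its carriers
    nodes_by_clade: dict[frozenset[str], TreeNode] = {}

    def index(n: TreeNode) -> frozenset[str]:
        clade = frozenset(n.leaves())
        nodes_by_clade.setdefault(clade, n)
        for c in n.children:
            index(c)
        return clade

    index(top)
    for pattern, keys in pattern_keys.items():
        mrca = min(
            (c for c in nodes_by_clade if pattern <= c), key=len
        )
        nodes_by_clade[mrca].edge_keys.extend(sorted(keys))
    for n in nodes_by_clade.values():
        n.edge_keys.sort()
    return tree


def parsimony_score(topology, pattern_counts: Mapping[frozenset[str], int]) -> int:
    """Total parsimony changes of a nested-tuple topology over weighted patterns."""
    return sum(
        count * _pattern_changes(topology, pattern)
        for pattern, count in pattern_counts.items()
    )


def infer_tree(pm: PresenceMatrix) -> CaseTree:
    """Infer the case tree from a presence matrix.

    Laminar (conflict-free) pattern sets yield their unique perfect
    phylogeny; otherwise a minimum-parsimony rooted binary topology is found
    by exhaustive enumeration (gains once, losses allowed at equal cost),
    deterministic under a lexicographic Newick tie-break.
    """
    if len(pm.samples) > MAX_SAMPLES:
        raise ValueError(
            f"exhaustive search handles at most {MAX_SAMPLES} samples, "
            f"got {len(pm.samples)}"
        )
    if not pm.samples:
        raise ValueError("presence matrix has no samples")
    pattern_keys = pm.patterns()
    if _is_laminar(list(pattern_keys)):
        return _laminar_tree(pattern_keys, pm.samples)
    counts = {p: len(k) for p, k in pattern_keys.items()}
    best = None
    for topo in _enumerate_topologies(sorted(pm.samples)):
        score = parsimony_score(topo, counts)
        nk = _topology_newick(topo)
        cand = (score, nk, topo)
        if best is None or cand[:2] < best[:2]:
            best = cand
    tree = _tree_from_topology(best[2], pattern_keys, pm.samples)
    tree.parsimony = best[0]
    return tree


def newick_string(tree: CaseTree) -> str:
    """Newick serialization with branch lengths equal to mutation counts."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.label}:{node.branch_length}"
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner}):{node.branch_length}"

    top = tree.trunk
    if top.is_leaf:
        return f"({fmt(top)});"
    return f"{fmt(top)};"


def write_newick(tree: CaseTree, path: str | Path) -> None:
    Path(path).write_text(newick_string(tree) + "\n")


def write_edge_assignments(tree: CaseTree, path: str | Path) -> None:
    """TSV of per-edge mutation assignments (clade, branch length, keys)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["clade", "n_mutations", "mutations"])
        for clade, keys in tree.edges():
            w.writerow(
                [
                    "+".join(sorted(clade)),
                    len(keys),
                    ";".join(str(k) for k in keys),
                ]
            )
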