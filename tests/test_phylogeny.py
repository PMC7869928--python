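"""Presence matrix and parsimony tree: oracle equivalence, conservation, Newick."""

import dendropy
import numpy as np
import pytest

from clonkit.io_model import VariantKey
from clonkit.phylogeny import (
    CaseTree,
    PresenceMatrix,
    build_presence_matrix,
    infer_tree,
    newick_string,
    write_edge_assignments,
    write_newick,
)

from conftest import make_call


# --- independent parsimony oracle (leaf-set splitting + exhaustive states) ---


def oracle_topologies(leaves):
    """All rooted binary leaf-labeled topologies, by recursive leaf-set splits."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for mask in range(2 ** len(rest) - 1):
        left = [first] + [r for i, r in enumerate(rest) if mask >> i & 1]
        right = [r for i, r in enumerate(rest) if not mask >> i & 1]
        for lt in oracle_topologies(left):
            for rt in oracle_topologies(right):
                yield (lt, rt)


def oracle_changes(topology, pattern):
    """Min state changes for one presence pattern by exhaustive internal states."""
    internals = []

    def collect(node):
        if isinstance(node, tuple):
            internals.append(node)
            for c in node:
                collect(c)

    collect(topology)

    def edges(node, parent_state, states):
        total = 0
        state = states[id(node)] if isinstance(node, tuple) else (
            1 if node in pattern else 0
        )
        total += state != parent_state
        if isinstance(node, tuple):
            for c in node:
                total += edges(c, state, states)
        return total

    best = None
    for bits in range(2 ** len(internals)):
        states = {id(n): (bits >> i) & 1 for i, n in enumerate(internals)}
        total = edges(topology, 0, states)  # germline parent state 0
        best = total if best is None else min(best, total)
    return best


def oracle_min_score(samples, pattern_counts):
    best = None
    for topo in oracle_topologies(list(samples)):
        s = sum(
            cnt * oracle_changes(topo, pat) for pat, cnt in pattern_counts.items()
        )
        best = s if best is None else min(best, s)
    return best


def matrix_from_patterns(samples, pattern_counts):
    keys, rows = [], []
    i = 0
    for pat, cnt in pattern_counts.items():
        for _ in range(cnt):
            keys.append(VariantKey("1", 1000 + i, "C", "T"))
            rows.append([s in pat for s in samples])
            i += 1
    return PresenceMatrix(keys, list(samples), np.array(rows, dtype=bool))


def random_laminar_patterns(rng, samples):
    """Random clades of a random binary topology, each with a random count."""
    topo = next(
        iter(
            sorted(
                oracle_topologies(list(samples)),
                key=lambda t: rng.random(),
            )
        )
    )
    clades = []

    def collect(node):
        if isinstance(node, tuple):
            leaves = []

            def lv(n):
                if isinstance(n, tuple):
                    for c in n:
                        lv(c)
                else:
                    leaves.append(n)

            lv(node)
            clades.append(frozenset(leaves))
            for c in node:
                collect(c)
        else:
            clades.append(frozenset([node]))

    collect(topo)
    chosen = [c for c in clades if rng.random() < 0.8]
    if not chosen:
        chosen = [frozenset(samples)]
    return {c: int(rng.integers(1, 6)) for c in set(chosen)}


# --- presence matrix --------------------------------------------------------


class TestPresenceMatrix:
    def test_jup3_patterns_match_narrative(self, jup3_calls):
        pm = build_presence_matrix(jup3_calls)
        pats = {p: len(ks) for p, ks in pm.patterns().items()}
        trio = frozenset(jup3_calls)
        assert pats[trio] == 3
        assert pats[frozenset({"JuP3-DCIS", "JuP3-IDC"})] == 29
        assert pats[frozenset({"JuP3-DCIS"})] == 3  # STAG2 + 2 synthetic private
        assert pats[frozenset({"JuP3-IDC"})] == 3

    def test_single_sample_single_column(self):
        pm = build_presence_matrix({"S": [make_call(sample_id="S")]})
        assert pm.samples == ["S"] and pm.present.shape == (1, 1)

    def test_disjoint_samples_block_pattern(self):
        calls = {
            "A": [make_call(sample_id="A", pos=10)],
            "B": [make_call(sample_id="B", pos=20)],
        }
        pm = build_presence_matrix(calls)
        assert pm.present.sum() == 2
        assert (pm.present.sum(axis=1) == 1).all()

    def test_ccf_threshold_guards_presence(self):
        calls = {
            "A": [make_call(sample_id="A", pos=10)],
            "B": [make_call(sample_id="B", pos=10)],
        }
        k = calls["A"][0].key
        ccf = {("A", k): 0.9, ("B", k): 0.05}
        pm = build_presence_matrix(calls, ccf=ccf, min_ccf=0.1)
        assert pm.present.sum() == 1

    def test_all_zero_rows_rejected(self):
        with pytest.raises(ValueError):
            PresenceMatrix(
                [VariantKey("1", 1, "C", "T")], ["A"], np.zeros((1, 1), dtype=bool)
            )


# --- tree inference ---------------------------------------------------------


def clades_with_counts(tree: CaseTree):
    return {clade: len(keys) for clade, keys in tree.edges() if keys}


class TestInferTree:
    def test_jup3_topology_and_trunk(self, jup3_calls):
        pm = build_presence_matrix(jup3_calls)
        tree = infer_tree(pm)
        trunk_genes = set()
        for call in jup3_calls["JuP3-JP"]:
            if call.key in tree.trunk.edge_keys:
                trunk_genes.add(call.gene)
        assert trunk_genes == {"PIK3CA", "CES1", "SMG1"}
        assert frozenset(tree.trunk.leaves()) == frozenset(jup3_calls)
        cc = clades_with_counts(tree)
        assert cc[frozenset({"JuP3-DCIS", "JuP3-IDC"})] == 29

    def test_star_when_single_shared_pattern(self):
        samples = ["A", "B", "C"]
        pm = matrix_from_patterns(samples, {frozenset(samples): 7})
        tree = infer_tree(pm)
        assert tree.trunk.branch_length == 7
        assert all(c.is_leaf for c in tree.trunk.children)

    def test_mutation_conservation(self, rng):
        samples = ["A", "B", "C", "D"]
        for _ in range(20):
            pats = random_laminar_patterns(rng, samples)
            pm = matrix_from_patterns(samples, pats)
            tree = infer_tree(pm)
            assert tree.total_mutations() == len(pm.keys)

    def test_laminar_matrices_match_oracle(self, rng):
        samples = ["A", "B", "C", "D"]
        for _ in range(15):
            pats = random_laminar_patterns(rng, samples)
            pm = matrix_from_patterns(samples, pats)
            tree = infer_tree(pm)
            # perfect phylogeny: every pattern's mutations on its own edge
            cc = clades_with_counts(tree)
            assert cc == dict(pats)
            assert tree.parsimony == oracle_min_score(samples, pats)

    def test_conflicting_matrix_matches_oracle_score(self, rng):
        samples = ["A", "B", "C", "D"]
        for _ in range(10):
            pats = {}
            n_pat = int(rng.integers(2, 5))
            for _ in range(n_pat):
                size = int(rng.integers(1, len(samples) + 1))
                pat = frozenset(rng.choice(samples, size=size, replace=False))
                pats[pat] = pats.get(pat, 0) + int(rng.integers(1, 4))
            pm = matrix_from_patterns(samples, pats)
            tree = infer_tree(pm)
            assert tree.total_mutations() == len(pm.keys)
            if tree.parsimony != len(pm.keys):  # took the search path
                assert tree.parsimony == oracle_min_score(samples, pats)

    def test_too_many_samples_rejected(self):
        samples = [f"S{i}" for i in range(9)]
        pm = matrix_from_patterns(samples, {frozenset(samples): 1})
        with pytest.raises(ValueError, match="8"):
            infer_tree(pm)


# --- newick -----------------------------------------------------------------


class TestNewick:
    def test_jup3_shape_and_branch_lengths(self, jup3_calls):
        tree = infer_tree(build_presence_matrix(jup3_calls))
        nwk = newick_string(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in parsed.leaf_node_iter()
        }
        assert lengths["JuP3-JP"] == 6
        # DCIS/IDC ancestor edge carries the 29 branch mutations
        internal = [
            n for n in parsed.preorder_node_iter() if n.taxon is None and n.parent_node
        ]
        assert 29 in {n.edge.length for n in internal}

    def test_round_trip_preserves_topology_and_lengths(self, sim_case):
        tree = infer_tree(build_presence_matrix(sim_case.calls_by_lesion))
        nwk = newick_string(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        total = sum(
            e.length for e in parsed.preorder_edge_iter() if e.length is not None
        )
        assert total == tree.total_mutations()

    def test_single_leaf_form(self):
        pm = matrix_from_patterns(["S"], {frozenset(["S"]): 4})
        tree = infer_tree(pm)
        assert newick_string(tree) == "(S:4);"

    def test_byte_stable(self, tmp_path, jup3_calls):
        pm = build_presence_matrix(jup3_calls)
        p1, p2 = tmp_path / "a.nwk", tmp_path / "b.nwk"
        write_newick(infer_tree(pm), p1)
        write_newick(infer_tree(pm), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_edge_assignment_table(self, tmp_path, jup3_calls):
        tree = infer_tree(build_presence_matrix(jup3_calls))
        out = tmp_path / "edges.tsv"
        write_edge_assignments(tree, out)
        text = out.read_text()
        assert "JuP3-DCIS+JuP3-IDC" in text
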