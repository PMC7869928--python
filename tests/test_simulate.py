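"""Generator determinism, truth consistency, and the packaged JuP3 fixture."""

import numpy as np
import pytest

from clonkit.ccf import expected_vaf
from clonkit.io_model import read_mutation_table, write_mutation_table
from clonkit.phylogeny import build_presence_matrix
from clonkit.simulate import (
    SimConfig,
    jup3_fixture_purities,
    jup3_fixture_segments,
    load_jup3_fixture,
    preset,
    simulate_case,
)


def small_config(seed=0):
    return SimConfig(
        case_id="T",
        lesions=("A", "B", "C"),
        trunk_size=2,
        branches={("B", "C"): 4},
        private_sizes={"A": 3, "B": 1, "C": 2},
        seed=seed,
    )


class TestGenerator:
    def test_deterministic_given_seed(self, tmp_path):
        c1 = simulate_case(small_config(5))
        c2 = simulate_case(small_config(5))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        c1.write(d1)
        c2.write(d2)
        for name in ("T.mutations.tsv", "T.segments.tsv", "T.purity.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_different_seed_differs(self):
        k1 = {c.key for c in simulate_case(small_config(1)).all_calls()}
        k2 = {c.key for c in simulate_case(small_config(2)).all_calls()}
        assert k1 != k2

    def test_configured_pattern_counts_exact(self):
        case = simulate_case(small_config(3))
        pm = build_presence_matrix(case.calls_by_lesion)
        pats = {frozenset(s.split("-", 1)[1] for s in p): len(k) for p, k in pm.patterns().items()}
        assert pats == {
            frozenset({"A", "B", "C"}): 2,
            frozenset({"B", "C"}): 4,
            frozenset({"A"}): 3,
            frozenset({"B"}): 1,
            frozenset({"C"}): 2,
        }

    def test_truth_edges_consistent_with_presence(self):
        case = simulate_case(small_config(4))
        present = {}
        for sample, calls in case.calls_by_lesion.items():
            for c in calls:
                present.setdefault(c.key, set()).add(sample)
        for key, edge in case.truth.edge.items():
            assert present[key] == set(edge)

    def test_trunk_has_hotspot_driver(self):
        case = simulate_case(small_config(6))
        drivers = [c for c in case.all_calls() if c.hotspot]
        assert drivers and all(c.gene == "PIK3CA" for c in drivers)
        assert case.truth.edge[drivers[0].key] == frozenset({"T-A", "T-B", "T-C"})

    def test_trunk_vaf_converges_at_high_depth(self):
        cfg = SimConfig(
            case_id="D",
            lesions=("A", "B"),
            trunk_size=200,
            purity={"A": 0.6, "B": 0.6},
            mean_depth=10_000,
            seed=8,
        )
        case = simulate_case(cfg)
        vafs = [
            c.tumor_vaf
            for c in case.calls_by_lesion["D-A"]
            if case.truth.ccf[("D-A", c.key)] == 1.0
        ]
        assert np.mean(vafs) == pytest.approx(expected_vaf(1.0, 0.6, 1, 2, 2), abs=0.005)

    def test_cross_case_mutations_disjoint(self):
        cfgs = preset("null_pair", seed=9)
        cases = [simulate_case(c) for c in cfgs]
        k1 = {c.key for c in cases[0].all_calls()}
        k2 = {c.key for c in cases[1].all_calls()}
        assert not (k1 & k2)

    def test_impossible_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(case_id="X", lesions=("A", "B"), branches={("A", "B"): 2})
        with pytest.raises(ValueError):
            SimConfig(case_id="X", lesions=("A",))
        with pytest.raises(ValueError):
            SimConfig(case_id="X", lesions=("A", "B"), trunk_size=0)

    def test_carcinoma_only_cn_events(self):
        case = simulate_case(preset("jup3_like", seed=2)[0])
        by_sample = {}
        for s in case.segments:
            if s.log2_ratio != 0.0:
                by_sample.setdefault(s.sample_id, set()).add(s.log2_ratio)
        assert "SIM3-JP" not in by_sample
        assert by_sample["SIM3-DCIS"] == {0.4, -0.4}


class TestJup3Fixture:
    def test_shared_trio_exactly(self, jup3_calls):
        keysets = {s: {c.key for c in cs} for s, cs in jup3_calls.items()}
        shared = set.intersection(*keysets.values())
        genes = {
            c.gene
            for cs in jup3_calls.values()
            for c in cs
            if c.key in shared and c.effect != "synonymous"
        }
        assert len(shared) == 3
        assert genes == {"PIK3CA", "CES1", "SMG1"}

    def test_pik3ca_is_hotspot(self, jup3_calls):
        pik = [c for c in jup3_calls["JuP3-JP"] if c.gene == "PIK3CA"]
        assert pik[0].hotspot and pik[0].protein_change == "E542K"

    def test_stag2_only_in_dcis_fgf12_only_in_idc(self, jup3_calls):
        where = {}
        for sample, calls in jup3_calls.items():
            for c in calls:
                where.setdefault(c.gene, set()).add(sample)
        assert where["STAG2"] == {"JuP3-DCIS"}
        assert where["FGF12"] == {"JuP3-IDC"}

    def test_named_branch_genes_in_both_carcinomas(self, jup3_calls):
        where = {}
        for sample, calls in jup3_calls.items():
            for c in calls:
                where.setdefault(c.gene, set()).add(sample)
        for gene in ("ARID1A", "KMT2C", "PIK3CB", "NUP93", "PIK3C2A"):
            assert where[gene] == {"JuP3-DCIS", "JuP3-IDC"}, gene

    def test_fixture_round_trips_through_io(self, tmp_path, jup3_calls):
        calls = [c for cs in jup3_calls.values() for c in cs]
        p = tmp_path / "jup3.tsv"
        write_mutation_table(calls, p)
        assert read_mutation_table(p) == calls

    def test_fixture_deterministic(self):
        a = load_jup3_fixture()
        b = load_jup3_fixture()
        assert a == b

    def test_fixture_segments_and_purities(self):
        segs = jup3_fixture_segments()
        purities = jup3_fixture_purities()
        assert set(purities) == {"JuP3-JP", "JuP3-DCIS", "JuP3-IDC"}
        jp = [s for s in segs if s.sample_id == "JuP3-JP"]
        assert all(s.log2_ratio == 0.0 for s in jp)
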