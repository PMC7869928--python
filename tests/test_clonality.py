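"""Clonality index: formula fidelity, monotonicity, permutation null behavior."""

import math

import pytest

from clonkit.clonality import (
    FrequencyTable,
    MutationFrequency,
    clonality_index,
    pair_probability,
    pairwise_clonality,
    read_frequency_table,
)
from clonkit.io_model import VariantKey

from conftest import make_call


def keys(n):
    return [VariantKey("1", 1000 + i, "C", "T") for i in range(n)]


def table_for(ks, ps, floor=1e-6):
    return FrequencyTable(
        [MutationFrequency(p=p, key=k) for k, p in zip(ks, ps)], floor=floor
    )


class TestPairProbability:
    @pytest.mark.parametrize("p,expected", [(0.1, 0.01), (1e-4, 1e-8), (0.5, 0.25)])
    def test_two_trial_binomial(self, p, expected):
        assert pair_probability(p) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.5])
    def test_domain(self, p):
        with pytest.raises(ValueError):
            pair_probability(p)


class TestClonalityIndex:
    def test_empty_product_is_zero(self):
        assert clonality_index([], table_for([], [])) == 0.0

    def test_two_shared_at_one_percent(self):
        ks = keys(2)
        assert clonality_index(ks, table_for(ks, [0.01, 0.01])) == pytest.approx(8.0)

    def test_log_form_equals_direct_product(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 8))
            ks = keys(m)
            ps = rng.uniform(1e-5, 0.5, size=m)
            ci = clonality_index(ks, table_for(ks, list(ps)))
            direct = -math.log10(math.prod(pair_probability(float(p)) for p in ps))
            assert ci == pytest.approx(direct, abs=1e-9, rel=1e-9)

    def test_adding_shared_mutation_strictly_increases(self):
        ks = keys(3)
        t = table_for(ks, [0.01, 0.05, 0.4])
        assert (
            clonality_index(ks[:1], t)
            < clonality_index(ks[:2], t)
            < clonality_index(ks, t)
        )

    def test_rarer_mutations_contribute_more(self):
        k1, k2 = keys(2)
        rare = clonality_index([k1], table_for([k1, k2], [1e-5, 0.1]))
        common = clonality_index([k2], table_for([k1, k2], [1e-5, 0.1]))
        assert rare > common

    def test_unknown_mutation_floors(self):
        t = table_for([], [], floor=1e-6)
        assert clonality_index(keys(1), t) == pytest.approx(12.0)  # -2 log10 1e-6

    def test_cap_bounds_contribution(self):
        k = keys(1)
        t = table_for(k, [0.99])  # capped at 0.5
        assert clonality_index(k, t) == pytest.approx(-2 * math.log10(0.5))


def _two_sample_calls(shared_p=0.01):
    ks = keys(4)
    a = [make_call(sample_id="A", pos=k.pos) for k in ks[:3]]
    b = [make_call(sample_id="B", pos=k.pos) for k in ks[1:]]
    freqs = table_for(ks, [shared_p] * 4)
    return {"A": a, "B": b}, freqs


class TestPairwise:
    def test_shared_set_is_key_intersection(self):
        calls, freqs = _two_sample_calls()
        (res,) = pairwise_clonality(calls, freqs, n_perm=200, seed=1)
        assert res.M == 2
        assert {k.pos for k in res.shared_keys} == {1001, 1002}

    def test_deterministic_given_seed(self):
        calls, freqs = _two_sample_calls()
        r1 = pairwise_clonality(calls, freqs, n_perm=300, seed=42)
        r2 = pairwise_clonality(calls, freqs, n_perm=300, seed=42)
        assert r1[0].ci == r2[0].ci
        assert r1[0].null_quantiles == r2[0].null_quantiles
        assert r1[0].related == r2[0].related

    def test_alpha_one_never_related(self):
        calls, freqs = _two_sample_calls(shared_p=1e-5)
        (res,) = pairwise_clonality(calls, freqs, n_perm=100, seed=1, alpha=1.0)
        assert res.related is False

    def test_disjoint_samples_zero_ci(self):
        a = [make_call(sample_id="A", pos=10)]
        b = [make_call(sample_id="B", pos=20)]
        freqs = table_for(keys(2), [0.01, 0.01])
        (res,) = pairwise_clonality({"A": a, "B": b}, freqs, n_perm=100, seed=1)
        assert res.M == 0 and res.ci == 0.0 and not res.related

    def test_empty_sample_warns_and_unrelated(self, caplog):
        a = [make_call(sample_id="A", pos=10)]
        freqs = table_for(keys(1), [0.01])
        (res,) = pairwise_clonality({"A": a, "B": []}, freqs, n_perm=100, seed=1)
        assert res.ci == 0.0 and res.related is False
        assert any("no retained mutations" in m for m in caplog.messages)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pairwise_clonality({"A": []}, table_for([], []))

    def test_identical_lists_related_against_null(self):
        ks = keys(5)
        a = [make_call(sample_id="A", pos=k.pos) for k in ks]
        b = [make_call(sample_id="B", pos=k.pos) for k in ks]
        # catalog with many background entries so the null has room to vary
        bg = [
            MutationFrequency(p=1e-4, key=VariantKey("2", 5000 + i, "C", "T"))
            for i in range(200)
        ]
        freqs = FrequencyTable(
            [MutationFrequency(p=1e-4, key=k) for k in ks] + bg
        )
        (res,) = pairwise_clonality({"A": a, "B": b}, freqs, n_perm=500, seed=3)
        assert res.M == 5 and res.related


def test_frequency_table_round_trip(tmp_path):
    p = tmp_path / "f.tsv"
    p.write_text(
        "chrom\tpos\tref\talt\tgene\tprotein_change\tp\n"
        "3\t178936082\tG\tA\tPIK3CA\tE542K\t0.02\n"
        "\t\t\t\tAKT1\tE17K\t0.005\n"
    )
    t = read_frequency_table(p)
    assert t.lookup(VariantKey("3", 178936082, "G", "A")) == pytest.approx(0.02)
    # fallback by gene + protein change for entries without coordinates
    assert t.lookup(VariantKey("14", 1, "C", "T"), "AKT1", "E17K") == pytest.approx(0.005)
    assert t.lookup(VariantKey("9", 9, "C", "T")) == pytest.approx(t.floor)
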