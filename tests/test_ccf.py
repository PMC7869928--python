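"""CCF grid posterior: oracle equivalence, classification rules, recovery."""

import numpy as np
import pytest
from scipy import stats

from clonkit.ccf import CCFEstimate, estimate_case, estimate_ccf, expected_vaf
from clonkit.io_model import CopySegment, SamplePurity

from conftest import make_call


def grid_posterior_oracle(t_alt, depth, purity, multiplicity, cn_t, cn_n, step=0.01):
    """Direct normalization of the binomial likelihood over the CCF grid."""
    grid = np.arange(step, 1.0 + step / 2, step)
    f = np.clip(
        purity * multiplicity * grid / (purity * cn_t + (1 - purity) * cn_n), 0, 1
    )
    lik = stats.binom.pmf(t_alt, depth, f)
    post = lik / lik.sum()
    return grid, post


class TestExpectedVaf:
    def test_fully_clonal_pure_diploid_het(self):
        assert expected_vaf(1.0, 1.0, 1, 2, 2) == 0.5

    def test_half_purity_halves_vaf(self):
        assert expected_vaf(1.0, 0.5, 1, 2, 2) == pytest.approx(0.25)

    def test_zero_ccf_gives_zero(self):
        assert expected_vaf(0.0, 0.8, 1, 2, 2) == 0.0

    def test_clamped_to_unit_interval(self):
        assert expected_vaf(1.0, 1.0, 4, 2, 2) == 1.0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            expected_vaf(1.0, 0.0, 1, 2, 2)
        with pytest.raises(ValueError):
            expected_vaf(1.0, 0.5, 1, 0, 2)
        with pytest.raises(ValueError):
            expected_vaf(1.0, 0.5, 1, 2, 3)


class TestGridPosterior:
    def test_high_depth_clonal_vaf_maps_to_ccf_one(self):
        est = estimate_ccf(make_call(t_ref=50, t_alt=50), SamplePurity("S1", 1.0))
        assert est.ccf_point == pytest.approx(1.0)
        assert est.clonal

    def test_subclonal_matches_independent_oracle(self):
        est = estimate_ccf(make_call(t_ref=90, t_alt=10), SamplePurity("S1", 1.0))
        grid, post = grid_posterior_oracle(10, 100, 1.0, 1, 2, 2)
        assert est.ccf_point == pytest.approx(grid[np.argmax(post)], abs=1e-12)
        assert est.ccf_point == pytest.approx(0.2, abs=0.01)
        assert est.p_clonal == pytest.approx(post[grid >= 0.9 - 1e-12].sum(), abs=1e-9)
        assert not est.clonal
        # midpoint (Hazen) discrete-percentile convention
        cdf_mid = np.cumsum(post) - 0.5 * post
        assert est.ci_low == pytest.approx(grid[np.searchsorted(cdf_mid, 0.025)], abs=1e-12)
        assert est.ci_high == pytest.approx(grid[np.searchsorted(cdf_mid, 0.975)], abs=1e-12)

    def test_posterior_mass_definition_of_p_clonal(self):
        for t_alt in (5, 20, 35, 50):
            est = estimate_ccf(
                make_call(t_ref=100 - t_alt, t_alt=t_alt), SamplePurity("S1", 1.0)
            )
            grid, post = grid_posterior_oracle(t_alt, 100, 1.0, 1, 2, 2)
            assert est.p_clonal == pytest.approx(post[grid >= 0.9 - 1e-12].sum(), abs=1e-9)

    def test_mode_monotone_in_alt_count(self):
        modes = [
            estimate_ccf(
                make_call(t_ref=100 - k, t_alt=k), SamplePurity("S1", 1.0)
            ).ccf_point
            for k in range(1, 50, 3)
        ]
        assert all(b >= a for a, b in zip(modes, modes[1:]))

    def test_interval_brackets_point(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            depth = int(rng.integers(10, 300))
            t_alt = int(rng.integers(1, depth + 1))
            est = estimate_ccf(
                make_call(t_ref=depth - t_alt, t_alt=t_alt),
                SamplePurity("S1", float(rng.uniform(0.2, 1.0))),
            )
            assert est.ci_low <= est.ccf_point <= est.ci_high


class TestClonalRules:
    def test_probability_rule_without_interval_rule(self):
        # mode near 0.95 at moderate depth: >50% mass above 0.9 but wide CI
        est = estimate_ccf(make_call(t_ref=52, t_alt=48), SamplePurity("S1", 1.0))
        assert est.p_clonal > 0.5 and est.ci_low <= 0.9
        assert est.clonal

    def test_interval_rule(self):
        est = estimate_ccf(make_call(t_ref=500, t_alt=500), SamplePurity("S1", 1.0))
        assert est.ci_low > 0.9
        assert est.clonal

    def test_both_rules_fail_subclonal(self):
        est = estimate_ccf(make_call(t_ref=70, t_alt=30), SamplePurity("S1", 1.0))
        assert est.p_clonal <= 0.5 and est.ci_low <= 0.9
        assert not est.clonal


class TestMultiplicityAndCopyNumber:
    def test_default_diploid_multiplicity_one(self):
        est = estimate_ccf(make_call(), SamplePurity("S1", 0.6))
        assert est.multiplicity == 1

    def test_high_vaf_on_amplified_segment_raises_multiplicity(self):
        seg = CopySegment("S1", "1", 1, 10_000, 0.6, cn_total=4, cn_minor=1)
        est = estimate_ccf(
            make_call(t_ref=30, t_alt=70), SamplePurity("S1", 0.9), seg
        )
        assert est.multiplicity > 1

    def test_homozygous_deletion_unestimable(self):
        seg = CopySegment("S1", "1", 1, 10_000, -2.0, cn_total=0, cn_minor=0)
        est = estimate_ccf(make_call(), SamplePurity("S1", 0.6), seg)
        assert not est.estimable and not est.clonal

    def test_zero_tumor_depth_rejected(self):
        with pytest.raises(ValueError):
            estimate_ccf(make_call(t_ref=0, t_alt=0), SamplePurity("S1", 0.6))


def test_missing_purity_names_sample():
    with pytest.raises(KeyError, match="S1"):
        estimate_case([make_call()], {"OTHER": SamplePurity("OTHER", 0.5)})


def test_recovery_and_coverage_quick(rng):
    """Smaller-scale version of the recovery study the acceptance run performs."""
    purity, depth_mean = 0.5, 100
    hits = 0
    err = []
    n = 120
    for _ in range(n):
        truth = float(rng.choice([0.2, 0.5, 1.0]))
        f = expected_vaf(truth, purity, 1, 2, 2)
        depth = max(1, int(rng.poisson(depth_mean)))
        t_alt = int(rng.binomial(depth, f))
        est = estimate_ccf(
            make_call(t_ref=depth - t_alt, t_alt=t_alt), SamplePurity("S1", purity)
        )
        err.append(abs(est.ccf_point - truth))
        hits += est.ci_low <= truth <= est.ci_high
    assert np.mean(err) <= 0.1
    assert hits / n >= 0.9


def test_invalid_interval_rejected():
    with pytest.raises(ValueError):
        CCFEstimate(0.5, 0.6, 0.9, 0.1, 1, False)
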