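import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from wcps import (
    DataValidationError,
    ExpressionProfile,
    build_empirical_distribution,
    critical_value,
    detect,
    dn_scan,
    flag_dge_samples,
    weight_function,
)
from conftest import brute_force_dn


class TestCriticalValue:
    def test_kolmogorov_constants(self):
        assert critical_value(0.05) == pytest.approx(1.358, abs=5e-4)
        assert critical_value(0.01) == pytest.approx(1.628, abs=5e-4)

    def test_monotone_decreasing_in_alpha(self):
        alphas = np.linspace(0.01, 0.99, 25)
        vals = [critical_value(a) for a in alphas]
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] < 0.5  # C(alpha) -> 0 as alpha -> 1

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 1.7])
    def test_invalid_alpha(self, alpha):
        with pytest.raises(DataValidationError):
            critical_value(alpha)


class TestEmpiricalDistribution:
    def test_step_function_values(self):
        ecdf = build_empirical_distribution([1, 2, 3, 4])
        assert ecdf.cdf(2.5) == 0.5
        assert ecdf.cdf(4) == 1.0
        assert ecdf.cdf(0.5) == 0.0

    def test_tied_degenerate_sample(self):
        ecdf = build_empirical_distribution([5, 5, 5])
        assert ecdf.cdf(5) == 1.0
        assert ecdf.cdf(4.9) == 0.0

    def test_generalized_inverse_contract(self, rng):
        x = rng.standard_normal(40)
        ecdf = build_empirical_distribution(x)
        assert np.all(ecdf.inverse(ecdf.cdf(x)) <= x + 1e-12)

    def test_sup_distance_to_normal_matches_brute_force(self, rng):
        x = rng.standard_normal(25)
        ecdf = build_empirical_distribution(x)
        # brute force: the sup of |ECDF - Phi| is attained at a jump point,
        # approaching from either side
        xs = np.sort(x)
        n = xs.size
        brute = max(
            max(abs((i + 1) / n - norm.cdf(v)), abs(i / n - norm.cdf(v)))
            for i, v in enumerate(xs)
        )
        grid = np.linspace(-5, 5, 200001)
        coarse = np.max(np.abs(ecdf.cdf(grid) - norm.cdf(grid)))
        assert coarse == pytest.approx(brute, abs=1e-4)

    @pytest.mark.parametrize("values", [[1.0], [1.0, np.nan], [np.inf, 0.0]])
    def test_invalid_inputs(self, values):
        with pytest.raises(DataValidationError):
            build_empirical_distribution(values)


class TestDnScan:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n1=st.integers(2, 15),
        n2=st.integers(2, 15),
    )
    def test_matches_brute_force_oracle(self, seed, n1, n2):
        """Exhaustive double loop over splits and ECDF jump points."""
        r = np.random.default_rng(seed)
        control = r.standard_normal(n1)
        case = r.standard_normal(n2)
        prof = ExpressionProfile("g", control, case, as_sequence=True)
        scan = dn_scan(prof)
        expected = brute_force_dn(control, case)
        np.testing.assert_allclose(scan.dn_values, expected, atol=1e-12)

    def test_oracle_with_ties_and_sorting(self, rng):
        control = np.round(rng.standard_normal(12), 1)  # force ties
        case = np.round(rng.standard_normal(10), 1)
        prof = ExpressionProfile("g", control, case)  # sorted-case convention
        scan = dn_scan(prof)
        np.testing.assert_allclose(
            scan.dn_values, brute_force_dn(control, case, as_sequence=False), atol=1e-12
        )

    def test_constant_sequence_all_zero(self):
        prof = ExpressionProfile("flat", [3.0] * 10, [3.0] * 10)
        scan = dn_scan(prof)
        assert np.all(scan.dn_values == 0)
        res = detect(prof, alpha=0.05)
        assert not res.significant
        assert res.direction == "none"
        assert res.statistic == 0.0

    def test_grid_lengths_and_bounds(self, null_profile):
        scan = dn_scan(null_profile)
        n = null_profile.n
        assert (
            len(scan.t_grid) == len(scan.dn_values) == len(scan.weights)
            == len(scan.weighted_values) == null_profile.n2
        )
        assert np.all(scan.dn_values >= 0)
        assert np.all(scan.weights >= 1)
        assert np.all((scan.t_grid > 0) & (scan.t_grid < 1))
        assert scan.positions[0] == null_profile.n1

    def test_too_short_sequence(self):
        with pytest.raises(DataValidationError):
            dn_scan(ExpressionProfile("g", [1.0, 2.0], [1.0]))
        with pytest.raises(DataValidationError):
            ExpressionProfile("g", [1.0], [1.0, 2.0])

    def test_grid_sup_is_approximation_from_below(self, shifted_profile):
        exact = dn_scan(shifted_profile, sup="exact")
        grid = dn_scan(shifted_profile, sup="grid")
        assert np.all(grid.dn_values <= exact.dn_values + 1e-12)
        fine = dn_scan(shifted_profile, sup="grid", y_step=1e-4)
        # the control-quantile grid recovers the control-side jump points
        assert fine.dn_values.max() <= exact.dn_values.max() + 1e-12

    def test_full_range_positions(self, null_profile):
        scan = dn_scan(null_profile, positions="full")
        assert scan.positions[0] == 1
        assert scan.positions[-1] == null_profile.n - 1


class TestWeightFunction:
    def test_left_end_near_one(self):
        w = weight_function(np.arange(25, 50), 50)
        assert 1.0 <= w[0] <= 1.05

    def test_non_decreasing_and_capped(self):
        w = weight_function(np.arange(25, 50), 50)
        assert np.all(np.diff(w) >= 0)
        assert w.max() <= 1.5 + 1e-12

    def test_short_sequence_error(self):
        with pytest.raises(DataValidationError):
            weight_function([1], 3)

    def test_identity_weight_recovers_unweighted(self, shifted_profile):
        scan = dn_scan(shifted_profile)
        np.testing.assert_allclose(scan.weighted_values / scan.weights, scan.dn_values)

    def test_max_contract(self, shifted_profile):
        scan = dn_scan(shifted_profile)
        assert np.all(scan.weighted_values.max() >= scan.weighted_values - 1e-15)


class TestInvariances:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rank_invariance_under_increasing_transforms(self, seed):
        """ECDF-based statistics are unchanged by strictly increasing maps."""
        r = np.random.default_rng(seed)
        control, case = r.standard_normal(12), r.standard_normal(14)
        base = dn_scan(ExpressionProfile("g", control, case, as_sequence=True))
        for f in (lambda v: np.exp(v), lambda v: v**3 + 2 * v, lambda v: 10 + 0.1 * v):
            scan = dn_scan(ExpressionProfile("g", f(control), f(case), as_sequence=True))
            np.testing.assert_allclose(scan.dn_values, base.dn_values, atol=1e-12)
            np.testing.assert_allclose(scan.weighted_values, base.weighted_values, atol=1e-12)

    def test_control_permutation_invariance(self, rng):
        control, case = rng.standard_normal(20), rng.standard_normal(20)
        base = dn_scan(ExpressionProfile("g", control, case, as_sequence=True))
        perm = dn_scan(
            ExpressionProfile("g", rng.permutation(control), case, as_sequence=True)
        )
        np.testing.assert_allclose(base.dn_values, perm.dn_values)

    def test_case_permutation_invariance_when_sorted(self, rng):
        control, case = rng.standard_normal(20), rng.standard_normal(20)
        base = dn_scan(ExpressionProfile("g", control, case))
        perm = dn_scan(ExpressionProfile("g", control, rng.permutation(case)))
        np.testing.assert_allclose(base.dn_values, perm.dn_values)


class TestDetect:
    def test_strong_shift_detected_with_direction(self, rng):
        case = rng.standard_normal(25)
        case[16:] += 4.0
        prof = ExpressionProfile("g", rng.standard_normal(25), case, as_sequence=True)
        res = detect(prof, alpha=0.01, mode="wcps")
        assert res.significant
        assert res.direction == "over"
        assert res.cp_fraction == pytest.approx(41 / 50, abs=0.04)

    def test_under_expression_via_negated_scan(self, rng):
        case = rng.standard_normal(24)
        down = rng.choice(24, size=8, replace=False)
        case[down] -= 4.0
        prof = ExpressionProfile("g", rng.standard_normal(25), case)
        res = detect(prof, alpha=0.01, mode="wcps")
        assert res.significant
        assert res.direction == "under"

    def test_significance_matches_threshold(self, shifted_profile):
        res = detect(shifted_profile, alpha=0.01, mode="wcps", direction="over")
        assert res.significant == (res.statistic > critical_value(0.01))
        assert res.cp_fraction == res.cp_index / shifted_profile.n

    def test_npcps_statistic_is_unweighted_max(self, shifted_profile):
        scan = dn_scan(shifted_profile)
        res = detect(shifted_profile, mode="npcps", direction="over")
        assert res.statistic == pytest.approx(scan.dn_values.max())

    def test_invalid_mode_and_direction(self, null_profile):
        with pytest.raises(DataValidationError):
            detect(null_profile, mode="bogus")
        with pytest.raises(DataValidationError):
            detect(null_profile, direction="sideways")


class TestFlagging:
    def test_threshold_crossing_example(self):
        prof = ExpressionProfile("g", [0.0, 0.0, 0.0, 0.1], [0.0, 0.0, 0.0, 5.0, 6.0])
        res = detect(prof, alpha=0.05, mode="wcps")
        assert res.significant and res.direction == "over"
        assert 0.0 <= res.cp_value < 5.0
        np.testing.assert_array_equal(flag_dge_samples(prof, res), [0, 0, 0, 1, 1])

    def test_non_significant_gives_zero_flags_with_warning(self, null_profile):
        res = detect(null_profile, alpha=1e-6, mode="npcps")
        if res.significant:  # extremely unlikely at this alpha
            pytest.skip("unexpected significance")
        with pytest.warns(UserWarning):
            flags = flag_dge_samples(null_profile, res)
        assert flags.sum() == 0

    def test_flag_count_recovers_planted_subset(self):
        """Over many simulated genes with k=9 of 25 case samples shifted,
        the flagged count concentrates near 9."""
        r = np.random.default_rng(5)
        counts = []
        for _ in range(300):
            case = r.standard_normal(25)
            case[16:] += 2.0
            prof = ExpressionProfile("g", r.standard_normal(25), case, as_sequence=True)
            res = detect(prof, alpha=0.05, mode="wcps", direction="over")
            if res.significant:
                counts.append(flag_dge_samples(prof, res).sum())
        counts = np.array(counts)
        assert len(counts) > 250
        assert abs(np.median(counts) - 9) <= 1
        assert abs(counts.mean() - 9) <= 1.5
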