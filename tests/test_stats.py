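import numpy as np
import pytest
from _oracles import (
    anova_2x2_hand,
    ks_statistic_exhaustive,
    rank_sum_exact_p,
    signed_rank_exact_p,
)

from ivmquant import (
    ValidationError,
    curve_anova,
    ks_compare,
    paired_group_test,
    pixel_pdf,
    unpaired_group_tests,
)
from ivmquant.kinetics import KineticCurve

# ---------------------------------------------------------------- pixel PDFs


class TestPixelPDF:
    def test_hand_histogram(self):
        # pixels (0,0,1,1) on edges (0, 0.5, 1.5): densities 1.0 and 0.5
        pdf = pixel_pdf([np.array([[0.0, 0.0], [1.0, 1.0]])], bins=np.array([0, 0.5, 1.5]))
        np.testing.assert_allclose(pdf.density, [1.0, 0.5])
        widths = np.diff(pdf.bin_edges)
        assert (pdf.density * widths).sum() == pytest.approx(1.0)

    def test_unit_integral_for_random_pools(self, rng):
        for _ in range(5):
            imgs = [rng.gamma(2.0, 3.0, size=(30, 30)) for _ in range(3)]
            pdf = pixel_pdf(imgs, bins=50)
            assert (pdf.density * np.diff(pdf.bin_edges)).sum() == pytest.approx(1.0)
            assert pdf.n_pixels == 3 * 900

    def test_pooling_proportionality(self, rng):
        img = rng.random((20, 20))
        edges = np.linspace(0, 1, 21)
        one = pixel_pdf([img], bins=edges)
        two = pixel_pdf([img, img], bins=edges)
        np.testing.assert_allclose(one.density, two.density)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValidationError):
            pixel_pdf([])

    def test_median_tracks_distribution(self, rng):
        pdf = pixel_pdf([rng.normal(10, 1, (100, 100))], bins=200, clip_negative=False)
        assert pdf.median == pytest.approx(10.0, abs=0.1)


# ---------------------------------------------------------------- KS


class TestKS:
    def test_identical_samples(self):
        res = ks_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.direction == "none"

    def test_statistic_matches_exhaustive_ecdf(self, rng):
        for _ in range(10):
            a = rng.normal(size=rng.integers(3, 12))
            b = rng.normal(size=rng.integers(3, 12))
            res = ks_compare(a, b)
            assert res.statistic == pytest.approx(ks_statistic_exhaustive(a, b))

    def test_disjoint_supports(self):
        res = ks_compare([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert res.statistic == 1.0
        assert res.direction == "right-shifted"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_compare([], [1.0])


# ---------------------------------------------------------------- paired


class TestSignedRank:
    def test_n4_one_directional(self):
        day0 = [10.0, 12.0, 9.0, 15.0]
        day4 = [4.0, 5.0, 3.0, 6.0]
        res = paired_group_test(day0, day4)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.125)
        assert res.direction == "decrease"

    def test_n5_one_directional(self):
        day0 = np.array([10.0, 12.0, 9.0, 15.0, 11.0])
        res = paired_group_test(day0, day0 - np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert res.p_value == pytest.approx(2 / 32)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_matches_enumeration_oracle(self, n, rng):
        for _ in range(5):
            day0 = rng.normal(10, 2, n)
            day4 = day0 + rng.normal(0, 2, n)
            res = paired_group_test(day0, day4)
            assert res.p_value == pytest.approx(signed_rank_exact_p(day0, day4))

    def test_symmetric_differences_null(self, rng):
        day0 = np.arange(1.0, 9.0)
        day4 = day0 + np.array([1, -1, 2, -2, 3, -3, 4, -4], dtype=float) * 0.99
        res = paired_group_test(day0, day4)
        assert res.p_value > 0.8

    def test_all_zero_differences_degenerate(self):
        res = paired_group_test([1.0, 2.0], [1.0, 2.0])
        assert res.direction == "degenerate" and res.p_value == 1.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            paired_group_test([1.0, 2.0], [1.0])


# ---------------------------------------------------------------- unpaired


class TestRankSum:
    def test_three_groups_bonferroni_multiplier(self, rng):
        groups = {g: list(rng.normal(size=4)) for g in "ABC"}
        results = unpaired_group_tests(groups)
        assert len(results) == 3
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_value * 3))

    def test_separated_groups_exact_p(self):
        results = unpaired_group_tests(
            {"a": [1.0, 2.0, 3.0], "b": [10.0, 11.0, 12.0]}
        )
        assert results[0].p_value == pytest.approx(0.1)

    def test_identical_groups_p_near_one(self):
        res = unpaired_group_tests({"a": [1.0, 2.0, 3.0, 4.0], "b": [1.1, 2.1, 3.1, 4.1]})
        assert res[0].p_value > 0.5

    @pytest.mark.parametrize("n,m", [(3, 3), (4, 4), (5, 6), (8, 8)])
    def test_matches_enumeration_oracle(self, n, m, rng):
        for _ in range(5):
            a = rng.normal(0, 1, n)
            b = rng.normal(0.5, 1, m)
            res = unpaired_group_tests({"a": list(a), "b": list(b)}, correction="none")[0]
            assert res.p_value == pytest.approx(rank_sum_exact_p(a, b))

    def test_singleton_group_rejected(self):
        with pytest.raises(ValidationError):
            unpaired_group_tests({"a": [1.0], "b": [1.0, 2.0]})


# ---------------------------------------------------------------- ANOVA


class TestCurveAnova:
    def _curves(self, y):
        # y[a][b][r]: group a, time b, replicate r
        times = [0.0, 60.0]
        return {
            g: [
                KineticCurve(times, [y[a][0][r], y[a][1][r]], animal_id=f"{g}{r}")
                for r in range(len(y[a][0]))
            ]
            for a, g in enumerate("AB")
        }

    def test_matches_hand_computed_sums_of_squares(self, rng):
        y = rng.normal(10, 2, size=(2, 2, 2))
        table = curve_anova(self._curves(y))
        hand = anova_2x2_hand(y)
        for term, f in hand.items():
            assert table.loc[term, "F"] == pytest.approx(f)

    def test_constant_offset_adds_group_effect_only(self, rng):
        base = rng.normal(10, 1, size=(2, 2, 3))
        y_off = base.copy()
        y_off[1] += 5.0
        t0 = curve_anova(self._curves(base))
        t1 = curve_anova(self._curves(y_off))
        assert t1.loc["group", "F"] > t0.loc["group", "F"]

    def test_mismatched_grids_rejected(self):
        curves = {
            "A": [KineticCurve([0.0, 60.0], [1.0, 2.0])] * 2,
            "B": [KineticCurve([0.0, 50.0], [1.0, 2.0])] * 2,
        }
        with pytest.raises(ValidationError):
            curve_anova(curves)

    def test_null_type_one_error_calibrated(self, rng):
        # identical group means: group-factor p < 0.05 in ~5% of replicates
        times = np.arange(0, 85, 5.0)
        shape = 100 * (1 - np.exp(-times / 10.0))
        rejections = 0
        n_reps = 400
        for _ in range(n_reps):
            curves = {
                g: [
                    KineticCurve(times, shape + rng.normal(0, 5, times.size))
                    for _ in range(4)
                ]
                for g in "AB"
            }
            if curve_anova(curves).loc["group", "PR(>F)"] < 0.05:
                rejections += 1
        rate = rejections / n_reps
        assert 0.02 <= rate <= 0.08
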