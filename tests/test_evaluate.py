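import numpy as np
import pytest

from uterosnake import BinaryMask, PairedSeries, generate
from uterosnake.evaluate import (
    agreement_report,
    area_error,
    bland_altman,
    dice_jaccard,
    linear_regression,
    parameter_sweep,
    similarity_report,
)
from uterosnake.image_io import ValidationError
from uterosnake.snake import SnakeParams

from conftest import disk_spec


def mask_of(total=100, on=None):
    m = np.zeros(total, dtype=bool)
    if on is not None:
        m[on] = True
    return BinaryMask(m.reshape(10, total // 10))


class TestDiceJaccard:
    def test_identity(self):
        a = mask_of(on=slice(0, 10))
        assert dice_jaccard(a, a) == (100.0, 100.0)

    def test_disjoint(self):
        a = mask_of(on=slice(0, 10))
        b = mask_of(on=slice(50, 60))
        assert dice_jaccard(a, b) == (0.0, 0.0)

    def test_partial_overlap_pixel_counts(self):
        # |A| = |B| = 10, |A ∩ B| = 8 -> dice 16/20, jaccard 8/12
        a = mask_of(on=slice(0, 10))
        b = mask_of(on=slice(2, 12))
        d, j = dice_jaccard(a, b)
        assert d == pytest.approx(80.0)
        assert j == pytest.approx(100 * 8 / 12, abs=5e-3)

    def test_both_empty_rejected(self):
        with pytest.raises(ValidationError):
            dice_jaccard(mask_of(), mask_of())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            dice_jaccard(mask_of(), BinaryMask(np.zeros((5, 5), bool)))

    @pytest.mark.parametrize("seed", range(10))
    def test_dice_dominates_jaccard(self, seed):
        rng = np.random.default_rng(seed)
        a = BinaryMask(rng.random((20, 20)) < 0.4)
        b = BinaryMask(rng.random((20, 20)) < 0.4)
        if not (a.pixels.any() or b.pixels.any()):
            return
        d, j = dice_jaccard(a, b)
        assert d >= j
        # equality only at the extremes
        if 0 < j < 100:
            assert d > j
        # pixel-count oracle
        inter = (a.pixels & b.pixels).sum()
        union = (a.pixels | b.pixels).sum()
        assert j == pytest.approx(100 * inter / union)
        assert d == pytest.approx(200 * inter / (a.area() + b.area()))


class TestLinearRegression:
    def test_identity_series(self):
        s = PairedSeries([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        slope, intercept, r, rmse = linear_regression(s)
        assert (slope, intercept, r, rmse) == pytest.approx((1, 0, 1, 0))

    def test_exact_line_slope_two(self):
        s = PairedSeries([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        slope, intercept, r, _ = linear_regression(s)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r == pytest.approx(1.0)

    def test_rmse_is_agreement_error_not_residual(self):
        # constant offset: perfect fit (zero residual) but nonzero RMSE
        manual = np.array([1.0, 2.0, 3.0, 4.0])
        s = PairedSeries(manual + 5.0, manual)
        _, _, _, rmse = linear_regression(s)
        assert rmse == pytest.approx(5.0)

    def test_recovers_seeded_slope(self, rng):
        manual = rng.uniform(0, 10, size=50)
        auto = 0.85 * manual + rng.normal(0, 0.1, size=50)
        slope, _, r, _ = linear_regression(PairedSeries(auto, manual))
        assert slope == pytest.approx(0.85, abs=0.05)
        assert r > 0.99

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            linear_regression(PairedSeries([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]))


class TestBlandAltman:
    def test_zero_differences(self):
        s = PairedSeries([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        bias, lo, hi, r95 = bland_altman(s)
        assert (bias, lo, hi, r95) == pytest.approx((0, 0, 0, 100))

    def test_alternating_unit_differences(self):
        manual = np.zeros(4)
        s = PairedSeries([1.0, -1.0, 1.0, -1.0], manual)
        bias, lo, hi, r95 = bland_altman(s)
        sd = 2 / np.sqrt(3)  # sample SD of (+1,-1,+1,-1)
        assert bias == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * sd, abs=1e-4)
        assert lo == pytest.approx(-1.96 * sd, abs=1e-4)
        assert r95 == 100.0

    def test_single_outlier_case(self):
        # d = (0,0,0,0,10): bias 2, sample SD sqrt(20); the outlier at 10
        # falls inside bias + 1.96*SD = 10.765 -> all points within limits
        s = PairedSeries([0.0, 0.0, 0.0, 0.0, 10.0], np.zeros(5))
        bias, lo, hi, r95 = bland_altman(s)
        assert bias == pytest.approx(2.0)
        assert hi == pytest.approx(2 + 1.96 * np.sqrt(20), abs=1e-6)
        assert (10.0 <= hi) and r95 == 100.0

    def test_gaussian_coverage_near_95(self):
        rng = np.random.default_rng(42)
        d = rng.normal(0, 1, size=10_000)
        s = PairedSeries(d, np.zeros_like(d))
        *_, r95 = bland_altman(s)
        assert 94.0 <= r95 <= 96.0

    def test_report_invariants(self, rng):
        manual = rng.uniform(0, 50, size=30)
        auto = manual + rng.normal(0.5, 2.0, size=30)
        rep = agreement_report(PairedSeries(auto, manual, "ua"))
        assert rep.loa_low <= rep.bias <= rep.loa_high
        assert rep.bias_ci_low <= rep.bias <= rep.bias_ci_high
        assert rep.loa_low <= rep.bias_ci_low and rep.bias_ci_high <= rep.loa_high
        assert -1 <= rep.r <= 1
        assert 0 <= rep.r95 <= 100


class TestAreaError:
    def test_equal_areas_even_if_displaced(self):
        a = mask_of(on=slice(0, 10))
        b = mask_of(on=slice(50, 60))
        assert area_error(a, b) == 0.0

    def test_known_difference(self):
        a = BinaryMask(np.zeros((256, 256), bool))
        b = BinaryMask(np.zeros((256, 256), bool))
        a.pixels.flat[:655] = True
        assert area_error(a, b) == pytest.approx(100 * 655 / 65536)

    def test_empty_vs_full_is_100(self):
        a = BinaryMask(np.zeros((16, 16), bool))
        b = BinaryMask(np.ones((16, 16), bool))
        assert area_error(a, b) == 100.0


class TestSimilarityReport:
    def test_per_case_and_summary(self):
        a = mask_of(on=slice(0, 10))
        b = mask_of(on=slice(2, 12))
        rep = similarity_report([(a, a), (a, b)])
        assert rep.per_case[0] == (100.0, 100.0)
        assert rep.dice == pytest.approx((100 + 80) / 2)
        assert rep.max_deviation_dice == pytest.approx(10.0)


@pytest.fixture(scope="module")
def tiny_phantom_set():
    cases = [generate(disk_spec(radius=18, seed=s)) for s in (1, 2)]
    return [(c.image, c.seeds, c.truth_mask) for c in cases]


@pytest.fixture(scope="module")
def fast_params():
    return SnakeParams(coarse_sigmas=(4.0,), max_iters=300)


class TestParameterSweep:
    def test_table_shape_and_finite(self, tiny_phantom_set, fast_params):
        table = parameter_sweep(
            tiny_phantom_set, alphas=[0.5, 1.23, 2.0], betas=[0.5, 0.91],
            params=fast_params,
        )
        assert len(table) == 5
        assert set(table["parameter"]) == {"alpha", "beta"}
        assert np.isfinite(table["mean_area_error"]).all()

    def test_duplicate_phantom_same_mean(self, tiny_phantom_set, fast_params):
        one = parameter_sweep(tiny_phantom_set[:1], [1.23], [], fast_params)
        two = parameter_sweep(tiny_phantom_set[:1] * 2, [1.23], [], fast_params)
        assert one["mean_area_error"][0] == pytest.approx(two["mean_area_error"][0])

    def test_deterministic(self, tiny_phantom_set, fast_params):
        t1 = parameter_sweep(tiny_phantom_set, [0.8, 1.23], [0.91], fast_params)
        t2 = parameter_sweep(tiny_phantom_set, [0.8, 1.23], [0.91], fast_params)
        assert t1.equals(t2)

    def test_empty_inputs_rejected(self, fast_params):
        with pytest.raises(ValidationError):
            parameter_sweep([], [1.0], [1.0], fast_params)
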