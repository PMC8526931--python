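import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from tissueatlas import (
    MaskMap,
    StatMap,
    content_mask,
    distribution_summary,
    gaussian_population,
    sample_kurtosis,
    sample_skewness,
    shapiro_wilk_p,
    stat_map,
    violin_export,
)
from tissueatlas.io import PopulationStack

finite_samples = arrays(
    np.float64,
    st.integers(3, 200),
    elements=st.floats(-1e3, 1e3, allow_nan=False),
)


def moment_oracle(x):
    """Direct central-moment summation (independent of the implementation)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    mu = sum(x) / n
    m2 = sum((xi - mu) ** 2 for xi in x) / n
    if m2 == 0:
        return 0.0, 0.0
    m3 = sum((xi - mu) ** 3 for xi in x) / n
    m4 = sum((xi - mu) ** 4 for xi in x) / n
    return m3 / m2**1.5, m4 / m2**2 - 3.0


class TestMoments:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([1, 2, 3], 0.0),
            ([0, 0, 1], 1 / np.sqrt(2)),
            ([0, 1, 1], -1 / np.sqrt(2)),
            ([5, 5, 5, 5], 0.0),
        ],
    )
    def test_skewness_hand_cases(self, x, expected):
        assert sample_skewness(x) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "x, expected",
        [
            ([1, 2, 3], -1.5),
            ([0, 1] * 10, -2.0),  # symmetric two-point mass
            ([7, 7, 7], 0.0),  # constant-input convention
        ],
    )
    def test_kurtosis_hand_cases(self, x, expected):
        assert sample_kurtosis(x) == pytest.approx(expected, abs=1e-12)

    def test_gaussian_limit_near_zero(self, rng):
        x = rng.standard_normal(100_000)
        assert sample_skewness(x) == pytest.approx(0.0, abs=0.05)
        assert sample_kurtosis(x) == pytest.approx(0.0, abs=0.05)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(finite_samples)
    def test_matches_bruteforce_oracle(self, x):
        # near-constant samples are dominated by cancellation noise in
        # both routes; the constant case has its own convention test
        assume(np.ptp(x) > 1e-8 * (1 + np.abs(x).max()))
        s_ref, k_ref = moment_oracle(x)
        scale = max(1.0, abs(s_ref), abs(k_ref))
        assert abs(sample_skewness(x) - s_ref) <= 1e-9 * scale
        assert abs(sample_kurtosis(x) - k_ref) <= 1e-9 * scale

    def test_matches_scipy_biased_estimators(self, rng):
        """scipy's n-denominator (biased) skew/kurtosis is the cross-check."""
        for _ in range(50):
            x = rng.gamma(2.0, size=rng.integers(3, 1000))
            assert sample_skewness(x) == pytest.approx(stats.skew(x), abs=1e-10)
            assert sample_kurtosis(x) == pytest.approx(
                stats.kurtosis(x, fisher=True, bias=True), abs=1e-10
            )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        finite_samples,
        st.floats(0.1, 50),
        st.floats(-100, 100),
    )
    def test_affine_invariance_and_sign_flip(self, x, a, b):
        assume(np.ptp(x) > 1e-6 * (1 + np.abs(x).max() + abs(b) / a))
        s0, k0 = sample_skewness(x), sample_kurtosis(x)
        tol = 1e-6 * max(1.0, abs(s0), abs(k0))
        assert sample_skewness(a * x + b) == pytest.approx(s0, abs=tol)
        assert sample_kurtosis(a * x + b) == pytest.approx(k0, abs=tol)
        assert sample_skewness(-a * x + b) == pytest.approx(-s0, abs=tol)
        assert sample_kurtosis(-a * x + b) == pytest.approx(k0, abs=tol)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(finite_samples)
    def test_kurtosis_skewness_bound(self, x):
        # K >= S^2 - 2 holds for every non-degenerate sample
        assume(np.ptp(x) > 1e-8 * (1 + np.abs(x).max()))
        s, k = sample_skewness(x), sample_kurtosis(x)
        assert k >= s * s - 2 - 1e-6 * max(1.0, s * s)

    def test_permutation_invariance(self, rng):
        x = rng.random(50)
        perm = rng.permutation(x)
        assert sample_skewness(perm) == pytest.approx(sample_skewness(x), rel=1e-12)
        assert sample_kurtosis(perm) == pytest.approx(sample_kurtosis(x), rel=1e-12)

    def test_too_short_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            sample_skewness([1.0, 2.0])


class TestShapiroWilk:
    def test_constant_input_gives_nan_sentinel(self):
        assert np.isnan(shapiro_wilk_p(np.full(10, 0.3)))

    def test_n_out_of_range(self, rng):
        with pytest.raises(ValueError):
            shapiro_wilk_p(rng.random(2))
        with pytest.raises(ValueError):
            shapiro_wilk_p(rng.random(5001))

    def test_type_one_error_calibrated(self, rng):
        # i.i.d. Gaussian voxels, n=96: rejection rate should sit near 5%
        x = rng.normal(size=(96, 2000))
        ps = np.array([shapiro_wilk_p(x[:, i]) for i in range(x.shape[1])])
        assert 0.025 <= float((ps < 0.05).mean()) <= 0.075

    def test_power_against_exponential(self, rng):
        rejected = sum(
            shapiro_wilk_p(rng.exponential(size=96)) < 0.05 for _ in range(200)
        )
        assert rejected >= 198  # >= 99% power at n=96


class TestStatMap:
    def test_symmetric_voxel_samples_give_zero_skewness(self):
        base = np.linspace(0.1, 0.9, 27).reshape(3, 3, 3)
        data = np.stack([base - 0.05, base, base + 0.05])
        stack = PopulationStack("GM", ["a", "b", "c"], data, np.eye(4))
        out = stat_map(stack, "skewness")
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_mean_of_identical_maps_is_identity(self, rng):
        base = rng.random((4, 4, 4))
        data = np.stack([base] * 3)
        stack = PopulationStack("GM", list("abc"), data, np.eye(4))
        np.testing.assert_allclose(stat_map(stack, "mean").data, base)

    def test_kurtosis_map_recovers_beta_excess_kurtosis(self, rng):
        # Beta(2,5) excess kurtosis is 3*7*(2*49 - 5*14)/(5*14*10*11) exactly
        a, b = 2.0, 5.0
        num = 6 * ((a - b) ** 2 * (a + b + 1) - a * b * (a + b + 2))
        true_k = num / (a * b * (a + b + 2) * (a + b + 3))
        data = rng.beta(a, b, size=(100, 10, 10, 10))
        stack = PopulationStack("GM", [f"s{i}" for i in range(100)], data, np.eye(4))
        med = float(np.median(stat_map(stack, "kurtosis").data))
        assert med == pytest.approx(true_k, abs=0.3)

    def test_sw_map_respects_mask(self, tiny_stack):
        mask = MaskMap(np.zeros((4, 4, 4), dtype=bool), 0.05)
        mask.data[0, 0, 0] = True
        out = stat_map(tiny_stack, "sw_p", mask=mask)
        assert np.isfinite(out.data[0, 0, 0])
        assert np.isnan(out.data[1:]).all()

    def test_unknown_statistic(self, tiny_stack):
        with pytest.raises(ValueError, match="unknown statistic"):
            stat_map(tiny_stack, "variance")

    def test_subject_permutation_invariance(self, tiny_stack, rng):
        perm = rng.permutation(tiny_stack.n)
        shuffled = PopulationStack(
            tiny_stack.tissue,
            [tiny_stack.subject_ids[i] for i in perm],
            tiny_stack.data[perm],
            tiny_stack.affine,
        )
        for statistic in ("skewness", "kurtosis", "mean"):
            np.testing.assert_allclose(
                stat_map(shuffled, statistic).data,
                stat_map(tiny_stack, statistic).data,
                atol=1e-12,
            )


class TestContentMask:
    def test_strict_inequality_at_threshold(self):
        data = np.array([0.04, 0.05, 0.051]).reshape(3, 1, 1)
        mask = content_mask(StatMap("mean", data, np.eye(4)), 0.05)
        np.testing.assert_array_equal(mask.data.ravel(), [False, False, True])

    def test_all_zero_map_warns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            mask = content_mask(StatMap("mean", np.zeros((2, 2, 2)), np.eye(4)))
        assert mask.n_voxels == 0

    def test_threshold_zero_is_positive_support(self, rng):
        data = rng.random((3, 3, 3))
        data[0] = 0.0
        mask = content_mask(StatMap("mean", data, np.eye(4)), 0.0)
        np.testing.assert_array_equal(mask.data, data > 0)

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            content_mask(StatMap("mean", np.ones((2, 2, 2)), np.eye(4)), 1.5)


class TestSummaryAndViolin:
    def test_single_voxel_mask_medians(self, rng):
        shape = (3, 3, 3)
        maps = {
            "skewness": StatMap("skewness", rng.random(shape), np.eye(4)),
            "kurtosis": StatMap("kurtosis", rng.random(shape), np.eye(4)),
        }
        mask = MaskMap(np.zeros(shape, dtype=bool), 0.05)
        mask.data[1, 1, 1] = True
        df = distribution_summary(maps, mask, label="All", tissue="GM")
        assert df.loc[0, "median_skewness"] == maps["skewness"].data[1, 1, 1]
        assert df.loc[0, "median_kurtosis"] == maps["kurtosis"].data[1, 1, 1]

    def test_empty_mask_rejected(self):
        mask = MaskMap(np.zeros((2, 2, 2), dtype=bool), 0.05)
        with pytest.raises(ValueError, match="empty mask"):
            distribution_summary({}, mask)

    def test_violin_export_multiset_roundtrip(self, tmp_path, rng):
        data = rng.random((4, 4, 4))
        mask = MaskMap(rng.random((4, 4, 4)) > 0.4, 0.4)
        sm = StatMap("skewness", data, np.eye(4))
        path = tmp_path / "violin.tsv"
        values = violin_export(sm, mask, path=path)
        assert len(values) == mask.n_voxels
        import pandas as pd

        back = pd.read_csv(path, sep="\t", float_precision="round_trip")[
            "value"
        ].to_numpy()
        np.testing.assert_array_equal(np.sort(back), np.sort(values))

    def test_sw_calibration_on_gaussian_population(self):
        stack = gaussian_population(96, 2000, seed=5)
        mask = MaskMap(np.ones(stack.grid_shape, dtype=bool), 0.0)
        sw = stat_map(stack, "sw_p", mask=mask)
        frac = float((sw.data[mask.data] < 0.05).mean())
        assert 0.025 <= frac <= 0.075
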