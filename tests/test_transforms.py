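"""Score-transform unit and property tests.

The independent oracle for the one-sided transforms is the quantile form:
zeta(z) must equal the standard-normal quantile of (1 + Phi(z)) / 2, i.e.
the fold of the two-sided score onto the positive axis.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize, special, stats

import retestkit as rk
from retestkit.transforms import (
    DegenerateDataError,
    InsufficientDataError,
    read_normalization_models,
    write_normalization_models,
)


def quantile_oracle(z):
    """Independent closed form: Phi^-1((1 + Phi(z)) / 2).

    Evaluated as isf(sf(z) / 2) — the same quantile, but computed through
    the survival function so the upper tail keeps full precision.
    """
    return stats.norm.isf(stats.norm.sf(z) / 2.0)


class TestOneSidedTransforms:
    def test_matches_quantile_oracle_on_grid(self):
        z = np.linspace(-6, 6, 2001)
        np.testing.assert_allclose(
            rk.zeta_transform(z), quantile_oracle(z), atol=1e-10, rtol=0
        )
        np.testing.assert_allclose(
            rk.task_score(z), quantile_oracle(z), atol=1e-10, rtol=0
        )

    @given(st.floats(min_value=-6, max_value=6))
    def test_matches_quantile_oracle_pointwise(self, z):
        assert rk.zeta_transform(z) == pytest.approx(
            quantile_oracle(z), abs=1e-10
        )

    def test_known_values(self):
        # zeta(0) is the 75th percentile of the standard normal
        assert rk.zeta_transform(0.0) == pytest.approx(0.674489750196, abs=1e-9)
        # brute-force root-find on erfc(q/sqrt(2)) = 0.5*erfc(1.64/sqrt(2))
        target = 0.5 * special.erfc(1.64 / np.sqrt(2))
        q = optimize.brentq(
            lambda x: special.erfc(x / np.sqrt(2)) - target, 0, 10, xtol=1e-13
        )
        assert rk.zeta_transform(1.64) == pytest.approx(q, abs=1e-9)
        assert q == pytest.approx(1.955, abs=1e-3)

    def test_lower_asymptote_and_monotonicity(self):
        # below z ~ -8 the folded tail mass is under double-precision
        # resolution of 1, so the mapping saturates at 0 from above
        z = np.linspace(-7, 8, 500)
        out = rk.zeta_transform(z)
        assert np.all(out > 0)
        assert np.all(np.diff(out) > 0)
        assert rk.zeta_transform(-7.0) < 1e-11

    def test_nonfinite_input_rejected(self):
        for bad in (np.nan, np.inf, -np.inf):
            with pytest.raises(ValueError):
                rk.zeta_transform(bad)
            with pytest.raises(ValueError):
                rk.task_score(bad)


class TestDistances:
    @pytest.mark.parametrize(
        "z, zeta, expected",
        [
            ([3, 4], [], 5.0),
            ([0, 0, 0], [0, 0], 0.0),
            ([1, 2], [2], 3.0),
        ],
    )
    def test_rss_examples(self, z, zeta, expected):
        assert rk.rss_distance(z, zeta) == pytest.approx(expected)

    def test_rss_drops_missing_components(self):
        assert rk.rss_distance([3.0, np.nan], [4.0]) == pytest.approx(5.0)

    def test_rss_all_missing_is_error(self):
        with pytest.raises(InsufficientDataError):
            rk.rss_distance([np.nan], [np.nan])
        with pytest.raises(InsufficientDataError):
            rk.rss_distance([], [])

    @given(
        st.lists(st.floats(-50, 50), max_size=8),
        st.lists(st.floats(0, 50), max_size=8),
    )
    def test_rss_squared_matches_loop_oracle(self, z, zeta):
        total = 0.0
        for v in list(z) + list(zeta):
            total += v * v
        if not z and not zeta:
            return
        assert rk.rss_distance(z, zeta) ** 2 == pytest.approx(total, abs=1e-9)

    def test_mahalanobis_identity_equals_rss(self, rng):
        z = rng.normal(size=5)
        assert rk.mahalanobis_distance(z, np.eye(5)) == pytest.approx(
            rk.rss_distance(z), rel=1e-6
        )

    def test_mahalanobis_zero_vector(self):
        assert rk.mahalanobis_distance([0, 0, 0], np.eye(3)) == 0.0

    def test_mahalanobis_correlated_2d_hand_oracle(self):
        # Sigma = [[1, .5], [.5, 1]]; inverse = [[4/3, -2/3], [-2/3, 4/3]]
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        z = np.array([1.0, 1.0])
        expected = np.sqrt(4 / 3 - 2 / 3 - 2 / 3 + 4 / 3)
        assert rk.mahalanobis_distance(z, cov) == pytest.approx(
            expected, rel=1e-6
        )

    def test_mahalanobis_shape_mismatch(self):
        with pytest.raises(ValueError):
            rk.mahalanobis_distance([1.0, 2.0], np.eye(3))

    def test_mahalanobis_singular_covariance_regularized(self):
        cov = np.ones((3, 3))  # rank 1
        d = rk.mahalanobis_distance([1.0, -1.0, 0.0], cov)
        assert np.isfinite(d) and d >= 0


class TestFitNormalization:
    def test_gross_outlier_trimmed(self, rng):
        values = np.append(rng.standard_normal(10_000), 8.0)
        model = rk.fit_normalization(values)
        assert model.n_outliers_trimmed >= 1
        z = model.transform(values)
        retained = z[np.abs(z) <= model.z_outlier_threshold]
        assert np.mean(retained) == pytest.approx(0.0, abs=0.02)
        assert np.std(retained, ddof=1) == pytest.approx(1.0, abs=0.02)
        assert model.transform(8.0) > model.z_outlier_threshold

    def test_lognormal_deskewed(self, rng):
        values = np.exp(rng.standard_normal(10_000))
        model = rk.fit_normalization(values)
        # Box-Cox lambda -> 0 recovers the log for log-normal data
        assert abs(model.box_cox_lambda) < 0.1
        z = model.transform(values)
        z = z[np.abs(z) <= model.z_outlier_threshold]
        assert abs(stats.skew(z)) < 0.1

    def test_standard_normal_nearly_untouched(self, rng):
        values = rng.standard_normal(10_000)
        model = rk.fit_normalization(values)
        # expected |Z| > 3.29 mass of the normal is ~0.1%
        assert model.n_outliers_trimmed <= 0.003 * values.size

    def test_insufficient_and_degenerate_inputs(self):
        with pytest.raises(InsufficientDataError):
            rk.fit_normalization(np.arange(9.0))
        with pytest.raises(DegenerateDataError):
            rk.fit_normalization(np.full(50, 3.14))

    def test_refit_on_own_output_is_nearly_identity(self, rng):
        """Refitting on the standardized retained output is ~ a no-op.

        The second fit should trim essentially nothing and its composed
        transform should reproduce the standardized values up to the small
        finite-sample wobble of the Box-Cox lambda estimate.
        """
        values = np.exp(rng.standard_normal(10_000))
        first = rk.fit_normalization(values)
        z = first.transform(values)
        z = z[np.abs(z) <= first.z_outlier_threshold]
        second = rk.fit_normalization(z)
        assert second.n_outliers_trimmed <= 0.003 * z.size
        z2 = second.transform(z)
        keep = np.abs(z2) <= second.z_outlier_threshold
        assert np.mean(z2[keep]) == pytest.approx(0.0, abs=1e-6)
        assert np.std(z2[keep], ddof=1) == pytest.approx(1.0, abs=1e-6)
        assert np.max(np.abs(z2 - z)) < 0.1

    def test_positivity_shift_recorded(self):
        values = np.linspace(-5, 5, 200)
        model = rk.fit_normalization(values)
        assert model.shift == pytest.approx(6.0)


class TestZTaskScore:
    def test_reference_median_maps_near_zero(self, rng):
        ref = np.exp(rng.standard_normal(10_000))  # skewed distances
        value = float(np.median(ref))
        assert abs(rk.z_task_score(ref, value)) < 0.05

    def test_monotone_outside_reference(self, rng):
        ref = np.abs(rng.standard_normal(500)) + 0.1
        assert rk.z_task_score(ref, ref.max() * 2) > 0
        assert rk.z_task_score(ref, ref.min() / 2) < 0


class TestTaskScoreCI:
    def test_unit_ci_widths_at_zero(self):
        res = rk.task_score_ci(0.0, 1.0)
        oracle = quantile_oracle
        assert res.task_score == pytest.approx(oracle(0.0), abs=1e-10)
        assert res.upper_bound - res.task_score == pytest.approx(
            oracle(1.0) - oracle(0.0), abs=1e-10
        )
        assert res.upper_bound - res.task_score == pytest.approx(0.735, abs=1e-3)
        assert res.task_score - res.lower_bound == pytest.approx(0.474, abs=1e-3)

    def test_asymmetry_and_convergence_on_grid(self):
        ci = 1.0
        z_grid = np.linspace(-4, 4, 161)
        upper = np.array(
            [rk.task_score_ci(z, ci).upper_bound - rk.task_score(z) for z in z_grid]
        )
        lower = np.array(
            [rk.task_score(z) - rk.task_score_ci(z, ci).lower_bound for z in z_grid]
        )
        assert np.all(upper >= lower - 1e-12)
        assert np.all(np.diff(upper) > 0)
        assert np.all(np.diff(lower) > 0)
        assert np.all(upper < ci)
        assert np.all(lower < ci)
        # both distances approach the two-sided ci (O(1/z) convergence)
        far = rk.task_score_ci(30.0, ci)
        assert far.upper_bound - far.task_score == pytest.approx(ci, abs=1e-3)
        assert far.task_score - far.lower_bound == pytest.approx(ci, abs=1e-3)

    @given(st.floats(-6, 6))
    def test_bounds_bracket_point_and_stay_positive(self, z):
        res = rk.task_score_ci(z, 0.8)
        assert 0 < res.lower_bound <= res.task_score <= res.upper_bound

    def test_invalid_ci_rejected(self):
        for bad in (0.0, -1.0, np.nan):
            with pytest.raises(ValueError):
                rk.task_score_ci(0.0, bad)


def test_normalization_model_round_trip(tmp_path, rng):
    models = {
        "rt": rk.fit_normalization(np.exp(rng.standard_normal(200))),
        "plr": rk.fit_normalization(rng.standard_normal(200) + 5),
    }
    path = tmp_path / "models.txt"
    write_normalization_models(models, path)
    loaded = read_normalization_models(path)
    assert set(loaded) == {"rt", "plr"}
    probe = np.linspace(0.5, 3.0, 7)
    for name in models:
        np.testing.assert_allclose(
            loaded[name].transform(probe), models[name].transform(probe)
        )
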