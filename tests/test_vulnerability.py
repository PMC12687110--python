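import numpy as np
import pandas as pd
import pytest

from grainvuln import (
    ExposurePair,
    InsufficientDataError,
    InvalidArgumentError,
    NicheModel,
    evaluate_pixels,
    mahalanobis_sq,
    partition,
    species_evs,
    suitability,
    suitability_drop,
    vulnerability_score,
)


def interaction_closed_form_2d(x, mu, sigma):
    """Closed-form 2-D interaction term of the squared Mahalanobis distance.

    Independent oracle: [ρ²(u−v)² + 2ρuv(ρ−1)] / (1−ρ²) with u, v the
    standardized offsets and 1−ρ² the determinant of the correlation matrix.
    """
    sx, sy = np.sqrt(sigma[0, 0]), np.sqrt(sigma[1, 1])
    rho = sigma[0, 1] / (sx * sy)
    u = (x[0] - mu[0]) / sx
    v = (x[1] - mu[1]) / sy
    det = 1.0 - rho**2
    return (rho**2 * (u - v) ** 2 + 2 * rho * u * v * (rho - 1)) / det


def random_niche(rng, n):
    a = rng.normal(size=(n, n))
    sigma = a @ a.T + n * np.eye(n)
    return NicheModel(rng.normal(size=n), sigma, [f"v{i}" for i in range(n)], 50)


class TestMahalanobisSq:
    def test_zero_at_center(self, correlated_niche_2d):
        assert mahalanobis_sq(correlated_niche_2d.mu, correlated_niche_2d) == 0.0

    def test_identity_sigma_reduces_to_squared_euclidean(self):
        niche = NicheModel([1.0, -1.0], np.eye(2), ["a", "b"], 10)
        assert mahalanobis_sq(np.array([4.0, 3.0]), niche) == pytest.approx(25.0)

    def test_correlated_standardized_offset(self, correlated_niche_2d):
        # σx=σy=1, ρ=0.5, offsets (1,0): (u²+v²−2ρuv)/(1−ρ²) = 1/0.75 = 4/3
        assert mahalanobis_sq(np.array([1.0, 0.0]), correlated_niche_2d) == pytest.approx(4 / 3)

    def test_vectorised_matches_scalar(self, rng, correlated_niche_2d):
        xs = rng.normal(size=(20, 2))
        batch = mahalanobis_sq(xs, correlated_niche_2d)
        singles = [mahalanobis_sq(x, correlated_niche_2d) for x in xs]
        np.testing.assert_allclose(batch, singles, atol=1e-12)

    def test_chi_square_law_in_two_dimensions(self):
        # P(MD² ≤ q) = 1 − e^{−q/2} for bivariate-normal data
        rng = np.random.default_rng(777)
        niche = NicheModel(
            [15.0, 100.0], [[4.0, 6.0], [6.0, 225.0]],
            ["temperature", "precipitation"], 100,
        )
        draws = rng.multivariate_normal(niche.mu, niche.sigma, size=100_000)
        md2 = mahalanobis_sq(draws, niche)
        for q in (0.45, 1.0, 2.0):
            p = 1.0 - np.exp(-q / 2.0)
            se = np.sqrt(p * (1 - p) / len(md2))
            assert abs(np.mean(md2 <= q) - p) < 3 * se


class TestVulnerabilityScore:
    def test_population_at_center_shift_one(self, scalar_niche_1d):
        pair = ExposurePair([0.0], [1.0])
        assert vulnerability_score(pair, scalar_niche_1d) == pytest.approx(1.0)

    def test_population_two_sigma_out_shift_one_away(self, scalar_niche_1d):
        pair = ExposurePair([2.0], [3.0])
        assert vulnerability_score(pair, scalar_niche_1d) == pytest.approx(5.0)

    def test_no_exposure_scores_zero(self, correlated_niche_2d, rng):
        x = rng.normal(size=2)
        assert vulnerability_score(ExposurePair(x, x), correlated_niche_2d) == 0.0

    def test_antisymmetry_under_time_swap(self, rng, correlated_niche_2d):
        for _ in range(20):
            x0, x1 = rng.normal(size=2), rng.normal(size=2)
            fwd = vulnerability_score(ExposurePair(x0, x1), correlated_niche_2d)
            rev = vulnerability_score(ExposurePair(x1, x0), correlated_niche_2d)
            assert fwd == pytest.approx(-rev, abs=1e-12)

    def test_affine_invariance(self, rng):
        niche = random_niche(rng, 3)
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        b = rng.normal(size=3)
        mapped = NicheModel(A @ niche.mu + b, A @ niche.sigma @ A.T,
                            niche.variables, niche.n_records)
        for _ in range(10):
            x0, x1 = rng.normal(size=3), rng.normal(size=3)
            vs = vulnerability_score(ExposurePair(x0, x1), niche)
            vs_mapped = vulnerability_score(
                ExposurePair(A @ x0 + b, A @ x1 + b), mapped
            )
            assert vs_mapped == pytest.approx(vs, abs=1e-9)


class TestPartition:
    def test_diagonal_sigma_has_no_interaction(self, rng):
        niche = NicheModel([1.0, 2.0], np.diag([4.0, 9.0]), ["a", "b"], 10)
        comp = partition(ExposurePair(rng.normal(size=2), rng.normal(size=2)), niche)
        assert comp.interaction == pytest.approx(0.0, abs=1e-12)
        assert comp.total == pytest.approx(comp.per_variable.sum(), abs=1e-12)

    def test_correlated_hand_computed_case(self, correlated_niche_2d):
        # t0 at μ, t1 with standardized offsets (1, 0), ρ = 0.5
        comp = partition(ExposurePair([0.0, 0.0], [1.0, 0.0]), correlated_niche_2d)
        np.testing.assert_allclose(comp.per_variable, [1.0, 0.0], atol=1e-12)
        assert comp.interaction == pytest.approx(1 / 3, abs=1e-12)
        assert comp.total == pytest.approx(4 / 3, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 3])
    def test_additivity_on_random_cases(self, n):
        rng = np.random.default_rng(n * 17)
        niche = random_niche(rng, n)
        for _ in range(1000):
            pair = ExposurePair(rng.normal(size=n), rng.normal(size=n))
            comp = partition(pair, niche)
            assert comp.total == pytest.approx(
                comp.per_variable.sum() + comp.interaction, abs=1e-9
            )
            assert comp.total == pytest.approx(comp.md2_t1 - comp.md2_t0, abs=1e-9)

    def test_residual_matches_closed_form_2d(self):
        rng = np.random.default_rng(55)
        for _ in range(1000):
            sx, sy = rng.uniform(0.5, 3.0, size=2)
            rho = rng.uniform(-0.9, 0.9)
            sigma = np.array(
                [[sx**2, rho * sx * sy], [rho * sx * sy, sy**2]]
            )
            mu = rng.normal(size=2)
            niche = NicheModel(mu, sigma, ["a", "b"], 10)
            x0, x1 = rng.normal(size=2), rng.normal(size=2)
            comp = partition(ExposurePair(x0, x1), niche)
            expected = interaction_closed_form_2d(x1, mu, sigma) - interaction_closed_form_2d(
                x0, mu, sigma
            )
            assert comp.interaction == pytest.approx(expected, abs=1e-9)

    def test_weight_is_gaussian_kernel_of_current_condition(self, correlated_niche_2d):
        comp = partition(ExposurePair([1.0, 0.0], [0.0, 0.0]), correlated_niche_2d)
        assert comp.weight == pytest.approx(np.exp(-4 / 3), abs=1e-12)

    def test_evaluate_pixels_matches_partition(self, rng, correlated_niche_2d):
        x0 = rng.normal(size=(30, 2))
        x1 = rng.normal(size=(30, 2))
        table = evaluate_pixels(x0, x1, correlated_niche_2d)
        for i in (0, 7, 29):
            comp = partition(ExposurePair(x0[i], x1[i]), correlated_niche_2d)
            assert table.loc[i, "vs_total"] == pytest.approx(comp.total, abs=1e-12)
            assert table.loc[i, "vs_temperature"] == pytest.approx(
                comp.per_variable[0], abs=1e-12
            )
            assert table.loc[i, "vs_interaction"] == pytest.approx(
                comp.interaction, abs=1e-12
            )
            assert table.loc[i, "weight"] == pytest.approx(comp.weight, abs=1e-12)


class TestSuitability:
    def test_one_at_niche_center(self, correlated_niche_2d):
        assert suitability(correlated_niche_2d.mu, correlated_niche_2d) == 1.0

    def test_known_value_at_unit_distance(self, scalar_niche_1d):
        assert suitability(np.array([1.0]), scalar_niche_1d) == pytest.approx(
            np.exp(-1.0)
        )

    def test_strictly_decreasing_along_a_ray(self, correlated_niche_2d):
        direction = np.array([0.3, 0.8])
        values = [
            suitability(correlated_niche_2d.mu + t * direction, correlated_niche_2d)
            for t in np.linspace(0, 4, 15)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_half_kernel_option(self, scalar_niche_1d):
        full = suitability(np.array([2.0]), scalar_niche_1d, kernel="full")
        half = suitability(np.array([2.0]), scalar_niche_1d, kernel="half")
        assert full == pytest.approx(np.exp(-4.0))
        assert half == pytest.approx(np.exp(-2.0))


class TestSuitabilityDrop:
    def test_chi_square_drop_values_two_dimensions(self):
        # closed form 100·(1 − e^{−vs/2}) for two dimensions
        assert suitability_drop(0.45, 2) == pytest.approx(100 * (1 - np.exp(-0.225)))
        assert round(suitability_drop(0.45, 2)) == 20
        assert suitability_drop(1.0, 2) == pytest.approx(100 * (1 - np.exp(-0.5)))
        assert suitability_drop(2.0, 2) == pytest.approx(100 * (1 - np.exp(-1.0)))
        assert round(suitability_drop(2.0, 2)) == 63

    def test_zero_vs_means_zero_drop(self):
        assert suitability_drop(0.0, 2) == 0.0

    def test_negative_vs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            suitability_drop(-0.1, 2)


class TestSpeciesEvs:
    @staticmethod
    def pixel_frame(vs, w):
        return pd.DataFrame(
            {"vs_total": vs, "vs_temperature": vs, "vs_precipitation": 0.0,
             "vs_interaction": 0.0, "weight": w, "md2_t0": 0.0, "md2_t1": vs}
        )

    def test_equal_weights_reduce_to_unweighted_mean(self):
        res = species_evs(self.pixel_frame([1.0, 2.0, 6.0], [0.4, 0.4, 0.4]), seed=0)
        assert res.evs == pytest.approx(3.0)

    def test_hand_computed_weighted_mean(self):
        res = species_evs(self.pixel_frame([1.0, 3.0, 5.0], [1.0, 1.0, 2.0]), seed=0)
        assert res.evs == pytest.approx(14 / 4)

    def test_single_pixel_zero_width_interval(self):
        res = species_evs(self.pixel_frame([2.5], [0.7]), seed=0)
        assert res.evs == res.ci_low == res.ci_high == 2.5
        assert res.n_pixels == 1

    def test_bootstrap_interval_brackets_estimate(self, rng):
        vs = rng.normal(size=200)
        w = rng.uniform(0.1, 1.0, size=200)
        res = species_evs(self.pixel_frame(vs, w), ci_reps=1000, seed=3)
        assert res.ci_low <= res.evs <= res.ci_high

    def test_components_use_same_weighting(self):
        res = species_evs(self.pixel_frame([1.0, 3.0, 5.0], [1.0, 1.0, 2.0]), seed=0)
        assert res.evs_components["vs_temperature"] == pytest.approx(14 / 4)
        assert res.evs_components["vs_interaction"] == pytest.approx(0.0)

    def test_empty_pixel_set_rejected(self):
        with pytest.raises(InsufficientDataError):
            species_evs(self.pixel_frame([], []), seed=0)

    def test_deterministic_given_seed(self, rng):
        frame = self.pixel_frame(rng.normal(size=50), rng.uniform(0.1, 1, size=50))
        a = species_evs(frame, seed=11)
        b = species_evs(frame, seed=11)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
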