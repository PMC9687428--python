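"""Embedded fuzzy c-means: centroids, memberships, label energies, coupling."""

import numpy as np
import pytest

from renalseg.fcm import (
    DegenerateInputError,
    LabelEnergy,
    coupled_step,
    fcm_objective,
    init_centroids,
    label_energy,
    static_fcm,
    update_centroids,
    update_memberships,
)
from renalseg.levelset import EvolutionParams, LevelSetField, initial_level_set, smeared_heaviside


def _two_region_image(shape=(32, 32), center=(16, 16), radius=8, hi=200.0, lo=50.0):
    rows, cols = np.indices(shape, dtype=float)
    disk = np.hypot(rows - center[0], cols - center[1]) <= radius
    return np.where(disk, hi, lo), disk


class TestInitCentroids:
    def test_constant_regions(self):
        img, disk = _two_region_image()
        field = initial_level_set((32, 32), (16, 16), 8.0)
        c_k, c_b = init_centroids(img, field)
        # seed circle matches the bright disk boundary, so means are near-pure
        assert c_k == pytest.approx(200.0, abs=10.0)
        assert c_b == pytest.approx(50.0, abs=10.0)

    def test_exact_means_with_matching_contour(self):
        img = np.where(np.arange(16)[None, :] < 8, 200.0, 50.0) * np.ones((16, 1))
        phi = np.where(np.arange(16)[None, :] < 8, 1.0, -1.0) * np.ones((16, 1))
        c_k, c_b = init_centroids(img, LevelSetField(phi, 1.5))
        assert (c_k, c_b) == (200.0, 50.0)

    def test_constant_image_degenerate(self):
        field = initial_level_set((16, 16), (8, 8), 4.0)
        with pytest.raises(DegenerateInputError):
            init_centroids(np.full((16, 16), 7.0), field)

    def test_empty_side_rejected(self):
        img, _ = _two_region_image()
        with pytest.raises(DegenerateInputError):
            init_centroids(img, LevelSetField(np.ones((32, 32)), 1.5))

    def test_checkerboard_centroids_near_half(self):
        rows, cols = np.indices((32, 32))
        img = ((rows + cols) % 2) * 100.0
        phi = np.where(cols < 16, 1.0, -1.0)
        c_k, c_b = init_centroids(img, LevelSetField(phi, 1.5))
        assert c_k == pytest.approx(50.0, abs=1e-9)
        assert c_b == pytest.approx(50.0, abs=1e-9)


class TestMemberships:
    @pytest.mark.parametrize(
        "intensity, c_k, c_b, expected_mu_k",
        [
            (100.0, 150.0, 50.0, 0.5),
            (140.0, 150.0, 50.0, 81.0 / 82.0),
            (150.0, 150.0, 50.0, 1.0),
            (50.0, 150.0, 50.0, 0.0),
        ],
    )
    def test_inverse_square_distance_rule(self, intensity, c_k, c_b, expected_mu_k):
        m = update_memberships(np.array([[intensity]]), c_k, c_b)
        assert m.mu_K[0, 0] == pytest.approx(expected_mu_k, abs=1e-12)

    def test_sum_to_one_everywhere(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        m = update_memberships(img, 180.0, 60.0)
        assert np.abs(m.mu_K + m.mu_B - 1.0).max() < 1e-12

    def test_equal_centroids_rejected(self):
        with pytest.raises(DegenerateInputError):
            update_memberships(np.zeros((4, 4)), 5.0, 5.0)


class TestCentroids:
    def test_full_domain_unit_membership_gives_global_mean(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        m = update_memberships(img, 300.0, -1.0)
        m.mu_K[:] = 1.0
        m.mu_B[:] = 0.0
        field = LevelSetField(np.full((16, 16), 10.0), 1.5)  # H = 1 everywhere
        m.mu_B[:] = 1e-6  # keep the background denominator nonzero
        c_k, _ = update_centroids(img, m, None)
        assert c_k == pytest.approx(img.mean(), rel=1e-9)

    def test_hard_labels_on_separated_regions(self):
        img, disk = _two_region_image()
        phi = np.where(disk, 5.0, -5.0)  # |phi| > eps on both sides
        m = update_memberships(img, 200.0, 50.0)
        c_k, c_b = update_centroids(img, m, LevelSetField(phi, 1.5))
        assert c_k == pytest.approx(200.0, abs=1e-9)
        assert c_b == pytest.approx(50.0, abs=1e-9)

    def test_matches_brute_force_double_loop(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        phi = rng.uniform(-3, 3, (16, 16))
        field = LevelSetField(phi, 1.5)
        m = update_memberships(img, 200.0, 60.0)
        c_k, c_b = update_centroids(img, m, field)
        num_k = num_b = den_k = den_b = 0.0
        for r in range(16):
            for c in range(16):
                h = smeared_heaviside(phi[r, c], 1.5)
                num_k += h * img[r, c] * m.mu_K[r, c] ** 2
                den_k += h * m.mu_K[r, c] ** 2
                num_b += (1 - h) * img[r, c] * m.mu_B[r, c] ** 2
                den_b += (1 - h) * m.mu_B[r, c] ** 2
        assert c_k == pytest.approx(num_k / den_k, rel=1e-12)
        assert c_b == pytest.approx(num_b / den_b, rel=1e-12)

    def test_centroids_within_intensity_range(self, rng):
        img = rng.uniform(10, 90, (16, 16))
        field = LevelSetField(rng.uniform(-2, 2, (16, 16)), 1.5)
        m = update_memberships(img, 80.0, 20.0)
        c_k, c_b = update_centroids(img, m, field)
        assert img.min() <= c_k <= img.max()
        assert img.min() <= c_b <= img.max()


class TestLabelEnergy:
    @staticmethod
    def _m(mu_k):
        from renalseg.fcm import MembershipField

        mu = np.asarray(mu_k, dtype=float)
        return MembershipField(mu_K=mu, mu_B=1.0 - mu, C_K=1.0, C_B=0.0)

    def test_pb_only_when_omega_one(self, rng):
        mu = rng.uniform(0, 1, (8, 8))
        p_k = rng.uniform(0, 1, (8, 8))
        e = label_energy(self._m(mu), (p_k, 1 - p_k), None, 1.0)
        assert np.allclose(e.F_K, mu * p_k)

    def test_ss_only_when_omega_zero(self, rng):
        mu = rng.uniform(0, 1, (8, 8))
        s_k = rng.uniform(0, 1, (8, 8))
        p_k = rng.uniform(0, 1, (8, 8))
        e = label_energy(self._m(mu), (p_k, 1 - p_k), (s_k, 1 - s_k), 0.0)
        assert np.allclose(e.F_K, mu * s_k)

    def test_blended_scalar_example(self):
        e = label_energy(
            self._m([[0.8]]), (np.array([[0.9]]), np.array([[0.1]])),
            (np.array([[0.5]]), np.array([[0.5]])), 0.4,
        )
        assert e.F_K[0, 0] == pytest.approx(0.4 * 0.8 * 0.9 + 0.6 * 0.8 * 0.5, abs=1e-12)

    def test_missing_ss_prior_rejected(self):
        with pytest.raises(ValueError):
            label_energy(self._m([[0.5]]), (np.ones((1, 1)), np.zeros((1, 1))), None, 0.5)

    def test_energies_form_subconvex_pair(self, rng):
        mu = rng.uniform(0, 1, (16, 16))
        p_k = rng.uniform(0, 1, (16, 16))
        s_k = rng.uniform(0, 1, (16, 16))
        e = label_energy(self._m(mu), (p_k, 1 - p_k), (s_k, 1 - s_k), 0.3)
        assert np.all(e.F_K + e.F_B <= 1.0 + 1e-12)
        assert np.all((e.F_K >= 0) & (e.F_K <= 1) & (e.F_B >= 0) & (e.F_B <= 1))


class TestCoupling:
    def test_zero_tau_updates_memberships_not_phi(self):
        img, _ = _two_region_image()
        field = initial_level_set((32, 32), (16, 16), 8.0)
        c_k, c_b = init_centroids(img, field)
        m = update_memberships(img, c_k + 5.0, c_b)  # deliberately offset
        flat = (np.full((32, 32), 0.5), np.full((32, 32), 0.5))
        params = EvolutionParams(tau=0.0, max_iters=1, tol=0.0)
        out_field, out_m, _ = coupled_step(img, field, m, flat, None, 1.0, params)
        assert np.array_equal(out_field.phi, field.phi)
        assert not np.allclose(out_m.mu_K, m.mu_K)

    def test_converges_to_region_means_with_flat_priors(self):
        img, disk = _two_region_image(hi=210.0, lo=40.0)
        field = initial_level_set((32, 32), (12, 20), 6.0)
        c_k, c_b = init_centroids(img, field)
        m = update_memberships(img, max(c_k, c_b), min(c_k, c_b))
        flat = (np.full((32, 32), 0.5), np.full((32, 32), 0.5))
        params = EvolutionParams(lambda1=1.0, lambda2=6.0, tau=0.25, max_iters=300, tol=1e-6)
        for _ in range(300):
            field, m, change = coupled_step(img, field, m, flat, None, 1.0, params)
            if change < params.tol:
                break
        assert m.C_K == pytest.approx(210.0, rel=0.01)
        assert m.C_B == pytest.approx(40.0, rel=0.01)

    def test_prior_dominated_limit_recovers_prior_support(self):
        # uniform image: memberships are uninformative, the prior decides
        img = np.full((32, 32), 100.0)
        rows, cols = np.indices((32, 32), dtype=float)
        support = np.hypot(rows - 16, cols - 16) <= 9
        p_k = np.where(support, 1.0, 0.0)
        field = initial_level_set((32, 32), (8, 8), 5.0)
        m = update_memberships(img, 101.0, 99.0)
        params = EvolutionParams(lambda1=1.0, lambda2=6.0, tau=0.25, max_iters=400, tol=0.0)
        from renalseg.levelset import evolve_step

        for _ in range(400):
            e = label_energy(m, (p_k, 1 - p_k), None, 1.0)
            field, _ = evolve_step(field, e.F_K, e.F_B, params)
        mismatch = field.mask().astype(bool) ^ support
        assert not np.any(mismatch & (np.abs(np.hypot(rows - 16, cols - 16) - 9) > 1.0))

    def test_fcm_objective_monotone_under_alternation(self, rng):
        img = rng.uniform(0, 255, (24, 24))
        m = update_memberships(img, 250.0, 5.0)
        prev = fcm_objective(img, m, None)
        for _ in range(10):
            c_k, c_b = update_centroids(img, m, None)
            m = update_memberships(img, c_k, c_b)
            j = fcm_objective(img, m, None)
            assert j <= prev + 1e-9
            prev = j


class TestTextbookEquivalence:
    def test_full_domain_alternation_matches_textbook_fcm(self, rng):
        """Region-indicator updates with R=1 are exactly classic 2-cluster FCM."""
        img = rng.uniform(0, 255, (20, 20))
        c_k, c_b = 180.0, 40.0
        ref_ck, ref_cb = c_k, c_b
        m = update_memberships(img, c_k, c_b)
        for _ in range(8):
            # independent textbook iteration (m = 2): explicit loops
            num_k = den_k = num_b = den_b = 0.0
            for r in range(20):
                for c in range(20):
                    d_k = abs(img[r, c] - ref_ck)
                    d_b = abs(img[r, c] - ref_cb)
                    if d_k == 0:
                        u_k = 1.0
                    elif d_b == 0:
                        u_k = 0.0
                    else:
                        u_k = 1.0 / (1.0 + (d_k / d_b) ** 2)
                    u_b = 1.0 - u_k
                    num_k += u_k**2 * img[r, c]
                    den_k += u_k**2
                    num_b += u_b**2 * img[r, c]
                    den_b += u_b**2
            ref_ck, ref_cb = num_k / den_k, num_b / den_b

            c_k, c_b = update_centroids(img, m, None)
            m = update_memberships(img, c_k, c_b)
            assert c_k == pytest.approx(ref_ck, abs=1e-9)
            assert c_b == pytest.approx(ref_cb, abs=1e-9)

    def test_static_fcm_converges_to_same_fixed_point(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        m = static_fcm(img, 200.0, 30.0)
        c_k, c_b = update_centroids(img, m, None)
        assert m.C_K == pytest.approx(c_k, abs=1e-5)
        assert m.C_B == pytest.approx(c_b, abs=1e-5)
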