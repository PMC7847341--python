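import numpy as np
import pytest

from geomhnn.config import RunConfig
from geomhnn.geometry import kappa_field, sign_matrix
from geomhnn.mhnn import (
    ClassPrototypes,
    build_network,
    class_interval_map,
    enhance_image,
    enhance_patch,
    init_prototypes,
    network_energy,
    objective,
    run_sequenced,
    step_activation_01,
)


def uniform_kappa(shape, k0):
    return kappa_field(k0, np.zeros(shape))


def two_pixel_params(sign):
    protos = ClassPrototypes(intensities=np.array([0.25, 0.75]))
    kap = uniform_kappa((1, 2), 0.1)
    return build_network(np.array([[0.2, 0.8]]), protos, kap, 4, sign)


class TestPrototypes:
    def test_equal_mass_midpoints(self, rng):
        patch = rng.random((40, 40))  # near-uniform histogram
        protos = init_prototypes(patch, 2)
        np.testing.assert_allclose(protos.intensities, [0.25, 0.75], atol=0.02)

    def test_constant_patch_degenerate(self):
        protos = init_prototypes(np.full((4, 4), 0.4), 2)
        assert protos.degenerate
        assert protos.intensities[0] == pytest.approx(0.4, abs=1e-5)

    @pytest.mark.parametrize("method", ["quantile", "kmeans"])
    def test_strictly_increasing(self, method, rng):
        for _ in range(10):
            protos = init_prototypes(rng.random((6, 6)), 4, method=method, seed=7)
            assert (np.diff(protos.intensities) > 0).all()

    def test_kmeans_deterministic_given_seed(self, rng):
        patch = rng.random((10, 10))
        a = init_prototypes(patch, 3, method="kmeans", seed=5)
        b = init_prototypes(patch, 3, method="kmeans", seed=5)
        np.testing.assert_array_equal(a.intensities, b.intensities)


class TestObjective:
    def test_two_pixels_different_classes(self):
        params = two_pixel_params("paper")
        pi = objective(np.array([[0.2, 0.8]]), np.array([[0, 1]]), params)
        assert pi == pytest.approx(0.005)

    def test_two_pixels_same_class_penalized(self):
        params = two_pixel_params("paper")
        pi = objective(np.array([[0.2, 0.8]]), np.array([[0, 0]]), params)
        # 0.0025 + 0.3025 + two ordered agreeing pairs at kappa 0.1
        assert pi == pytest.approx(0.505)

    def test_potts_sign_rewards_agreement(self):
        params = two_pixel_params("potts")
        pi = objective(np.array([[0.2, 0.8]]), np.array([[0, 0]]), params)
        assert pi == pytest.approx(0.0025 + 0.3025 - 0.2)

    def test_invalid_labels_rejected(self):
        params = two_pixel_params("potts")
        with pytest.raises(ValueError):
            objective(np.array([[0.2, 0.8]]), np.array([[0, 5]]), params)


class TestBuildNetwork:
    def test_bias_formula(self):
        protos = ClassPrototypes(intensities=np.array([0.25, 0.75]))
        params = build_network(np.array([[0.5]]), protos, uniform_kappa((1, 1), 0.1))
        # d1 = d2 = 0.0625 -> bias = 0.0625 - 0.8*(2 - 0.0625) for both classes
        np.testing.assert_allclose(params.biases[0, 0], [-1.4875, -1.4875])

    def test_kappa_to_zero_bias_limit(self):
        protos = ClassPrototypes(intensities=np.array([0.2, 0.6]))
        params = build_network(np.array([[0.3]]), protos, uniform_kappa((1, 1), 1e-12))
        d = (0.3 - protos.intensities) ** 2
        np.testing.assert_allclose(params.biases[0, 0], d.mean(), atol=1e-10)

    def test_shape_mismatch(self):
        protos = ClassPrototypes(intensities=np.array([0.2, 0.6]))
        with pytest.raises(ValueError):
            build_network(np.zeros((2, 2)), protos, uniform_kappa((3, 3), 0.1))


class TestActivationAndEnergy:
    @pytest.mark.parametrize("phi, expected", [(0.5, 1), (0.0, 0), (-3.0, 0)])
    def test_step_01(self, phi, expected):
        assert step_activation_01(phi) == expected

    def test_single_pixel_energy_is_bias_term(self):
        protos = ClassPrototypes(intensities=np.array([0.25, 0.75]))
        params = build_network(np.array([[0.5]]), protos, uniform_kappa((1, 1), 0.1))
        e = network_energy(np.array([[0]]), np.array([[0.5]]), params)
        b = params.biases[0, 0]
        assert e == pytest.approx(-(b[0] * 1 + b[1] * -1))

    def test_energy_not_higher_after_relaxation(self, rng):
        for s in range(20):
            patch = rng.random((4, 4))
            kap = kappa_field(0.15, rng.random((4, 4)))
            protos = init_prototypes(patch, 2, seed=s)
            params = build_network(patch, protos, kap)
            init = np.argmin((patch[..., None] - protos.intensities) ** 2, axis=-1)
            labels, _, _ = run_sequenced(patch, params)
            e0 = network_energy(init, patch, params)
            e1 = network_energy(labels, patch, params)
            assert e1 <= e0 + 1e-9


class TestRunSequenced:
    def test_kappa_zero_recovers_nearest_prototype(self, rng):
        patch = rng.random((5, 5))
        protos = init_prototypes(patch, 3)
        params = build_network(patch, protos, uniform_kappa((5, 5), 1e-9))
        labels, trace, converged = run_sequenced(patch, params)
        assert converged and len(trace) == 2
        nearest = np.argmin((patch[..., None] - protos.intensities) ** 2, axis=-1)
        np.testing.assert_array_equal(labels, nearest)

    @pytest.mark.parametrize("sign", ["potts", "paper"])
    @pytest.mark.parametrize("neighborhood", [4, 8])
    def test_descent_and_one_pixel_optimality(self, sign, neighborhood, rng):
        for s in range(25):
            patch = rng.random((3, 3))
            kap = kappa_field(float(rng.uniform(0.05, 0.3)), rng.random((3, 3)))
            protos = init_prototypes(patch, 2, seed=s)
            params = build_network(patch, protos, kap, neighborhood, sign)
            labels, trace, converged = run_sequenced(patch, params)
            assert converged
            assert (np.diff(trace) <= 1e-12).all()
            pi0 = objective(patch, labels, params)
            for r in range(3):
                for c in range(3):
                    alt = labels.copy()
                    alt[r, c] = 1 - alt[r, c]
                    assert objective(patch, alt, params) >= pi0 - 1e-12

    def test_outlier_absorbed_under_strong_coupling(self):
        patch = np.full((3, 3), 0.2)
        patch[1, 1] = 0.8
        protos = ClassPrototypes(intensities=np.array([0.2, 0.8]))
        params = build_network(patch, protos, uniform_kappa((3, 3), 0.2), 4, "potts")
        labels, _, converged = run_sequenced(patch, params)
        assert converged and (labels == 0).all()

    def test_checkerboard_parities_cover_all_pixels(self):
        s = sign_matrix(6, 7)
        assert ((s == 1).sum() + (s == -1).sum()) == 42


class TestEnhancePatch:
    def test_alpha_zero_identity(self, rng):
        patch = rng.random((4, 4))
        protos = ClassPrototypes(intensities=np.array([0.3, 0.7]))
        labels = np.zeros((4, 4), dtype=int)
        np.testing.assert_array_equal(enhance_patch(patch, labels, protos, 0.0), patch)

    def test_full_range_stretch_two_classes(self):
        patch = np.array([[0.4, 0.45], [0.55, 0.6]])
        labels = np.array([[0, 0], [1, 1]])
        protos = ClassPrototypes(intensities=np.array([0.425, 0.575]))
        out = enhance_patch(patch, labels, protos, 1.0)
        np.testing.assert_allclose(out, [[0.0, 0.5], [0.5, 1.0]], atol=1e-9)

    def test_monotone_map(self, rng):
        patch = np.sort(rng.random(25)).reshape(5, 5)
        protos = init_prototypes(patch, 3)
        labels = np.argmin((patch[..., None] - protos.intensities) ** 2, axis=-1)
        out = enhance_patch(patch, labels, protos, 1.0)
        assert (np.diff(out.ravel()) >= -1e-12).all()

    def test_output_in_unit_interval(self, rng):
        patch = rng.random((6, 6))
        protos = init_prototypes(patch, 4)
        labels = np.argmin((patch[..., None] - protos.intensities) ** 2, axis=-1)
        out = enhance_patch(patch, labels, protos, 0.8)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_empty_class_skipped(self):
        patch = np.array([[0.1, 0.2], [0.15, 0.12]])
        labels = np.zeros((2, 2), dtype=int)  # class 1 empty
        protos = ClassPrototypes(intensities=np.array([0.15, 0.8]))
        out = enhance_patch(patch, labels, protos, 1.0)
        assert np.isfinite(out).all()
        xs, ys = class_interval_map(patch, labels, 2)
        assert xs.size == 2  # only class 0 contributes control points


class TestEnhanceImage:
    def test_alpha_zero_is_identity_on_8bit(self, degraded):
        img8 = np.floor(degraded * 255 + 0.5) / 255
        out, _ = enhance_image(img8, RunConfig(alpha=0.0))
        np.testing.assert_array_equal(out, img8)

    def test_deterministic(self, degraded):
        cfg = RunConfig(seed=9)
        a, _ = enhance_image(degraded, cfg)
        b, _ = enhance_image(degraded, cfg)
        np.testing.assert_array_equal(a, b)

    def test_diagnostics_per_patch(self, degraded):
        out, diag = enhance_image(degraded, RunConfig())
        assert len(diag) == 440
        assert all(d["converged"] for d in diag)
        assert out.shape == degraded.shape

    def test_contrast_increases_on_fixture(self, phantom, degraded):
        from geomhnn.metrics import contrast, glcm

        out, _ = enhance_image(degraded, RunConfig())
        assert contrast(glcm(out)) > contrast(glcm(degraded))
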