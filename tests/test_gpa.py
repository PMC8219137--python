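import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import mandimorph as mm
from mandimorph.gpa import preshape


def random_similarity(rng, coords):
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    return rng.uniform(0.5, 2.0) * coords @ R.T + rng.uniform(-10, 10, 3)


def test_centroid_size_square_and_invariances(rng):
    square = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], float)
    assert mm.centroid_size(square) == pytest.approx(2.0, abs=1e-12)
    assert mm.centroid_size(np.array([[3.0, -2.0, 7.0]])) == 0.0
    cfg = rng.standard_normal((14, 3))
    assert mm.centroid_size(cfg + np.array([5.0, 5.0, 5.0])) == pytest.approx(
        mm.centroid_size(cfg), rel=1e-12)
    R = Rotation.random(random_state=np.random.RandomState(0)).as_matrix()
    assert mm.centroid_size(cfg @ R.T) == pytest.approx(mm.centroid_size(cfg), rel=1e-12)
    assert mm.centroid_size(3.0 * cfg) == pytest.approx(3.0 * mm.centroid_size(cfg), rel=1e-12)


def test_optimal_rotation_recovers_known_rotation(template):
    A = template.coords
    Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    B = A @ Rz.T
    R = mm.optimal_rotation(A, B)
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)
    assert np.linalg.norm(A - B @ R) < 1e-12


def test_optimal_rotation_never_reflects(template):
    A = template.coords
    mirror = A * np.array([1.0, -1.0, 1.0])
    # mirrored template is a genuinely different shape (not rotation-equivalent)
    R = mm.optimal_rotation(A, mirror)
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)
    assert np.linalg.norm(A - mirror @ R) > 1e-3


def test_optimal_rotation_degenerate_input_raises():
    line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
    with pytest.raises(ValueError, match="identifiable"):
        mm.optimal_rotation(line, line)


def brute_force_rotation_residual(A, B):
    best = np.inf
    rng = np.random.default_rng(1)
    from scipy.optimize import minimize

    for _ in range(8):
        x0 = rng.uniform(-np.pi, np.pi, 3)
        res = minimize(
            lambda r: np.sum((A - B @ Rotation.from_rotvec(r).as_matrix()) ** 2),
            x0, method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000},
        )
        best = min(best, res.fun)
    return best


def test_optimal_rotation_matches_numeric_minimization(rng):
    A = rng.standard_normal((8, 3))
    B = rng.standard_normal((8, 3))
    A -= A.mean(0)
    B -= B.mean(0)
    R = mm.optimal_rotation(A, B)
    assert np.sum((A - B @ R) ** 2) == pytest.approx(
        brute_force_rotation_residual(A, B), abs=1e-6)


def test_procrustes_distance_similarity_invariance_and_symmetry(rng, template):
    A = template.coords + 0.05 * rng.standard_normal((14, 3))
    B = random_similarity(rng, A)
    assert mm.full_procrustes_distance(A, B) == pytest.approx(0.0, abs=1e-10)
    for _ in range(5):
        C = template.coords + 0.1 * rng.standard_normal((14, 3))
        D = template.coords + 0.1 * rng.standard_normal((14, 3))
        assert mm.full_procrustes_distance(C, D) == pytest.approx(
            mm.full_procrustes_distance(D, C), rel=1e-12)
        assert mm.full_procrustes_distance(C, random_similarity(rng, D)) == pytest.approx(
            mm.full_procrustes_distance(C, D), rel=1e-9)


def test_planar_triangle_distance_matches_brute_force():
    from scipy.optimize import minimize

    A = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
    B = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], float)
    Za, Zb = preshape(A), preshape(B)

    def objective(params):
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        return np.sum((Za - params[3] * Zb @ R) ** 2)

    best = min(
        minimize(objective, np.array([0, 0, a, 1.0]), method="Nelder-Mead",
                 options={"xatol": 1e-13, "fatol": 1e-15, "maxiter": 6000}).fun
        for a in np.linspace(-np.pi, np.pi, 9)
    )
    assert mm.full_procrustes_distance(A, B) == pytest.approx(np.sqrt(best), abs=1e-6)


def test_triangle_inequality_on_random_triples(rng, template):
    for _ in range(30):
        A, B, C = (template.coords + 0.2 * rng.standard_normal((14, 3)) for _ in range(3))
        dab = mm.full_procrustes_distance(A, B)
        dbc = mm.full_procrustes_distance(B, C)
        dac = mm.full_procrustes_distance(A, C)
        assert dac <= dab + dbc + 1e-12


def test_gpa_of_identical_shapes_under_similarity(rng, template):
    X = np.stack([random_similarity(rng, template.coords) for _ in range(6)])
    fit = mm.gpa(X)
    assert fit.objective < 1e-18
    assert np.allclose(fit.aligned, fit.aligned[0], atol=1e-9)


def test_gpa_invariants_and_unit_sizes(default_fit):
    centroids = default_fit.aligned.mean(axis=1)
    assert np.abs(centroids).max() < 1e-9
    sizes = np.linalg.norm(default_fit.aligned, axis=(1, 2))
    np.testing.assert_allclose(sizes, 1.0, atol=1e-9)
    assert mm.centroid_size(default_fit.consensus) == pytest.approx(1.0, abs=1e-9)
    # consensus equals rescaled mean of aligned coordinates
    m = default_fit.aligned.mean(axis=0)
    np.testing.assert_allclose(m / np.linalg.norm(m), default_fit.consensus, atol=1e-9)
    # objective path non-increasing
    diffs = np.diff(default_fit.objective_path)
    assert (diffs <= 1e-12).all()


def test_gpa_two_specimens_reproduce_pairwise_distance(rng, template):
    A = template.coords + 0.05 * rng.standard_normal((14, 3))
    B = template.coords + 0.05 * rng.standard_normal((14, 3))
    fit = mm.gpa(np.stack([A, B]))
    assert fit.pairwise_distance(0, 1, "full") == pytest.approx(
        mm.full_procrustes_distance(A, B), abs=1e-8)


def test_gpa_result_invariant_to_input_similarity_transforms(rng, default_dataset):
    sub = default_dataset.subset(np.arange(20))
    fit1 = mm.gpa(sub)
    X = sub.coords_array()
    X2 = np.stack([random_similarity(rng, x) for x in X])
    fit2 = mm.gpa(X2)
    # consensus agrees up to rotation: full Procrustes distance ~ 0
    assert mm.full_procrustes_distance(fit1.consensus, fit2.consensus) < 1e-7


def test_gpa_idempotent(default_fit):
    again = mm.gpa(default_fit.aligned)
    assert np.abs(again.aligned - default_fit.aligned).max() < 1e-9


def test_mean_shape_definitions(default_fit, rng):
    np.testing.assert_allclose(
        mm.mean_shape(default_fit), default_fit.consensus, atol=1e-9)
    two = mm.mean_shape(default_fit, [0, 1])
    direct = default_fit.aligned[[0, 1]].mean(axis=0)
    direct /= np.linalg.norm(direct)
    assert mm.full_procrustes_distance(two, direct) < 1e-10
    with pytest.raises(ValueError, match="empty"):
        mm.mean_shape(default_fit, np.array([], dtype=int))
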