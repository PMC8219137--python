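import numpy as np
import pandas as pd
import pytest

import mandimorph as mm
from mandimorph.gpa import ProcrustesFit


def make_fit(Y, labels=None, **meta):
    """Wrap an (n, 3k) matrix as a ProcrustesFit for inference tests."""
    n, p = Y.shape
    k = p // 3
    md = pd.DataFrame({"specimen_id": [str(i) for i in range(n)], **meta})
    return ProcrustesFit(
        Y.reshape(n, k, 3), Y.mean(0).reshape(k, 3), np.ones(n),
        tuple(f"L{i}" for i in range(k)), list(md.specimen_id), md,
        1, True, 0.0, [],
    )


def test_pca_single_factor_dominates(rng):
    direction = rng.standard_normal(42)
    direction /= np.linalg.norm(direction)
    scores = rng.standard_normal(50)
    Y = np.outer(scores, direction) + 1e-4 * rng.standard_normal((50, 42))
    res = mm.shape_pca(make_fit(Y))
    assert res.pct_variance[0] > 99.0
    assert res.pct_variance.sum() == pytest.approx(100.0, abs=1e-6)
    assert (np.diff(res.eigenvalues) <= 1e-12).all()


def test_pca_reconstruction_and_rank_cap(default_fit):
    res = mm.shape_pca(default_fit)
    X = default_fit.flattened()
    recon = res.scores @ res.loadings + res.mean
    np.testing.assert_allclose(recon, X, atol=1e-9)
    # centering leaves 3 exact null directions out of 3k
    assert res.q <= min(default_fit.n - 1, 3 * default_fit.k - 3)


def test_pca_requires_three_specimens(rng):
    with pytest.raises(ValueError, match="n >= 3"):
        mm.shape_pca(make_fit(rng.standard_normal((2, 42))))


def test_anova_ss_decomposition_exact(default_fit):
    res = mm.ProcrustesANOVA(default_fit, "sex + age + sex:age").fit(n_perm=9, seed=0)
    total_about_mean = np.sum(
        (default_fit.flattened() - default_fit.flattened().mean(0)) ** 2)
    ss_sum = sum(t["SS"] for t in res.terms) + res.residual["SS"]
    assert ss_sum == pytest.approx(total_about_mean, abs=1e-9)


def test_anova_min_p_and_reproducibility(default_fit):
    m = mm.ProcrustesANOVA(default_fit, ["sex"])
    res1 = m.fit(n_perm=999, seed=42)
    res2 = m.fit(n_perm=999, seed=42)
    assert res1.terms[0]["p_perm"] == res2.terms[0]["p_perm"]
    # strong effect: p attains exactly the permutation floor 1/(n_perm+1)
    assert res1.terms[0]["p_perm"] == pytest.approx(1 / 1000)


def test_single_factor_f_equals_goodall_closed_form(default_fit):
    res = mm.ProcrustesANOVA(default_fit, ["sex"]).fit(n_perm=9, seed=1)
    closed = mm.goodall_f_two_sample(default_fit, default_fit.metadata["sex"].to_numpy())
    assert res.terms[0]["F"] == pytest.approx(closed, abs=1e-9)


def test_anova_f_invariant_to_specimen_order(default_fit, rng):
    perm = rng.permutation(default_fit.n)
    shuffled = default_fit.subset(perm)
    f1 = mm.ProcrustesANOVA(default_fit, ["sex"]).fit(n_perm=9, seed=0).terms[0]["F"]
    f2 = mm.ProcrustesANOVA(shuffled, ["sex"]).fit(n_perm=9, seed=0).terms[0]["F"]
    assert f1 == pytest.approx(f2, rel=1e-9)


def test_anova_error_contracts(default_fit):
    md = default_fit.metadata.assign(const="x")
    bad = default_fit.subset(np.arange(default_fit.n))
    bad.metadata = md
    with pytest.raises(ValueError, match="constant"):
        mm.ProcrustesANOVA(bad, ["const"])
    with pytest.raises(ValueError, match="n_perm"):
        mm.ProcrustesANOVA(default_fit, ["sex"]).fit(n_perm=0, seed=0)


def test_mahalanobis_identity_covariance_is_euclidean(rng):
    # two groups, unit within-group covariance, mean offset (3, 4, 0, ...)
    n = 4000
    scores = rng.standard_normal((2 * n, 6))
    scores[:n, 0] += 3.0
    scores[:n, 1] += 4.0
    ts = mm.TangentScores(scores, np.eye(6), np.ones(6), np.full(6, 100 / 6), np.zeros(6))
    labels = np.array(["a"] * n + ["b"] * n)
    D, q = mm.mahalanobis_shape_distance(ts, labels, q=6)
    assert D == pytest.approx(5.0, rel=0.05)


def test_mahalanobis_scale_and_linear_invariance(rng):
    scores = rng.standard_normal((40, 5))
    scores[:20] += rng.standard_normal(5)
    labels = np.array(["a"] * 20 + ["b"] * 20)

    def dist(S):
        ts = mm.TangentScores(S, np.eye(5), np.ones(5), np.full(5, 20.0), np.zeros(5))
        return mm.mahalanobis_shape_distance(ts, labels, q=5)[0]

    base = dist(scores)
    assert dist(2.0 * scores) == pytest.approx(base, rel=1e-9)
    A = rng.standard_normal((5, 5)) + 3 * np.eye(5)  # invertible reparameterization
    assert dist(scores @ A) == pytest.approx(base, rel=1e-6)


def test_mahalanobis_closed_form_small_example():
    S = np.array([
        [1.0, 0.0], [3.0, 0.0], [2.0, 1.0], [2.0, -1.0],
        [7.0, 0.0], [9.0, 0.0], [8.0, 1.0], [8.0, -1.0],
    ])
    labels = np.array(["a"] * 4 + ["b"] * 4)
    ts = mm.TangentScores(S, np.eye(2), np.ones(2), np.array([50.0, 50.0]), np.zeros(2))
    D, _ = mm.mahalanobis_shape_distance(ts, labels, q=2)
    # pooled covariance diag(2/3, 2/3); diff (-6, 0) -> sqrt(36 * 3/2)
    assert D == pytest.approx(np.sqrt(54.0), rel=1e-12)


def test_group_distance_identical_groups_near_zero(rng, template):
    X = template.coords + 0.001 * rng.standard_normal((40, 14, 3))
    fit = mm.gpa(X)
    labels = np.array(["a", "b"] * 20)
    gd = mm.group_distance(fit, labels, n_perm=99, seed=3)
    # mean-estimation noise only: ~ noise_sd * sqrt(3k * 2/20)
    assert gd.procrustes_distance < 0.005
    assert gd.p_perm > 0.05


def test_group_distance_recovers_constructed_offset(default_fit):
    gd = mm.group_distance(default_fit, "sex", n_perm=99, seed=9)
    # generator default offset is 0.03; estimate includes aging + noise bias
    assert 0.02 < gd.procrustes_distance < 0.05
    assert gd.mahalanobis_distance > 0
    assert gd.p_perm <= 0.05
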