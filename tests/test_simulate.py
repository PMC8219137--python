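import numpy as np
import pytest

import mandimorph as mm
from mandimorph.simulate import _age_grid, similarity_tangent_basis


def test_template_symmetry_and_size(template):
    labels = list(template.labels)
    for lb in ("Id", "Mns", "Pg", "Gn"):
        assert template.coords[labels.index(lb), 1] == pytest.approx(0.0, abs=1e-12)
    for base in ("Cs", "Mn", "Co", "Go", "Ml"):
        left = template.coords[labels.index(f"{base}_L")]
        right = template.coords[labels.index(f"{base}_R")]
        np.testing.assert_allclose(left * np.array([1, -1, 1]), right, atol=1e-12)
    assert mm.centroid_size(template) == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError, match="14"):
        mm.make_template(k=10)


def test_same_seed_bitwise_identical():
    a = mm.simulate_dataset(mm.SimulationSpec(seed=99))
    b = mm.simulate_dataset(mm.SimulationSpec(seed=99))
    np.testing.assert_array_equal(a.coords_array(), b.coords_array())
    assert a.metadata.equals(b.metadata)


def test_age_grid_matches_study_design():
    ages = _age_grid(mm.SimulationSpec())
    assert len(ages) == 80
    vals, counts = np.unique(ages, return_counts=True)
    assert vals.min() == 40 and vals.max() == 79
    assert (counts == 2).all()  # homogeneous sequential coverage


def test_similarity_basis_is_orthonormal(template):
    B = similarity_tangent_basis(template.coords)
    np.testing.assert_allclose(B.T @ B, np.eye(7), atol=1e-12)


def test_dimorphism_magnitude_survives_gpa():
    # offset built orthogonal to similarity directions: GPA keeps ~all of it
    spec = mm.SimulationSpec(
        seed=31, noise_sd=0.001,
        aging_female=mm.AgingProfile(onset=50, rate=0.0),
        aging_male=mm.AgingProfile(onset=60, rate=0.0),
    )
    ds = mm.simulate_dataset(spec)
    fit = mm.gpa(ds)
    sx = ds.metadata.sex.to_numpy()
    d = mm.full_procrustes_distance(
        mm.mean_shape(fit, sx == "F"), mm.mean_shape(fit, sx == "M"))
    assert d == pytest.approx(0.03, rel=0.05)


def test_aging_profile_shapes():
    const = mm.AgingProfile(onset=60, rate=0.001, peak_age=None)
    assert const.drift(50) == 0.0
    assert const.drift(70) == pytest.approx(0.01)
    peaked = mm.AgingProfile(onset=50, rate=0.002, peak_age=60)
    assert peaked.instantaneous_rate(50) == 0.0
    assert peaked.instantaneous_rate(60) == pytest.approx(0.002)
    assert peaked.instantaneous_rate(70) == pytest.approx(0.0)
    # drift accumulates the triangular rate: half at the peak, all by 70
    assert peaked.drift(60) == pytest.approx(0.01)
    assert peaked.drift(79) == pytest.approx(0.02)
    with pytest.raises(ValueError, match="peak_age"):
        mm.AgingProfile(onset=50, rate=0.1, peak_age=40).instantaneous_rate(55)


def test_convergence_mode_narrows_sex_gap_with_age():
    ds = mm.simulate_dataset(mm.SimulationSpec(seed=44, convergence_mode=True,
                                               noise_sd=0.001))
    fit = mm.gpa(ds)
    meta = ds.metadata
    old = meta.age.to_numpy() >= 70
    young = meta.age.to_numpy() < 50
    sx = meta.sex.to_numpy()
    d_young = mm.full_procrustes_distance(
        mm.mean_shape(fit, young & (sx == "F")), mm.mean_shape(fit, young & (sx == "M")))
    d_old = mm.full_procrustes_distance(
        mm.mean_shape(fit, old & (sx == "F")), mm.mean_shape(fit, old & (sx == "M")))
    # female path length by 79 (0.02) covers two thirds of the 0.03 gap
    assert d_old < 0.7 * d_young


def test_calibration_alpha_zero_rejects_nothing():
    spec = mm.SimulationSpec(seed=1, n_per_sex_per_bin=2, bin_width=10,
                             dimorphism_magnitude=0.0)
    res = mm.calibration_experiment(spec, reps=5, alpha=0.0, seed=2, n_perm=19)
    assert res["rejection_rate"] == 0.0


def test_power_monotone_in_dimorphism():
    base = mm.SimulationSpec(
        n_per_sex_per_bin=5, bin_width=10,
        aging_female=mm.AgingProfile(onset=50, rate=0.0),
        aging_male=mm.AgingProfile(onset=60, rate=0.0),
    )
    rates = []
    for i, delta in enumerate((0.0, 0.03, 0.08)):
        spec = base.with_(seed=70 + i, dimorphism_magnitude=delta)
        res = mm.calibration_experiment(spec, reps=25, alpha=0.05, seed=70 + i,
                                        n_perm=99)
        rates.append(res["rejection_rate"])
    assert rates[0] <= rates[1] + 0.1
    assert rates[1] < rates[2] + 1e-12
    assert rates[2] > 0.8


def test_invalid_magnitudes_rejected():
    with pytest.raises(ValueError, match="non-negative"):
        mm.simulate_dataset(mm.SimulationSpec(seed=0, dimorphism_magnitude=-0.1))
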