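import numpy as np
import pandas as pd
import pytest

import mandimorph as mm
from mandimorph.io import LandmarkConfiguration, LandmarkDataset


def test_cutoff_partitions_are_exhaustive_and_disjoint(default_dataset):
    table = mm.cutoff_cohort_tests(default_dataset, n_perm=19, seed=1)
    assert set(table.sex) == {"M", "F"}
    for _, row in table.iterrows():
        assert row.n_younger + row.n_older == 80
        assert not row.flagged
    # female age effect (onset 50) is detectable, male (onset 60, weaker) less so
    f60 = table[(table.sex == "F") & (table.cutoff_years == 60)].iloc[0]
    assert f60.goodall_F > 1.5


def test_cutoff_flags_small_cohorts(default_dataset):
    young = default_dataset.subset(default_dataset.metadata.age.to_numpy() < 46)
    table = mm.cutoff_cohort_tests(young, cutoffs=[60], n_perm=19, seed=0)
    assert table.flagged.all()
    assert table.goodall_F.isna().all()


def test_intercohort_table_symmetry_and_diagonal(default_dataset):
    icd = mm.intercohort_distances(default_dataset, n_perm=19, seed=2)
    D = icd.distances.to_numpy()
    np.testing.assert_allclose(D, D.T, atol=1e-15)
    np.testing.assert_allclose(np.diag(D), 0.0)
    assert list(icd.distances.index) == ["youngF", "oldF", "youngM", "oldM"]


def test_intercohort_empty_cohort_raises(default_dataset):
    males = default_dataset.subset(default_dataset.metadata.sex.to_numpy() == "M")
    with pytest.raises(ValueError, match="empty cohort"):
        mm.intercohort_distances(males, n_perm=9, seed=0)


def test_convergent_generator_orders_cohort_distances():
    ds = mm.simulate_dataset(mm.SimulationSpec(seed=77, convergence_mode=True))
    icd = mm.intercohort_distances(ds, n_perm=19, seed=3)
    assert icd.distances.loc["oldF", "oldM"] < icd.distances.loc["youngF", "youngM"]


def test_aging_rate_noise_free_linear_drift_is_exact():
    # constant post-onset rate from age 40 on: every window slope equals b
    b = 1e-4
    spec = mm.SimulationSpec(
        seed=3, noise_sd=0.0, dimorphism_magnitude=0.0,
        aging_female=mm.AgingProfile(onset=40, rate=b, peak_age=None),
        aging_male=mm.AgingProfile(onset=40, rate=b, peak_age=None),
    )
    curve = mm.aging_rate_curve(mm.simulate_dataset(spec), "F")
    # exact up to the (quadratically small) curvature of the unit-size constraint
    np.testing.assert_allclose(curve.rates, b, atol=1e-8)
    assert len(curve.centers) == 80 - 20 + 1
    assert (np.diff(curve.centers) >= 0).all()


def test_aging_rate_window_contract(default_dataset):
    curve = mm.aging_rate_curve(default_dataset, "M", window=30)
    assert len(curve.rates) == 80 - 30 + 1
    assert (curve.rates[np.isfinite(curve.rates)] >= 0).all()
    with pytest.raises(ValueError, match="window"):
        mm.aging_rate_curve(default_dataset.subset(np.arange(30)), "F", window=40)


def test_noise_slope_bias_decreases_with_window():
    # pure noise: expected rate (norm of noisy slope) shrinks as window grows
    spec = mm.SimulationSpec(
        seed=8, dimorphism_magnitude=0.0,
        aging_female=mm.AgingProfile(onset=50, rate=0.0),
        aging_male=mm.AgingProfile(onset=60, rate=0.0),
    )
    means = {w: [] for w in (10, 20, 40)}
    for s in range(6):
        ds = mm.simulate_dataset(spec.with_(seed=800 + s))
        for w in means:
            means[w].append(np.nanmean(mm.aging_rate_curve(ds, "F", w).rates))
    avg = {w: np.mean(v) for w, v in means.items()}
    assert avg[10] > avg[20] > avg[40]


def test_age_permutation_destroys_trend():
    ds = mm.simulate_dataset(mm.SimulationSpec(seed=21, noise_sd=0.005))
    rng = np.random.default_rng(4)
    slopes = []
    for _ in range(5):
        meta = ds.metadata.copy()
        meta["age"] = rng.permutation(meta["age"].to_numpy())
        shuffled = LandmarkDataset(ds.configurations, meta)
        c = mm.aging_rate_curve(shuffled, "F")
        slopes.append(np.polyfit(c.centers, c.rates, 1)[0])
    # no systematic rise of rate with age once ages are shuffled
    assert abs(np.mean(slopes)) < 2e-4


def test_cohort_mean_comparison_identities(default_dataset):
    labels = np.where(default_dataset.metadata.age.to_numpy() >= 60, "old", "young")
    cc = mm.cohort_mean_comparison(default_dataset, labels)
    assert np.sum(cc.magnitudes**2) == pytest.approx(
        mm.partial_procrustes_distance(cc.mean_a, cc.mean_b) ** 2, abs=1e-9)
    frame = cc.to_frame()
    assert list(frame.columns) == ["landmark", "dx", "dy", "dz", "magnitude"]


def test_cohort_mean_comparison_identical_groups(template, rng):
    X = np.stack([template.coords] * 8) + 1e-9 * rng.standard_normal((8, 14, 3))
    ds = LandmarkDataset(
        [LandmarkConfiguration(str(i), X[i]) for i in range(8)],
        pd.DataFrame({"specimen_id": [str(i) for i in range(8)]}),
    )
    cc = mm.cohort_mean_comparison(ds, np.array(["a", "b"] * 4))
    assert cc.magnitudes.max() < 1e-6


def test_localized_effect_shows_at_injected_landmarks(template, rng):
    # symphysis retrusion: displace Pg, Mns, Id along -x in one group
    labels = list(template.labels)
    bump = np.zeros((14, 3))
    for lm in ("Pg", "Mns", "Id"):
        bump[labels.index(lm), 0] = -0.03
    configs, meta = [], []
    for i in range(40):
        grp = "young" if i < 20 else "old"
        coords = template.coords + (bump if grp == "old" else 0)
        coords = coords + 0.002 * rng.standard_normal((14, 3))
        configs.append(LandmarkConfiguration(str(i), coords))
        meta.append({"specimen_id": str(i), "group": grp})
    ds = LandmarkDataset(configs, pd.DataFrame(meta))
    cc = mm.cohort_mean_comparison(ds, "group")
    top3 = set(np.array(labels)[np.argsort(cc.magnitudes)[-3:]])
    assert top3 == {"Pg", "Mns", "Id"}
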