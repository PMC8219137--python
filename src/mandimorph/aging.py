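"""Study-design drivers: age-cohort cut-off tests, inter-cohort distances,
the moving-window aging-rate curve, and cohort mean-shape comparison.

Sex-stratified analyses re-superimpose within sex; the four-cohort distance
table uses one common superimposition because it compares across sexes.
Cohorts split as ``younger = age < cutoff``, ``older = age >= cutoff``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gpa import gpa, mean_shape, optimal_rotation, procrustes_distance
from .inference import ProcrustesANOVA
from .io import LandmarkDataset

__all__ = [
    "cutoff_cohort_tests",
    "InterCohortDistances",
    "intercohort_distances",
    "AgingRateCurve",
    "aging_rate_curve",
    "CohortComparison",
    "cohort_mean_comparison",
]

DEFAULT_CUTOFFS = (55, 60, 65)
DEFAULT_SEX_CUTOFFS = {"F": 55, "M": 65}


def _require_columns(dataset: LandmarkDataset, cols):
    for c in cols:
        if c not in dataset.metadata.columns:
            raise ValueError(f"dataset metadata lacks required column {c!r}")


def cutoff_cohort_tests(
    dataset: LandmarkDataset,
    cutoffs=DEFAULT_CUTOFFS,
    n_perm: int = 999,
    seed: int | None = None,
    min_cell: int = 3,
) -> pd.DataFrame:
    """Goodall's F between younger/older cohorts at each cut-off, per sex.

    Each sex is superimposed separately (fresh GPA), then a single-factor
    permutation ANOVA tests cohort membership.  Rows whose cohorts fall
    below ``min_cell`` specimens are flagged (F and p set to NaN) rather
    than computed.
    """
    _require_columns(dataset, ["sex", "age"])
    rng = np.random.default_rng(seed)
    rows = []
    for sex in ("M", "F"):
        sub = dataset.subset(dataset.metadata["sex"].to_numpy() == sex)
        if sub.n == 0:
            continue
        fit = gpa(sub)
        ages = sub.metadata["age"].to_numpy(int)
        for cutoff in cutoffs:
            young = ages < cutoff
            old = ~young
            row = {
                "sex": sex,
                "cutoff_years": int(cutoff),
                "younger_range": f"{ages[young].min()}-{ages[young].max()}" if young.any() else "",
                "older_range": f"{ages[old].min()}-{ages[old].max()}" if old.any() else "",
                "n_younger": int(young.sum()),
                "n_older": int(old.sum()),
            }
            if young.sum() < min_cell or old.sum() < min_cell:
                row.update(goodall_F=np.nan, p_perm=np.nan, flagged=True)
            else:
                fit.metadata = fit.metadata.assign(_cohort=np.where(young, "younger", "older"))
                sub_seed = int(rng.integers(2**31 - 1))
                res = ProcrustesANOVA(fit, ["_cohort"]).fit(n_perm=n_perm, seed=sub_seed)
                t = res.terms[0]
                row.update(goodall_F=t["F"], p_perm=t["p_perm"], flagged=False)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class InterCohortDistances:
    """Symmetric full-Procrustes distance table between four age cohorts."""

    cohorts: list
    distances: pd.DataFrame
    p_values: pd.DataFrame
    n_perm: int
    seed: int | None


def intercohort_distances(
    dataset: LandmarkDataset,
    sex_cutoffs: dict = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> InterCohortDistances:
    """Distances among youngF/oldF/youngM/oldM cohorts under a common GPA.

    Pairwise permutation p-values shuffle cohort labels within the pair and
    recompute the mean-shape distance.  ``sex_cutoffs`` maps sex to the age
    splitting its younger/older cohorts (defaults F:55, M:65, the cut-offs
    at which each sex first shows significant change).
    """
    _require_columns(dataset, ["sex", "age"])
    if sex_cutoffs is None:
        sex_cutoffs = dict(DEFAULT_SEX_CUTOFFS)
    fit = gpa(dataset)
    sexes = dataset.metadata["sex"].to_numpy()
    ages = dataset.metadata["age"].to_numpy(int)
    names, masks = [], []
    for sex in ("F", "M"):
        cut = sex_cutoffs[sex]
        for tag, mask in (
            (f"young{sex}", (sexes == sex) & (ages < cut)),
            (f"old{sex}", (sexes == sex) & (ages >= cut)),
        ):
            if not mask.any():
                raise ValueError(f"empty cohort {tag!r}")
            names.append(tag)
            masks.append(mask)
    Y = fit.flattened()
    means = {nm: mean_shape(fit, m) for nm, m in zip(names, masks)}
    dist = pd.DataFrame(0.0, index=names, columns=names)
    pval = pd.DataFrame(np.nan, index=names, columns=names)
    rng = np.random.default_rng(seed)
    for i in range(4):
        for j in range(i + 1, 4):
            d = procrustes_distance(means[names[i]], means[names[j]], "full")
            dist.iloc[i, j] = dist.iloc[j, i] = d
            pool = np.where(masks[i] | masks[j])[0]
            n_i = int(masks[i].sum())
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(pool)
                a, b = perm[:n_i], perm[n_i:]
                ma = _unit_mean(Y[a], fit.k)
                mb = _unit_mean(Y[b], fit.k)
                if procrustes_distance(ma, mb, "full") >= d - 1e-12:
                    count += 1
            p = (1.0 + count) / (1.0 + n_perm)
            pval.iloc[i, j] = pval.iloc[j, i] = p
    return InterCohortDistances(names, dist, pval, n_perm, seed)


def _unit_mean(flat_rows: np.ndarray, k: int) -> np.ndarray:
    m = flat_rows.mean(axis=0).reshape(k, 3)
    m = m - m.mean(axis=0)
    return m / np.linalg.norm(m)


@dataclass
class AgingRateCurve:
    """Moving-window shape-change rate against window-centre age.

    ``rates`` are Euclidean norms of the multivariate regression slope of
    aligned coordinates on age within each window — the displacement of the
    predicted mean shape per year, in Procrustes-coordinate units.
    """

    sex: str
    window: int
    centers: np.ndarray
    rates: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sex": self.sex, "center_age": self.centers,
                             "rate": self.rates})


def aging_rate_curve(
    dataset: LandmarkDataset, sex: str, window: int = 20
) -> AgingRateCurve:
    """Sex-specific moving-window regression of shape on age (step 1).

    Specimens are superimposed within sex, sorted by age (ties broken by
    specimen id), and for each contiguous window the flattened aligned
    coordinates are regressed on age.  A window with zero age variance
    yields a NaN rate.
    """
    _require_columns(dataset, ["sex", "age"])
    sub = dataset.subset(dataset.metadata["sex"].to_numpy() == sex)
    if sub.n < window:
        raise ValueError(f"need at least window={window} specimens of sex {sex!r}, have {sub.n}")
    order = np.lexsort((np.asarray(sub.specimen_ids), sub.metadata["age"].to_numpy(int)))
    sub = sub.subset(order)
    fit = gpa(sub)
    Y = fit.flattened()
    ages = sub.metadata["age"].to_numpy(float)
    n = sub.n
    centers, rates = [], []
    for start in range(n - window + 1):
        a = ages[start:start + window]
        yw = Y[start:start + window]
        centers.append(a.mean())
        sa = a - a.mean()
        saa = float(sa @ sa)
        if saa == 0.0:
            rates.append(np.nan)
            continue
        slope = (sa @ (yw - yw.mean(axis=0))) / saa
        rates.append(float(np.linalg.norm(slope)))
    return AgingRateCurve(sex, window, np.array(centers), np.array(rates))


@dataclass
class CohortComparison:
    """Two cohort mean shapes with per-landmark displacement vectors."""

    labels: tuple
    group_a: str
    group_b: str
    mean_a: np.ndarray   # (k, 3), reference frame
    mean_b: np.ndarray   # (k, 3), superimposed onto mean_a
    displacements: np.ndarray  # (k, 3), mean_b - mean_a
    magnitudes: np.ndarray     # (k,)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "landmark": list(self.labels),
            "dx": self.displacements[:, 0],
            "dy": self.displacements[:, 1],
            "dz": self.displacements[:, 2],
            "magnitude": self.magnitudes,
        })


def cohort_mean_comparison(dataset: LandmarkDataset, grouping) -> CohortComparison:
    """Mean shapes of two groups from a common GPA, one rotated onto the other.

    ``grouping`` is a metadata column name (two levels) or a label vector.
    The summed squared displacement equals the squared partial Procrustes
    distance between the two means.
    """
    fit = gpa(dataset)
    if isinstance(grouping, str):
        _require_columns(dataset, [grouping])
        labels = dataset.metadata[grouping].to_numpy()
    else:
        labels = np.asarray(grouping)
    levels = np.unique(labels)
    if levels.size != 2:
        raise ValueError("cohort comparison needs exactly two groups")
    for lv in levels:
        if (labels == lv).sum() < 2:
            raise ValueError(f"group {lv!r} has n < 2")
    ma = mean_shape(fit, labels == levels[0])
    mb = mean_shape(fit, labels == levels[1])
    R = optimal_rotation(ma, mb)  # rotate mb onto ma (both unit size)
    mb_on_a = mb @ R
    disp = mb_on_a - ma
    return CohortComparison(
        fit.labels, str(levels[0]), str(levels[1]),
        ma, mb_on_a, disp, np.linalg.norm(disp, axis=1),
    )
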