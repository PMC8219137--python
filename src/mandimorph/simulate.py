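"""Seeded generator of synthetic mandibular landmark datasets.

The generator reproduces the statistical structure the analyses assume:
a balanced two-sex sample on a 40-79-year grid, a mean-shape offset of
controllable Procrustes magnitude between the sexes, sex-specific
piecewise-linear age drift (earlier onset and a peaked rate for females),
log-normal centroid size, isotropic per-landmark digitization noise, and
repeated digitizations for the reliability study.  Effect directions are
constructed orthogonal to the similarity-transform tangent directions at
the template, so nominal Procrustes-unit magnitudes survive the
superimposition.  All randomness flows from a single spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import DEFAULT_LANDMARK_LABELS, LandmarkConfiguration, LandmarkDataset

__all__ = [
    "AgingProfile",
    "SimulationSpec",
    "make_template",
    "similarity_tangent_basis",
    "simulate_dataset",
    "simulate_gstudy",
    "simulate_digitizations",
    "calibration_experiment",
]

# Stylized mandible landmark layout (x anterior, y lateral-left, z superior;
# arbitrary mm-like units, later normalized to unit centroid size).
_TEMPLATE_MM = {
    "Cs": (-45.0, 50.0, 40.0),
    "Mn": (-38.0, 48.0, 30.0),
    "Co": (-30.0, 46.0, 38.0),
    "Go": (-40.0, 47.0, -15.0),
    "Ml": (20.0, 22.0, -5.0),
    "Id": (35.0, 0.0, 10.0),
    "Mns": (37.0, 0.0, 0.0),
    "Pg": (38.0, 0.0, -8.0),
    "Gn": (36.0, 0.0, -14.0),
}


def make_template(k: int = 14) -> LandmarkConfiguration:
    """Deterministic bilaterally symmetric template at unit centroid size.

    Midline landmarks (Id, Mns, Pg, Gn) sit on the midsagittal plane
    (zero lateral coordinate); the Cs/Mn/Co/Go/Ml pairs mirror across it.
    """
    if k != 14:
        raise ValueError("the canonical mandible template has k = 14 landmarks")
    rows = []
    for label in DEFAULT_LANDMARK_LABELS:
        if label.endswith(("_L", "_R")):
            base, side = label[:-2], label[-1]
            x, y, z = _TEMPLATE_MM[base]
            rows.append((x, y if side == "L" else -y, z))
        else:
            rows.append(_TEMPLATE_MM[label])
    coords = np.array(rows, float)
    coords -= coords.mean(axis=0)
    coords /= np.linalg.norm(coords)
    return LandmarkConfiguration("template", coords, DEFAULT_LANDMARK_LABELS)


def similarity_tangent_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3k, 7) of the similarity-transform directions.

    Columns span infinitesimal translations (3), rotations (3) and scaling
    (1) at the centred unit-size template; shape-effect directions are
    projected out of this span so GPA cannot absorb them.
    """
    T = np.asarray(template, float)
    k = T.shape[0]
    cols = []
    for ax in range(3):
        e = np.zeros((k, 3))
        e[:, ax] = 1.0
        cols.append(e.ravel())
    gens = [
        np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], float),
        np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0]], float),
        np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], float),
    ]
    for J in gens:
        cols.append((T @ J.T).ravel())
    cols.append(T.ravel())
    B = np.column_stack(cols)
    Q, _ = np.linalg.qr(B)
    return Q


def _orthogonal_unit_direction(rng, basis_cols: list[np.ndarray], dim: int) -> np.ndarray:
    v = rng.standard_normal(dim)
    for b in basis_cols:
        v -= (v @ b) * b
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class AgingProfile:
    """Piecewise-linear age drift of shape for one sex.

    ``rate`` is the peak instantaneous shape-change rate in Procrustes
    units per year.  With ``peak_age=None`` the rate is constant from
    ``onset`` on (drift ``rate * max(0, age - onset)``).  With a peak, the
    instantaneous rate ramps linearly from 0 at ``onset`` to ``rate`` at
    ``peak_age`` and back to 0 at ``2*peak_age - onset`` (a triangular
    rate profile, a local rate maximum at ``peak_age``).
    """

    onset: float
    rate: float
    peak_age: float | None = None

    def instantaneous_rate(self, age) -> np.ndarray:
        a = np.asarray(age, float)
        if self.peak_age is None:
            return np.where(a >= self.onset, self.rate, 0.0)
        w = self.peak_age - self.onset
        if w <= 0:
            raise ValueError("peak_age must exceed onset")
        up = np.clip((a - self.onset) / w, 0.0, None)
        tri = np.clip(np.minimum(up, 2.0 - up), 0.0, 1.0)
        return self.rate * tri

    def drift(self, age) -> np.ndarray:
        """Accumulated shape displacement (Procrustes units) by ``age``."""
        a = np.asarray(age, float)
        if self.peak_age is None:
            return self.rate * np.clip(a - self.onset, 0.0, None)
        w = self.peak_age - self.onset
        t = np.clip(a - self.onset, 0.0, 2.0 * w)
        rising = 0.5 * self.rate * t**2 / w
        falling = 0.5 * self.rate * w + self.rate * (
            (t - w) - 0.5 * (t - w) ** 2 / w
        )
        return np.where(t <= w, rising, falling)


@dataclass(frozen=True)
class SimulationSpec:
    """Study-design conditions for the synthetic sample.

    Defaults emulate the reference study: 10 specimens per sex per 5-year
    bin over 40-79 years (n = 160), k = 14 landmarks, a sex mean-shape
    offset of 0.03 Procrustes units, female aging onset 50 with peak rate
    0.002/yr near 60, male onset 60 with constant rate 0.001/yr, isotropic
    per-landmark digitization noise of 0.01 (unit-size scale), and
    log-normal centroid size around 180 mm.
    """

    n_per_sex_per_bin: int = 10
    k: int = 14
    age_range: tuple = (40, 79)
    bin_width: int = 5
    dimorphism_magnitude: float = 0.03
    aging_female: AgingProfile = AgingProfile(onset=50.0, rate=0.002, peak_age=60.0)
    aging_male: AgingProfile = AgingProfile(onset=60.0, rate=0.001, peak_age=None)
    convergence_mode: bool = False
    noise_sd: float = 0.01
    size_lognormal: tuple = (np.log(180.0), 0.06)
    seed: int = 0

    def with_(self, **kw) -> "SimulationSpec":
        return replace(self, **kw)

    @property
    def n_bins(self) -> int:
        lo, hi = self.age_range
        return (hi - lo + 1) // self.bin_width

    @property
    def n_total(self) -> int:
        return 2 * self.n_bins * self.n_per_sex_per_bin


def _age_grid(spec: SimulationSpec) -> np.ndarray:
    """Homogeneous sequential integer ages over the design bins."""
    lo, _ = spec.age_range
    ages = []
    for b in range(spec.n_bins):
        start = lo + b * spec.bin_width
        for i in range(spec.n_per_sex_per_bin):
            ages.append(start + (i % spec.bin_width))
    return np.array(sorted(ages), int)


def simulate_dataset(spec: SimulationSpec) -> LandmarkDataset:
    """Draw one landmark dataset under the spec's conditions.

    Per-specimen mean shape = template +/- half the dimorphism offset along
    a fixed unit direction, plus the sex's accumulated age drift along its
    own unit direction; in ``convergence_mode`` the female mean instead
    drifts toward the current male mean of the same age (yearly attraction
    steps, never overshooting).  Isotropic landmark noise, a random
    rotation/translation and log-normal size are then applied.  Fully
    reproducible from ``spec.seed``.
    """
    if spec.dimorphism_magnitude < 0 or spec.noise_sd < 0:
        raise ValueError("magnitudes must be non-negative")
    rng = np.random.default_rng(spec.seed)
    template = make_template(spec.k).coords
    flat_t = template.ravel()
    B = similarity_tangent_basis(template)
    sim_cols = [B[:, i] for i in range(B.shape[1])]
    d_sex = _orthogonal_unit_direction(rng, sim_cols, flat_t.size)
    u_f = _orthogonal_unit_direction(rng, sim_cols + [d_sex], flat_t.size)
    u_m = _orthogonal_unit_direction(rng, sim_cols + [d_sex, u_f], flat_t.size)

    lo, hi = spec.age_range
    years = np.arange(lo, hi + 1)
    male_mean = {
        int(a): flat_t + 0.5 * spec.dimorphism_magnitude * d_sex
        + spec.aging_male.drift(a) * u_m
        for a in years
    }
    female_mean: dict[int, np.ndarray] = {}
    if spec.convergence_mode:
        pos = flat_t - 0.5 * spec.dimorphism_magnitude * d_sex
        for a in years:
            female_mean[int(a)] = pos.copy()
            step = float(spec.aging_female.instantaneous_rate(a))
            gap = male_mean[int(a)] - pos
            dist = np.linalg.norm(gap)
            if dist > 0 and step > 0:
                pos = pos + min(step, dist) * gap / dist
    else:
        for a in years:
            female_mean[int(a)] = (
                flat_t - 0.5 * spec.dimorphism_magnitude * d_sex
                + spec.aging_female.drift(a) * u_f
            )

    ages = _age_grid(spec)
    mu_log, sd_log = spec.size_lognormal
    configs, meta_rows = [], []
    for sex, means in (("F", female_mean), ("M", male_mean)):
        for i, a in enumerate(ages):
            mean = means[int(a)].reshape(spec.k, 3)
            shape = mean + rng.normal(0.0, spec.noise_sd, (spec.k, 3))
            # random proper rotation, log-normal size, random translation
            Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            if np.linalg.det(Q) < 0:
                Q[:, 0] *= -1
            size = float(np.exp(rng.normal(mu_log, sd_log)))
            t = rng.uniform(-100.0, 100.0, 3)
            coords = size * (shape @ Q.T) + t
            sid = f"{sex}{i + 1:03d}"
            configs.append(LandmarkConfiguration(sid, coords, DEFAULT_LANDMARK_LABELS))
            meta_rows.append({"specimen_id": sid, "sex": sex, "age": int(a)})
    return LandmarkDataset(configs, pd.DataFrame(meta_rows))


# ---------------------------------------------------------------------------
# G-study simulation
# ---------------------------------------------------------------------------

_GSTUDY_KEYS = ("s", "r", "l", "sr", "sl", "rl", "srl_e")


def simulate_gstudy(
    components: dict,
    n_subjects: int = 40,
    n_raters: int = 2,
    n_variables: int = 91,
    mean: float = 60.0,
    seed: int | None = None,
) -> np.ndarray:
    """Crossed s x r x l measurement cube with known variance components.

    Additive random-effects model on inter-landmark distances:
    ``X[s,r,l] = mean + a_s + b_r + c_l + (ab) + (ac) + (bc) + e`` with
    independent zero-mean normal effects at the requested variances
    (missing keys default to 0).  The default cube shape matches the
    reference protocol: 40 subjects x 2 digitizations x 91 landmark pairs.
    """
    bad = set(components) - set(_GSTUDY_KEYS)
    if bad:
        raise ValueError(f"unknown variance components: {sorted(bad)}")
    var = {k: float(components.get(k, 0.0)) for k in _GSTUDY_KEYS}
    if any(v < 0 for v in var.values()):
        raise ValueError("variance components must be non-negative")
    rng = np.random.default_rng(seed)
    ns, nr, nl = n_subjects, n_raters, n_variables
    X = np.full((ns, nr, nl), mean)
    X += rng.normal(0, np.sqrt(var["s"]), (ns, 1, 1))
    X += rng.normal(0, np.sqrt(var["r"]), (1, nr, 1))
    X += rng.normal(0, np.sqrt(var["l"]), (1, 1, nl))
    X += rng.normal(0, np.sqrt(var["sr"]), (ns, nr, 1))
    X += rng.normal(0, np.sqrt(var["sl"]), (ns, 1, nl))
    X += rng.normal(0, np.sqrt(var["rl"]), (1, nr, nl))
    X += rng.normal(0, np.sqrt(var["srl_e"]), (ns, nr, nl))
    return X


def simulate_digitizations(
    spec: SimulationSpec,
    n_subjects: int = 40,
    n_occasions: int = 2,
    digitization_sd: float = 0.5,
    seed: int | None = None,
) -> list[LandmarkDataset]:
    """Repeated landmark digitizations of the same specimens (in mm).

    Draws ``n_subjects`` specimens from the spec's population at a common
    fixed pose, then adds independent isotropic placement error of
    ``digitization_sd`` mm per occasion — the protocol behind the
    intra/inter-rater reliability study.  Feed the result to
    :func:`mandimorph.gstudy.cube_from_datasets`.
    """
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    base = simulate_dataset(spec.with_(seed=int(rng.integers(2**31 - 1))))
    idx = rng.choice(base.n, size=min(n_subjects, base.n), replace=False)
    base = base.subset(np.sort(idx))
    out = []
    for _ in range(n_occasions):
        configs = [
            LandmarkConfiguration(
                c.specimen_id,
                c.coords + rng.normal(0.0, digitization_sd, c.coords.shape),
                c.labels,
            )
            for c in base.configurations
        ]
        out.append(LandmarkDataset(configs, base.metadata.copy()))
    return out


# ---------------------------------------------------------------------------
# Calibration harness
# ---------------------------------------------------------------------------

def calibration_experiment(
    spec: SimulationSpec,
    reps: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
    n_perm: int = 199,
    factor: str = "sex",
) -> dict:
    """Rejection rate of the permutation test over replicate datasets.

    Simulates ``reps`` datasets from ``spec`` (each with its own child
    seed), runs the single-factor Procrustes ANOVA on ``factor`` after a
    fresh GPA, and reports the fraction of p-values at or below ``alpha``
    with a 95% Wilson confidence interval.  Under a null spec this is the
    empirical type-I error; under an effect spec it is power.
    """
    from .gpa import gpa
    from .inference import ProcrustesANOVA

    if reps < 1:
        raise ValueError("reps must be >= 1")
    ss = np.random.SeedSequence(seed if seed is not None else spec.seed)
    children = ss.spawn(reps)
    rejections = 0
    pvals = []
    for child in children:
        s1, s2 = child.generate_state(2) % (2**31 - 1)
        ds = simulate_dataset(spec.with_(seed=int(s1)))
        fit = gpa(ds)
        res = ProcrustesANOVA(fit, [factor]).fit(n_perm=n_perm, seed=int(s2))
        p = res.terms[0]["p_perm"]
        pvals.append(p)
        if p <= alpha:
            rejections += 1
    rate = rejections / reps
    z = 1.959963984540054
    denom = 1 + z**2 / reps
    centre = (rate + z**2 / (2 * reps)) / denom
    half = z * np.sqrt(rate * (1 - rate) / reps + z**2 / (4 * reps**2)) / denom
    return {
        "rejection_rate": rate,
        "ci_low": max(0.0, centre - half),
        "ci_high": min(1.0, centre + half),
        "reps": reps,
        "alpha": alpha,
        "p_values": np.array(pvals),
    }
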