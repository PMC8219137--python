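"""Generalizability-theory reliability of landmark digitization.

The measurement design is fully crossed subject x rater x variable
(``s x r x l``) without replication, the variables being the k(k-1)/2
inter-landmark distances of each digitization (rigid-motion invariant, so
no superimposition enters the reliability analysis).  Variance components
come from the three-way random-effects expected-mean-square equations; the
relative (norm-referenced) G coefficient is
``G = sigma2_s / (sigma2_s + sigma2_sr/n_r + sigma2_sl/n_l + sigma2_srl_e/(n_r n_l))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .io import LandmarkConfiguration, LandmarkDataset

__all__ = [
    "interlandmark_distances",
    "cube_from_datasets",
    "GeneralizabilityStudy",
    "GStudyResults",
]


def interlandmark_distances(config) -> np.ndarray:
    """All k(k-1)/2 unordered inter-landmark Euclidean distances (mm).

    Pair order is the canonical condensed order over the configuration's
    label order.  Invariant to rigid motion of the configuration.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    return pdist(coords)


def pair_labels(labels) -> list[str]:
    labels = list(labels)
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out.append(f"{labels[i]}-{labels[j]}")
    return out


def cube_from_datasets(replicates: list[LandmarkDataset]) -> np.ndarray:
    """Build the (n_s, n_r, n_l) G-study cube from repeated digitizations.

    ``replicates`` holds one dataset per rater/session occasion, all
    covering the same specimens (matched by id) with the same landmarks.
    """
    if len(replicates) < 2:
        raise ValueError("need at least two digitization occasions")
    ids = replicates[0].specimen_ids
    for rep in replicates[1:]:
        if set(rep.specimen_ids) != set(ids):
            raise ValueError("digitization occasions cover different specimens")
    cube = np.empty((len(ids), len(replicates), len(ids) and replicates[0].k * (replicates[0].k - 1) // 2))
    for r, rep in enumerate(replicates):
        lookup = {c.specimen_id: c for c in rep.configurations}
        for s, sid in enumerate(ids):
            cube[s, r] = interlandmark_distances(lookup[sid])
    return cube


@dataclass
class GStudyResults:
    """Variance components and mean squares of the s x r x l design.

    ``components`` holds the truncated-at-zero estimates for s, r, l, sr,
    sl, rl and the confounded srl/error term.  ``g_coefficient`` evaluates
    the relative G for any decision-study facet sizes (defaults: the
    observed design), and is non-decreasing in both.
    """

    components: dict
    mean_squares: dict
    design: tuple  # (n_s, n_r, n_l)

    def relative_error_variance(self, n_r: int | None = None, n_l: int | None = None) -> float:
        _, nr0, nl0 = self.design
        n_r = nr0 if n_r is None else n_r
        n_l = nl0 if n_l is None else n_l
        c = self.components
        return c["sr"] / n_r + c["sl"] / n_l + c["srl_e"] / (n_r * n_l)

    def g_coefficient(self, n_r: int | None = None, n_l: int | None = None) -> float:
        var_s = self.components["s"]
        var_delta = self.relative_error_variance(n_r, n_l)
        denom = var_s + var_delta
        if denom == 0:
            raise ValueError("G undefined: zero subject and error variance")
        return var_s / denom

    def summary(self) -> str:
        n_s, n_r, n_l = self.design
        lines = [
            f"G-study, crossed s x r x l design: {n_s} subjects x {n_r} raters x {n_l} variables",
            "",
            "variance components (negative estimates truncated to 0):",
        ]
        for name in ("s", "r", "l", "sr", "sl", "rl", "srl_e"):
            lines.append(f"  sigma2_{name:<6} = {self.components[name]:.6g}")
        lines += [
            "",
            f"relative error variance sigma2_delta = {self.relative_error_variance():.6g}",
            f"relative G coefficient               = {self.g_coefficient():.4f}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"component": list(self.components), "variance": list(self.components.values())}
        )


class GeneralizabilityStudy:
    """Model object for a crossed s x r x l G-study without replication.

    Parameters
    ----------
    cube : (n_s, n_r, n_l) array
        One measurement per subject x rater x variable cell; no missing
        cells (unbalanced designs are rejected, not estimated).
    """

    def __init__(self, cube: np.ndarray):
        cube = np.asarray(cube, float)
        if cube.ndim != 3:
            raise ValueError("G-study cube must be 3-dimensional (s, r, l)")
        if not np.all(np.isfinite(cube)):
            raise ValueError("G-study cube has missing cells; crossed design required")
        if min(cube.shape) < 2:
            raise ValueError("each facet needs at least 2 levels")
        self.cube = cube

    def fit(self) -> GStudyResults:
        X = self.cube
        ns, nr, nl = X.shape
        grand = X.mean()
        ms_ = X.mean(axis=(1, 2))
        mr_ = X.mean(axis=(0, 2))
        ml_ = X.mean(axis=(0, 1))
        msr = X.mean(axis=2)
        msl = X.mean(axis=1)
        mrl = X.mean(axis=0)

        ss_s = nr * nl * np.sum((ms_ - grand) ** 2)
        ss_r = ns * nl * np.sum((mr_ - grand) ** 2)
        ss_l = ns * nr * np.sum((ml_ - grand) ** 2)
        ss_sr = nl * np.sum((msr - ms_[:, None] - mr_[None, :] + grand) ** 2)
        ss_sl = nr * np.sum((msl - ms_[:, None] - ml_[None, :] + grand) ** 2)
        ss_rl = ns * np.sum((mrl - mr_[:, None] - ml_[None, :] + grand) ** 2)
        resid = (
            X
            - msr[:, :, None] - msl[:, None, :] - mrl[None, :, :]
            + ms_[:, None, None] + mr_[None, :, None] + ml_[None, None, :]
            - grand
        )
        ss_srl = np.sum(resid**2)

        ms = {
            "s": ss_s / (ns - 1),
            "r": ss_r / (nr - 1),
            "l": ss_l / (nl - 1),
            "sr": ss_sr / ((ns - 1) * (nr - 1)),
            "sl": ss_sl / ((ns - 1) * (nl - 1)),
            "rl": ss_rl / ((nr - 1) * (nl - 1)),
            "srl_e": ss_srl / ((ns - 1) * (nr - 1) * (nl - 1)),
        }
        raw = {
            "srl_e": ms["srl_e"],
            "sr": (ms["sr"] - ms["srl_e"]) / nl,
            "sl": (ms["sl"] - ms["srl_e"]) / nr,
            "rl": (ms["rl"] - ms["srl_e"]) / ns,
            "s": (ms["s"] - ms["sr"] - ms["sl"] + ms["srl_e"]) / (nr * nl),
            "r": (ms["r"] - ms["sr"] - ms["rl"] + ms["srl_e"]) / (ns * nl),
            "l": (ms["l"] - ms["sl"] - ms["rl"] + ms["srl_e"]) / (ns * nr),
        }
        components = {k: max(0.0, float(v)) for k, v in raw.items()}
        return GStudyResults(components, {k: float(v) for k, v in ms.items()}, (ns, nr, nl))
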