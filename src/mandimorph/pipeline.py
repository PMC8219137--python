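"""End-to-end analysis driver.

``run_full_analysis`` executes the whole study on one dataset — sample
summary, cut-off cohort tests, shape models, sex distances (whole sample
and two 20-year age groups), the four-cohort distance matrix, aging-rate
curves, PCA scores and wireframe figures — writing every table as CSV with
4-decimal formatting plus a run log.  Deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aging as _aging
from .gpa import gpa, mean_shape
from .inference import ProcrustesANOVA, group_distance, shape_pca
from .io import LandmarkDataset, validate_dataset
from .wireframe import Wireframe, render_comparison

__all__ = ["RunConfig", "run_full_analysis"]

log = logging.getLogger("mandimorph")


@dataclass
class RunConfig:
    """Configuration of a full analysis run (echoed into the output dir)."""

    out_dir: str
    seed: int
    n_perm: int = 999
    cutoffs: tuple = (55, 60, 65)
    sex_cutoffs: dict = field(default_factory=lambda: {"F": 55, "M": 65})
    window: int = 20
    age_groups: tuple = ((40, 59), (60, 79))
    shape_design: str = "sex + age + sex:age"
    size_design: str = "size + sex + size:sex"
    paper_replication: bool = True

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["cutoffs"] = list(d["cutoffs"])
        d["age_groups"] = [list(g) for g in d["age_groups"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["cutoffs"] = tuple(d["cutoffs"])
        d["age_groups"] = tuple(tuple(g) for g in d["age_groups"])
        return cls(**d)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=True, float_format="%.4f")


def run_full_analysis(dataset: LandmarkDataset, config: RunConfig) -> dict:
    """Run every stage of the study on ``dataset``; returns artifact paths.

    Any stage failure aborts with the stage name and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    seeds = iter(np.random.SeedSequence(config.seed).generate_state(16) % (2**31 - 1))
    artifacts: dict[str, Path] = {}
    t0 = time.time()
    config.to_yaml(out / "run_config.yaml")
    artifacts["config"] = out / "run_config.yaml"
    stage = "validate"
    try:
        log.info("stage %s", stage)
        report = validate_dataset(dataset, paper_replication=config.paper_replication)
        _write(report.counts, out / "sample_summary.csv")
        artifacts["sample_summary"] = out / "sample_summary.csv"
        if report.violations:
            log.warning("validation violations: %s", report.violations)

        stage = "cutoff_tests"
        log.info("stage %s", stage)
        table3 = _aging.cutoff_cohort_tests(
            dataset, config.cutoffs, n_perm=config.n_perm, seed=int(next(seeds))
        )
        table3.to_csv(out / "cutoff_tests.csv", index=False, float_format="%.4f")
        artifacts["cutoff_tests"] = out / "cutoff_tests.csv"

        stage = "gpa"
        log.info("stage %s", stage)
        fit = gpa(dataset)

        stage = "pca"
        log.info("stage %s", stage)
        pca = shape_pca(fit)
        scores = pd.DataFrame(
            pca.scores[:, : min(10, pca.q)],
            columns=[f"PC{i + 1}" for i in range(min(10, pca.q))],
        )
        scores.insert(0, "specimen_id", fit.specimen_ids)
        scores.to_csv(out / "pca_scores.csv", index=False, float_format="%.6f")
        pd.DataFrame({
            "component": [f"PC{i + 1}" for i in range(pca.q)],
            "eigenvalue": pca.eigenvalues,
            "pct_variance": pca.pct_variance,
        }).to_csv(out / "pca_variance.csv", index=False, float_format="%.4f")
        artifacts["pca_scores"] = out / "pca_scores.csv"
        artifacts["pca_variance"] = out / "pca_variance.csv"

        stage = "shape_models"
        log.info("stage %s", stage)
        rows = []
        for model_name, design in (
            ("shape~sex+age", config.shape_design),
            ("shape~size+sex", config.size_design),
        ):
            res = ProcrustesANOVA(fit, design).fit(
                n_perm=config.n_perm, seed=int(next(seeds))
            )
            for t in res.terms:
                rows.append({"model": model_name, "term": t["name"], "df": t["df"],
                             "goodall_F": t["F"], "p_perm": t["p_perm"]})
        pd.DataFrame(rows).to_csv(out / "model_terms.csv", index=False, float_format="%.4f")
        artifacts["model_terms"] = out / "model_terms.csv"

        stage = "sex_distances"
        log.info("stage %s", stage)
        ages = dataset.metadata["age"].to_numpy(int)
        drows = []
        for name, mask in [("whole sample", np.ones(dataset.n, bool))] + [
            (f"{lo}-{hi}", (ages >= lo) & (ages <= hi)) for lo, hi in config.age_groups
        ]:
            sub = dataset.subset(mask)
            gd = group_distance(
                gpa(sub), "sex", n_perm=config.n_perm, seed=int(next(seeds))
            )
            drows.append({
                "group": f"{name} (F/M)",
                "mahalanobis_distance": gd.mahalanobis_distance,
                "procrustes_distance": gd.procrustes_distance,
                "goodall_F": gd.goodall_F,
                "p_perm": gd.p_perm,
                "q_used": gd.q_used,
            })
        pd.DataFrame(drows).to_csv(out / "sex_distances.csv", index=False, float_format="%.4f")
        artifacts["sex_distances"] = out / "sex_distances.csv"

        stage = "cohort_distances"
        log.info("stage %s", stage)
        icd = _aging.intercohort_distances(
            dataset, config.sex_cutoffs, n_perm=config.n_perm, seed=int(next(seeds))
        )
        _write(icd.distances, out / "cohort_distance_matrix.csv")
        _write(icd.p_values, out / "cohort_distance_pvalues.csv")
        artifacts["cohort_distances"] = out / "cohort_distance_matrix.csv"

        stage = "aging_rate"
        log.info("stage %s", stage)
        curves = pd.concat(
            [_aging.aging_rate_curve(dataset, s, config.window).to_frame() for s in "MF"]
        )
        curves.to_csv(out / "aging_rate.csv", index=False, float_format="%.6f")
        artifacts["aging_rate"] = out / "aging_rate.csv"

        stage = "wireframes"
        log.info("stage %s", stage)
        wf = Wireframe()
        sexes = dataset.metadata["sex"].to_numpy()
        for sex in "MF":
            cut = config.sex_cutoffs[sex]
            sub = dataset.subset(sexes == sex)
            sfit = gpa(sub)
            young = sub.metadata["age"].to_numpy(int) < cut
            ma = mean_shape(sfit, young)
            mb = mean_shape(sfit, ~young)
            for view in ("lateral", "anterior"):
                path = out / f"wireframe_{sex}_{view}.svg"
                render_comparison(
                    ma, mb, wf, view=view, out=path,
                    title=f"{sex}: age<{cut} solid vs age>={cut} dashed, arrows x3",
                )
                artifacts[f"wireframe_{sex}_{view}"] = path
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"analysis stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    log.info("completed in %.1f s", time.time() - t0)
    return artifacts
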