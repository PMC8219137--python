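"""Landmark file input/output and dataset assembly.

Datasets couple one :class:`LandmarkConfiguration` per specimen (a ``k x 3``
coordinate matrix in mm with named landmarks) with a covariate table (sex,
age, optional rater/session).  Supported on-disk formats are long and wide
CSV layouts and the 3D (``LM3``) dialect of the TPS landmark format.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_LANDMARK_LABELS",
    "LandmarkConfiguration",
    "LandmarkDataset",
    "ValidationReport",
    "read_landmark_table",
    "write_landmark_table",
    "read_tps",
    "write_tps",
    "attach_metadata",
    "validate_dataset",
]

#: Canonical 14 mandibular landmarks: bilateral condylion superior (Cs),
#: mandibular notch (Mn), coronion (Co), gonion (Go) and mentale (Ml) pairs,
#: plus the midline infradentale (Id), mandibular symphysis (Mns),
#: pogonion (Pg) and gnathion (Gn).
DEFAULT_LANDMARK_LABELS: tuple[str, ...] = (
    "Cs_L", "Cs_R", "Mn_L", "Mn_R", "Co_L", "Co_R", "Go_L", "Go_R",
    "Ml_L", "Ml_R", "Id", "Mns", "Pg", "Gn",
)

PAPER_AGE_RANGE = (40, 79)


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's landmark coordinates.

    Parameters
    ----------
    specimen_id : str
    coords : (k, 3) float array, mm
    labels : sequence of k unique landmark names
    """

    specimen_id: str
    coords: np.ndarray
    labels: tuple[str, ...] = DEFAULT_LANDMARK_LABELS

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "labels", tuple(self.labels))
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(
                f"specimen {self.specimen_id!r}: coords must be (k, 3), got {coords.shape}"
            )
        k = coords.shape[0]
        if k < 3:
            raise ValueError(f"specimen {self.specimen_id!r}: need k >= 3 landmarks, got {k}")
        if len(self.labels) != k:
            raise ValueError(
                f"specimen {self.specimen_id!r}: {len(self.labels)} labels for {k} landmarks"
            )
        if len(set(self.labels)) != k:
            raise ValueError(f"specimen {self.specimen_id!r}: duplicate landmark labels")
        if not np.all(np.isfinite(coords)):
            bad = [self.labels[i] for i in np.unique(np.argwhere(~np.isfinite(coords))[:, 0])]
            raise ValueError(
                f"specimen {self.specimen_id!r}: missing/non-finite coordinates at "
                f"landmark(s) {', '.join(bad)}"
            )

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def reordered(self, labels: Sequence[str]) -> "LandmarkConfiguration":
        """Return a copy with rows permuted into the given label order."""
        if set(labels) != set(self.labels):
            missing = sorted(set(labels) - set(self.labels))
            extra = sorted(set(self.labels) - set(labels))
            raise ValueError(
                f"specimen {self.specimen_id!r}: landmark set mismatch "
                f"(missing {missing}, unexpected {extra})"
            )
        idx = [self.labels.index(lb) for lb in labels]
        return LandmarkConfiguration(self.specimen_id, self.coords[idx], tuple(labels))


class LandmarkDataset:
    """An ordered collection of configurations plus per-specimen covariates.

    All configurations share ``k`` and landmark label order (later specimens
    are re-ordered by label to match the first).  ``metadata`` is a DataFrame
    indexed like ``configurations`` with at least ``specimen_id``; analyses
    requiring sex/age validate their presence themselves.
    """

    def __init__(
        self,
        configurations: Iterable[LandmarkConfiguration],
        metadata: pd.DataFrame | None = None,
    ):
        configs = list(configurations)
        if configs:
            canonical = configs[0].labels
            configs = [
                c if c.labels == canonical else c.reordered(canonical) for c in configs
            ]
            ks = {c.k for c in configs}
            if len(ks) != 1:
                raise ValueError(f"inconsistent landmark counts across specimens: {sorted(ks)}")
        ids = [c.specimen_id for c in configs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate specimen ids: {dupes}")
        self.configurations = configs
        if metadata is None:
            metadata = pd.DataFrame({"specimen_id": ids})
        else:
            metadata = metadata.reset_index(drop=True).copy()
            if list(metadata["specimen_id"]) != ids:
                raise ValueError("metadata order/ids do not match configurations")
        self.metadata = metadata

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.configurations)

    @property
    def k(self) -> int:
        return self.configurations[0].k if self.configurations else 0

    @property
    def labels(self) -> tuple[str, ...]:
        return self.configurations[0].labels if self.configurations else ()

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def coords_array(self) -> np.ndarray:
        """Stack coordinates into an (n, k, 3) array."""
        return np.stack([c.coords for c in self.configurations])

    def subset(self, mask_or_index) -> "LandmarkDataset":
        """Row-subset by boolean mask or integer index array (order kept)."""
        idx = np.arange(self.n)[np.asarray(mask_or_index)]
        configs = [self.configurations[i] for i in idx]
        meta = self.metadata.iloc[idx].reset_index(drop=True)
        return LandmarkDataset(configs, meta)

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:
        return f"<LandmarkDataset n={self.n} k={self.k}>"


# ---------------------------------------------------------------------------
# CSV layouts
# ---------------------------------------------------------------------------

def read_landmark_table(path, layout: str = "long") -> LandmarkDataset:
    """Read a landmark CSV in ``long`` or ``wide`` layout.

    Long layout columns: ``specimen_id, landmark, x, y, z``.  Wide layout:
    one row per specimen, ``specimen_id`` plus ``<label>_x/_y/_z`` columns.
    Coordinates pass through unchanged (mm assumed).  Missing cells raise,
    naming the specimen and landmark.
    """
    if layout == "long":
        df = pd.read_csv(path)
        required = {"specimen_id", "landmark", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise ValueError(f"long layout needs columns {sorted(required)}")
        configs = []
        for sid, grp in df.groupby("specimen_id", sort=False):
            coords = grp[["x", "y", "z"]].to_numpy(dtype=float)
            labels = tuple(str(lb) for lb in grp["landmark"])
            bad = np.argwhere(~np.isfinite(coords))
            if bad.size:
                lm = labels[bad[0, 0]]
                raise ValueError(f"specimen {sid!r}: missing coordinate at landmark {lm!r}")
            configs.append(LandmarkConfiguration(str(sid), coords, labels))
        return LandmarkDataset(configs)
    elif layout == "wide":
        df = pd.read_csv(path)
        if "specimen_id" not in df.columns:
            raise ValueError("wide layout needs a specimen_id column")
        coord_cols = [c for c in df.columns if c.endswith(("_x", "_y", "_z"))]
        labels = []
        for c in coord_cols:
            lb = c[:-2]
            if lb not in labels:
                labels.append(lb)
        for lb in labels:
            for ax in "xyz":
                if f"{lb}_{ax}" not in df.columns:
                    raise ValueError(f"wide layout: missing column {lb}_{ax}")
        configs = []
        for _, row in df.iterrows():
            sid = str(row["specimen_id"])
            coords = np.empty((len(labels), 3))
            for i, lb in enumerate(labels):
                for j, ax in enumerate("xyz"):
                    v = row[f"{lb}_{ax}"]
                    if pd.isna(v):
                        raise ValueError(
                            f"specimen {sid!r}: missing coordinate at landmark {lb!r}"
                        )
                    coords[i, j] = float(v)
            configs.append(LandmarkConfiguration(sid, coords, tuple(labels)))
        return LandmarkDataset(configs)
    raise ValueError(f"unknown layout {layout!r} (expected 'long' or 'wide')")


def write_landmark_table(dataset: LandmarkDataset, path, layout: str = "long") -> None:
    """Write a dataset to CSV in ``long`` or ``wide`` layout."""
    if layout == "long":
        rows = []
        for c in dataset.configurations:
            for lb, xyz in zip(c.labels, c.coords):
                rows.append((c.specimen_id, lb, *xyz))
        pd.DataFrame(rows, columns=["specimen_id", "landmark", "x", "y", "z"]).to_csv(
            path, index=False
        )
    elif layout == "wide":
        cols: dict[str, list] = {"specimen_id": dataset.specimen_ids}
        for i, lb in enumerate(dataset.labels):
            for j, ax in enumerate("xyz"):
                cols[f"{lb}_{ax}"] = [c.coords[i, j] for c in dataset.configurations]
        pd.DataFrame(cols).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# TPS (LM3 dialect)
# ---------------------------------------------------------------------------

def read_tps(path) -> LandmarkDataset:
    """Read a 3D TPS file (``LM3=k`` records, optional ``ID=`` lines).

    2D ``LM=`` records are rejected — this reader handles the 3D dialect
    only.  A record whose row count disagrees with its LM3 header raises.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    configs = []
    i, rec = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        upper = line.upper()
        if upper.startswith("LM3="):
            k = int(line.split("=", 1)[1])
            rows = []
            i += 1
            while i < len(lines) and len(rows) < k:
                s = lines[i].strip()
                if not s or "=" in s:
                    break
                rows.append([float(v) for v in s.split()])
                i += 1
            if len(rows) != k:
                raise ValueError(f"TPS record {rec}: LM3={k} but {len(rows)} coordinate rows")
            if any(len(r) != 3 for r in rows):
                raise ValueError(f"TPS record {rec}: expected 3 coordinates per row")
            sid = str(rec)
            # optional trailing keyword lines (ID=, IMAGE=, SCALE=)
            while i < len(lines):
                s = lines[i].strip()
                if s.upper().startswith("ID="):
                    sid = s.split("=", 1)[1].strip()
                    i += 1
                elif "=" in s and not s.upper().startswith(("LM3=", "LM=")):
                    i += 1
                else:
                    break
            labels = tuple(f"L{j + 1}" for j in range(k))
            configs.append(LandmarkConfiguration(sid, np.array(rows), labels))
            rec += 1
        elif upper.startswith("LM="):
            raise ValueError("2D TPS record (LM=) found: this reader requires 3D (LM3=) records")
        else:
            i += 1
    return LandmarkDataset(configs)


def write_tps(dataset: LandmarkDataset, path) -> None:
    """Write a dataset as 3D TPS records (landmark labels are not stored)."""
    buf = _stdio.StringIO()
    for c in dataset.configurations:
        buf.write(f"LM3={c.k}\n")
        for xyz in c.coords:
            buf.write(" ".join(repr(float(v)) for v in xyz) + "\n")
        buf.write(f"ID={c.specimen_id}\n")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def attach_metadata(dataset: LandmarkDataset, metadata) -> LandmarkDataset:
    """Join a covariate table (CSV path or DataFrame) onto a dataset.

    The table needs ``specimen_id, sex, age`` and may carry ``rater`` and
    ``session``.  Ids must match one-to-one; mismatches in either direction
    raise listing the offending ids.
    """
    meta = metadata if isinstance(metadata, pd.DataFrame) else pd.read_csv(metadata)
    meta = meta.copy()
    if "specimen_id" not in meta.columns:
        raise ValueError("metadata needs a specimen_id column")
    meta["specimen_id"] = meta["specimen_id"].astype(str)
    if meta["specimen_id"].duplicated().any():
        dupes = sorted(meta.loc[meta["specimen_id"].duplicated(), "specimen_id"].unique())
        raise ValueError(f"duplicated specimen_id in metadata: {dupes}")
    ids = dataset.specimen_ids
    missing = sorted(set(ids) - set(meta["specimen_id"]))
    extra = sorted(set(meta["specimen_id"]) - set(ids))
    if missing or extra:
        raise ValueError(
            f"metadata/configuration id mismatch: missing from metadata {missing}, "
            f"unmatched metadata rows {extra}"
        )
    meta = meta.set_index("specimen_id").loc[ids].reset_index()
    if "sex" in meta.columns:
        meta["sex"] = meta["sex"].astype(str).str.upper().str[0]
    if "age" in meta.columns:
        meta["age"] = meta["age"].astype(int)
    return LandmarkDataset(dataset.configurations, meta)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    n: int
    k: int
    counts: pd.DataFrame  # sex x 5-year age bin
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        lines = [f"n = {self.n}, k = {self.k}", "", str(self.counts)]
        if self.violations:
            lines += ["", "violations:"] + [f"  - {v}" for v in self.violations]
        else:
            lines += ["", "no violations"]
        return "\n".join(lines)


def validate_dataset(
    dataset: LandmarkDataset,
    paper_replication: bool = False,
    age_range: tuple[int, int] | None = None,
    bin_width: int = 5,
) -> ValidationReport:
    """Report sample composition (n per sex per 5-year age bin) and problems.

    Pure function: never mutates the dataset.  ``paper_replication`` enforces
    the 40-79-year study design age range.
    """
    violations: list[str] = []
    n, k = dataset.n, dataset.k
    if n == 0:
        return ValidationReport(0, 0, pd.DataFrame(), ["empty dataset (n = 0)"])
    meta = dataset.metadata
    if age_range is None and paper_replication:
        age_range = PAPER_AGE_RANGE
    have_sex = "sex" in meta.columns and meta["sex"].notna().all()
    have_age = "age" in meta.columns and meta["age"].notna().all()
    if not have_sex:
        violations.append("sex missing for some or all specimens")
    if not have_age:
        violations.append("age missing for some or all specimens")
    counts = pd.DataFrame()
    if have_sex and have_age:
        ages = meta["age"].astype(int)
        if age_range is not None:
            out = meta.loc[(ages < age_range[0]) | (ages > age_range[1]), "specimen_id"]
            for sid in out:
                violations.append(
                    f"specimen {sid!r}: age outside [{age_range[0]}, {age_range[1]}]"
                )
        lo = (ages.min() // bin_width) * bin_width
        hi = ages.max() + 1
        edges = list(range(lo, hi + bin_width, bin_width))
        bins = pd.cut(
            ages, edges, right=False,
            labels=[f"{e}-{e + bin_width - 1}" for e in edges[:-1]],
        )
        counts = (
            pd.crosstab(bins, meta["sex"])
            .rename_axis(index="age_group", columns="sex")
        )
    if have_sex:
        bad_sex = sorted(set(meta["sex"]) - {"M", "F"})
        if bad_sex:
            violations.append(f"unrecognized sex codes: {bad_sex}")
    return ValidationReport(n, k, counts, violations)
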