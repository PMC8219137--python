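"""Statistics on superimposed shapes.

Tangent-space PCA, Procrustes ANOVA with Goodall's F assessed by
permutation (residual randomization, RRPP), and between-group Procrustes /
Mahalanobis distances.  The ANOVA follows the statsmodels model/results
convention: build a :class:`ProcrustesANOVA` from a Procrustes fit and a
design, call ``.fit()``, read the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gpa import ProcrustesFit, mean_shape, procrustes_distance

__all__ = [
    "TangentScores",
    "shape_pca",
    "ProcrustesANOVA",
    "ProcrustesAnovaResults",
    "procrustes_anova",
    "goodall_f_two_sample",
    "mahalanobis_shape_distance",
    "GroupDistanceResult",
    "group_distance",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class TangentScores:
    """Principal components of the aligned (tangent-space) coordinates."""

    scores: np.ndarray       # (n, q)
    loadings: np.ndarray     # (q, 3k), rows are unit component vectors
    eigenvalues: np.ndarray  # (q,)
    pct_variance: np.ndarray  # (q,), sums to 100 over the retained rank
    mean: np.ndarray         # (3k,) column means removed before the SVD

    @property
    def q(self) -> int:
        return self.scores.shape[1]


def shape_pca(fit: ProcrustesFit) -> TangentScores:
    """SVD-based PCA of the column-centred flattened aligned coordinates.

    Components with eigenvalue below ``1e-12`` of the leading one are
    dropped, so the scores and loadings reproduce the centred data exactly.
    Centering makes three directions exactly null; the four further
    superimposition directions (scale and rotations) are only first-order
    null and keep tiny genuine variance, so the retained rank is
    ``min(n - 1, 3k - 3)`` rather than the theoretical shape-space
    dimension ``3k - 7`` (which an exact tangent projection would give).
    """
    n = fit.n
    if n < 3:
        raise ValueError("shape PCA requires n >= 3 specimens")
    X = fit.flattened()
    mu = X.mean(axis=0)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ev = s**2 / (n - 1)
    keep = (ev > 1e-12 * ev[0]) & (np.arange(ev.size) < n - 1)
    U, s, Vt, ev = U[:, keep], s[keep], Vt[keep], ev[keep]
    pct = 100.0 * ev / ev.sum()
    return TangentScores(U * s, Vt, ev, pct, mu)


# ---------------------------------------------------------------------------
# Design matrices (sequential term blocks)
# ---------------------------------------------------------------------------

def _parse_design(design) -> list[str]:
    if isinstance(design, str):
        rhs = design.split("~", 1)[-1]
        terms = [t.strip() for t in rhs.split("+") if t.strip()]
    else:
        terms = [str(t).strip() for t in design]
    if not terms:
        raise ValueError("empty design")
    return terms


def _variable_column(name: str, fit: ProcrustesFit) -> pd.Series:
    if name == "size":
        return pd.Series(fit.centroid_sizes, name="size")
    if name in fit.metadata.columns:
        return fit.metadata[name]
    raise ValueError(f"unknown design variable {name!r}")


def _encode(var: pd.Series) -> tuple[np.ndarray, bool]:
    """Return (columns, is_categorical); dummy coding drops the first level."""
    if pd.api.types.is_numeric_dtype(var):
        return var.to_numpy(float)[:, None], False
    levels = sorted(pd.unique(var.astype(str)))
    if len(levels) < 2:
        raise ValueError(f"factor {var.name!r} is constant (needs >= 2 levels)")
    cols = np.column_stack([(var.astype(str) == lv).astype(float) for lv in levels[1:]])
    return cols, True


def build_term_blocks(terms: list[str], fit: ProcrustesFit) -> list[tuple[str, np.ndarray]]:
    """One design-matrix block per term; interactions are column products."""
    blocks = []
    for term in terms:
        parts = [p.strip() for p in term.split(":")]
        mats = [_encode(_variable_column(p, fit))[0] for p in parts]
        block = mats[0]
        for m in mats[1:]:
            block = np.einsum("ni,nj->nij", block, m).reshape(len(m), -1)
        blocks.append((term, block))
    return blocks


# ---------------------------------------------------------------------------
# Procrustes ANOVA (Goodall's F with RRPP permutation)
# ---------------------------------------------------------------------------

@dataclass
class ProcrustesAnovaResults:
    """Sequential (Type I) Procrustes ANOVA table with permutation p-values.

    Sums of squares are summed squared Euclidean deviations of the
    flattened aligned coordinates under nested least-squares fits;
    ``F = MS_term / MS_residual`` is Goodall's F generalized to the
    sequential design, and ``p_perm`` is the proportion of observed-plus-
    permuted statistics at least as large as the observed one.
    """

    terms: list = field(default_factory=list)
    residual: dict = field(default_factory=dict)
    total_ss: float = 0.0
    n_perm: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t["name"], "df": t["df"], "SS": t["SS"], "MS": t["MS"],
             "F": t["F"], "p_perm": t["p_perm"]}
            for t in self.terms
        ]
        rows.append({"term": "Residual", "df": self.residual["df"],
                     "SS": self.residual["SS"], "MS": self.residual["MS"],
                     "F": np.nan, "p_perm": np.nan})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        with pd.option_context("display.float_format", lambda v: f"{v:.4f}"):
            table = df.to_string(index=False)
        return (
            "Procrustes ANOVA (Goodall's F, RRPP permutation)\n"
            f"permutations: {self.n_perm}, seed: {self.seed}\n\n{table}\n"
        )

    def term(self, name: str) -> dict:
        for t in self.terms:
            if t["name"] == name:
                return t
        raise KeyError(name)


class ProcrustesANOVA:
    """Model object for a sequential Procrustes ANOVA on aligned shapes.

    Parameters
    ----------
    fit : ProcrustesFit
        Superimposed sample; metadata supplies the design variables
        (``size`` resolves to centroid size).
    design : str or list of str
        Term list in order, e.g. ``"sex + age + sex:age"`` (an optional
        ``"shape ~"`` left side is accepted and ignored).

    Notes
    -----
    Permutation uses residual randomization of the reduced model (RRPP):
    for each term the residuals of the model containing all preceding
    terms are row-permuted and added back to the reduced fitted values.
    For a single-factor design this coincides with raw label shuffling.
    """

    def __init__(self, fit: ProcrustesFit, design):
        self.procrustes_fit = fit
        self.terms = _parse_design(design)
        self.blocks = build_term_blocks(self.terms, fit)
        self.Y = fit.flattened()
        n = self.Y.shape[0]
        # nested orthonormal bases: Q[i] spans intercept + blocks[:i]
        X = np.ones((n, 1))
        self._bases = []
        self._dfs = []
        Q, _ = np.linalg.qr(X)
        rank = 1
        self._bases.append(Q)
        for name, block in self.blocks:
            X = np.hstack([X, block])
            Q, R = np.linalg.qr(X)
            newrank = int(np.sum(np.abs(np.diag(R)) > 1e-9 * max(1.0, np.abs(R).max())))
            # drop numerically dependent columns from the basis
            keep = np.abs(np.diag(R)) > 1e-9 * max(1.0, np.abs(R).max())
            Q = Q[:, keep]
            df = newrank - rank
            if df < 1:
                raise ValueError(f"term {name!r} adds no rank (constant or aliased factor)")
            self._dfs.append(df)
            self._bases.append(Q)
            rank = newrank
        self._rank_full = rank
        self._df_res = n - rank
        if self._df_res < 1:
            raise ValueError("saturated design: no residual degrees of freedom")

    def _stats(self, Y: np.ndarray) -> tuple[np.ndarray, float]:
        """Sequential term SS and full-model residual SS for response Y."""
        total = float(np.sum(Y * Y))
        fitted = [float(np.sum((Q.T @ Y) ** 2)) for Q in self._bases]
        ss_terms = np.diff(fitted)
        rss_full = total - fitted[-1]
        return ss_terms, rss_full

    def fit(self, n_perm: int = 999, seed: int | None = None) -> ProcrustesAnovaResults:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        Y = self.Y
        n = Y.shape[0]
        ss_obs, rss_obs = self._stats(Y)
        dfs = np.array(self._dfs, float)
        ms_res = rss_obs / self._df_res
        F_obs = (ss_obs / dfs) / ms_res

        exceed = np.zeros(len(self.terms))
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        for i in range(len(self.terms)):
            Qred = self._bases[i]
            fitted_red = Qred @ (Qred.T @ Y)
            resid_red = Y - fitted_red
            Fi = np.empty(n_perm)
            for b in range(n_perm):
                Yb = fitted_red + resid_red[perms[b]]
                ssb, rssb = self._stats(Yb)
                Fi[b] = (ssb[i] / dfs[i]) / (rssb / self._df_res)
            exceed[i] = np.sum(Fi >= F_obs[i] - 1e-12)
        p = (1.0 + exceed) / (1.0 + n_perm)

        res = ProcrustesAnovaResults(
            terms=[
                {"name": name, "SS": float(ss_obs[i]), "df": int(dfs[i]),
                 "MS": float(ss_obs[i] / dfs[i]), "F": float(F_obs[i]),
                 "p_perm": float(p[i])}
                for i, (name, _) in enumerate(self.blocks)
            ],
            residual={"SS": float(rss_obs), "df": int(self._df_res),
                      "MS": float(ms_res)},
            total_ss=float(ss_obs.sum() + rss_obs),
            n_perm=n_perm, seed=seed,
        )
        return res


def procrustes_anova(
    fit: ProcrustesFit, design, n_perm: int = 999, seed: int | None = None
) -> ProcrustesAnovaResults:
    """Functional wrapper: ``ProcrustesANOVA(fit, design).fit(...)``."""
    return ProcrustesANOVA(fit, design).fit(n_perm=n_perm, seed=seed)


def goodall_f_two_sample(fit: ProcrustesFit, labels) -> float:
    """Classical two-sample Goodall F from group means of aligned shapes.

    ``F = [d^2(m1, m2) / (1/n1 + 1/n2)] / [SS_within / (n1 + n2 - 2)]``
    with ``d`` the Euclidean distance between the group mean configurations
    in the common superimposition (the tangent-space metric under which the
    sequential ANOVA decomposition is exact).
    """
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if levels.size != 2:
        raise ValueError("two-sample Goodall F needs exactly two groups")
    Y = fit.flattened()
    g1, g2 = (labels == levels[0]), (labels == levels[1])
    n1, n2 = int(g1.sum()), int(g2.sum())
    m1, m2 = Y[g1].mean(axis=0), Y[g2].mean(axis=0)
    d2 = float(np.sum((m1 - m2) ** 2))
    ssw = float(np.sum((Y[g1] - m1) ** 2) + np.sum((Y[g2] - m2) ** 2))
    return (d2 / (1.0 / n1 + 1.0 / n2)) / (ssw / (n1 + n2 - 2))


# ---------------------------------------------------------------------------
# Group distances
# ---------------------------------------------------------------------------

def mahalanobis_shape_distance(scores: TangentScores, labels, q="auto") -> tuple[float, int]:
    """Mahalanobis distance between two group centroids on the first q PCs.

    ``D = sqrt((mu1 - mu2)^T S_pooled^{-1} (mu1 - mu2))`` with the pooled
    within-group covariance on the retained component scores.  ``q='auto'``
    keeps the largest q with pooled-covariance condition number below 1e8
    and ``q <= n - 4``.  Returns ``(D, q_used)``.
    """
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if levels.size != 2:
        raise ValueError("Mahalanobis shape distance needs exactly two groups")
    g1, g2 = (labels == levels[0]), (labels == levels[1])
    n1, n2 = int(g1.sum()), int(g2.sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2 for a within-group covariance")
    S = scores.scores
    n = S.shape[0]
    qcap = min(S.shape[1], n - 4)
    if qcap < 1:
        raise ValueError("not enough specimens for any Mahalanobis dimension")

    def pooled(qq):
        s1, s2 = S[g1, :qq], S[g2, :qq]
        c1 = np.cov(s1, rowvar=False).reshape(qq, qq)
        c2 = np.cov(s2, rowvar=False).reshape(qq, qq)
        return ((n1 - 1) * c1 + (n2 - 1) * c2) / (n1 + n2 - 2)

    if q == "auto":
        q_used = 1
        for qq in range(qcap, 0, -1):
            Sp = pooled(qq)
            if np.linalg.cond(Sp) < 1e8:
                q_used = qq
                break
    else:
        q_used = int(q)
        if q_used > S.shape[1]:
            raise ValueError(f"q={q_used} exceeds available components ({S.shape[1]})")
    Sp = pooled(q_used)
    diff = S[g1, :q_used].mean(axis=0) - S[g2, :q_used].mean(axis=0)
    try:
        sol = np.linalg.solve(Sp, diff)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"singular pooled covariance at q={q_used}; request a smaller q"
        ) from exc
    if np.linalg.cond(Sp) > 1e12:
        raise ValueError(f"singular pooled covariance at q={q_used}; request a smaller q")
    return float(np.sqrt(max(0.0, diff @ sol))), q_used


@dataclass
class GroupDistanceResult:
    """Between-group shape separation summary (one two-level factor)."""

    group_a: str
    group_b: str
    procrustes_distance: float
    mahalanobis_distance: float
    goodall_F: float
    p_perm: float
    q_used: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "groups": f"{self.group_a}/{self.group_b}",
            "mahalanobis_distance": self.mahalanobis_distance,
            "procrustes_distance": self.procrustes_distance,
            "goodall_F": self.goodall_F,
            "p_perm": self.p_perm,
            "q_used": self.q_used,
        }])


def group_distance(
    fit: ProcrustesFit,
    grouping,
    n_perm: int = 999,
    seed: int | None = None,
    q="auto",
) -> GroupDistanceResult:
    """Procrustes + Mahalanobis distance and Goodall's F between two groups.

    ``grouping`` is a metadata column name or an explicit label vector.
    The Procrustes distance is the full Procrustes distance between the
    group mean shapes; the Mahalanobis distance is computed on tangent PC
    scores; F and its permutation p come from the single-factor ANOVA.
    """
    if isinstance(grouping, str):
        labels = fit.metadata[grouping].to_numpy()
        colname = grouping
    else:
        labels = np.asarray(grouping)
        colname = "_group"
        fit = ProcrustesFit(**{**fit.__dict__})
        fit.metadata = fit.metadata.copy()
        fit.metadata[colname] = labels
    levels = np.unique(labels)
    if levels.size != 2:
        raise ValueError("group_distance needs exactly a two-level factor")
    ma = mean_shape(fit, labels == levels[0])
    mb = mean_shape(fit, labels == levels[1])
    pd_full = procrustes_distance(ma, mb, "full")
    D, q_used = mahalanobis_shape_distance(shape_pca(fit), labels, q=q)
    res = ProcrustesANOVA(fit, [colname]).fit(n_perm=n_perm, seed=seed)
    t = res.terms[0]
    return GroupDistanceResult(
        str(levels[0]), str(levels[1]), pd_full, D, t["F"], t["p_perm"], q_used
    )
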