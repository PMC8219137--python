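"""Procrustes superimposition primitives.

Partial-Procrustes convention throughout: configurations are centred and
scaled to unit centroid size, and only proper rotations (no reflections)
are used.  Downstream statistics treat the aligned coordinates as points in
the tangent space at the consensus — the standard small-variation Euclidean
approximation; an explicit orthogonal tangent projection is available but
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LandmarkConfiguration, LandmarkDataset

__all__ = [
    "centroid_size",
    "center",
    "preshape",
    "optimal_rotation",
    "procrustes_distance",
    "full_procrustes_distance",
    "partial_procrustes_distance",
    "ProcrustesFit",
    "gpa",
    "mean_shape",
]


def _coords(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.coords
    return np.asarray(config, dtype=float)


def centroid_size(config) -> float:
    """Square root of the summed squared landmark distances to the centroid.

    Invariant to translation and rotation; scales linearly under uniform
    scaling.  This is the size measure removed by GPA.
    """
    x = _coords(config)
    return float(np.linalg.norm(x - x.mean(axis=0)))


def center(config) -> np.ndarray:
    x = _coords(config)
    return x - x.mean(axis=0)


def preshape(config) -> np.ndarray:
    """Centre and scale to unit centroid size."""
    x = center(config)
    cs = np.linalg.norm(x)
    if cs == 0:
        raise ValueError("degenerate configuration: zero centroid size")
    return x / cs


def optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||A - B @ R||_F for centred A, B.

    Reflections are excluded: det(R) = +1 always, so a mirrored
    configuration keeps a positive residual.  Raises if the cross-product
    matrix has rank < 2 (rotation not identifiable).
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    M = B.T @ A
    U, s, Vt = np.linalg.svd(M)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate configuration: optimal rotation not identifiable")
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, 1.0, d]) @ Vt


def _proper_fit(Za: np.ndarray, Zb: np.ndarray):
    """Optimal proper rotation R and trace t for unit preshapes (lenient)."""
    M = Zb.T @ Za
    U, s, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    if d == 0:
        d = 1.0
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    t = float(s[0] + s[1] + d * s[2])
    return R, t


def procrustes_distance(A, B, kind: str = "full") -> float:
    """Shape distance between two configurations.

    ``full``: residual after optimal translation, proper rotation and mutual
    scaling of the unit preshapes (equals ``sqrt(1 - t^2)`` with ``t`` the
    optimal-rotation trace); ``partial``: at unit centroid size
    (``sqrt(2 - 2 t)``).  Both are computed from the explicit residual
    matrix, which stays accurate near zero where the closed forms cancel.
    Symmetric and invariant to similarity transforms of either argument.
    Label orders must agree when configurations are passed.
    """
    if isinstance(A, LandmarkConfiguration) and isinstance(B, LandmarkConfiguration):
        if A.labels != B.labels:
            raise ValueError("landmark label mismatch between configurations")
    Za, Zb = preshape(A), preshape(B)
    R, t = _proper_fit(Za, Zb)
    if kind == "full":
        return float(np.linalg.norm(Za - min(t, 1.0) * (Zb @ R)))
    if kind == "partial":
        return float(np.linalg.norm(Za - Zb @ R))
    raise ValueError(f"unknown Procrustes distance kind {kind!r}")


def full_procrustes_distance(A, B) -> float:
    return procrustes_distance(A, B, "full")


def partial_procrustes_distance(A, B) -> float:
    return procrustes_distance(A, B, "partial")


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------

@dataclass
class ProcrustesFit:
    """Result of a generalized Procrustes superimposition.

    ``aligned`` holds the centred, unit-centroid-size, optimally rotated
    coordinates (n, k, 3); ``consensus`` is the unit-size mean shape.
    ``centroid_sizes`` are the original sizes in mm.  ``metadata`` is
    carried along from the input dataset for downstream designs.
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    labels: tuple
    specimen_ids: list
    metadata: pd.DataFrame
    iterations: int
    converged: bool
    objective: float
    objective_path: list

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    def flattened(self) -> np.ndarray:
        """Aligned coordinates as an (n, 3k) matrix."""
        return self.aligned.reshape(self.n, -1)

    def pairwise_distance(self, i: int, j: int, kind: str = "full") -> float:
        return procrustes_distance(self.aligned[i], self.aligned[j], kind)

    def subset(self, mask_or_index) -> "ProcrustesFit":
        """Row-subset of an existing fit (no re-superimposition)."""
        idx = np.arange(self.n)[np.asarray(mask_or_index)]
        return ProcrustesFit(
            self.aligned[idx], self.consensus, self.centroid_sizes[idx],
            self.labels, [self.specimen_ids[i] for i in idx],
            self.metadata.iloc[idx].reset_index(drop=True),
            self.iterations, self.converged, self.objective, self.objective_path,
        )


def _rotate_all_to(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Batched proper rotation of each X[i] onto ref (all centred)."""
    M = np.einsum("nkj,kl->njl", X, ref)  # X[i].T @ ref
    U, s, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.zeros_like(M)
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    R = U @ D @ Vt
    return X @ R


def _tangent_project(flat: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the tangent space at the consensus."""
    c = consensus.ravel()
    c = c / np.linalg.norm(c)
    centered = flat - flat @ np.outer(c, c)
    return centered + c  # keep points near the consensus pole


def gpa(
    data,
    tol: float = 1e-10,
    max_iter: int = 100,
    project_tangent: bool = False,
) -> ProcrustesFit:
    """Generalized Procrustes analysis of a landmark dataset.

    Iteratively rotates every unit-size centred configuration onto the
    running consensus (itself rescaled to unit centroid size each round)
    until the partial Procrustes distance between successive consensus
    shapes falls below ``tol``.  The initial reference is the first
    specimen; by GPA theory the converged result is reference-independent
    to tolerance.  Non-convergence sets ``converged=False`` rather than
    raising.

    ``data`` may be a :class:`LandmarkDataset` or an (n, k, 3) array.
    """
    if isinstance(data, LandmarkDataset):
        X = data.coords_array()
        labels = data.labels
        ids = data.specimen_ids
        meta = data.metadata.copy()
    else:
        X = np.asarray(data, float)
        labels = tuple(f"L{i + 1}" for i in range(X.shape[1]))
        ids = [str(i) for i in range(X.shape[0])]
        meta = pd.DataFrame({"specimen_id": ids})
    n = X.shape[0]
    if n < 2:
        raise ValueError("GPA requires n >= 2 configurations")

    centred = X - X.mean(axis=1, keepdims=True)
    sizes = np.linalg.norm(centred, axis=(1, 2))
    if np.any(sizes == 0):
        raise ValueError("degenerate configuration with zero centroid size")
    Z = centred / sizes[:, None, None]

    consensus = Z[0].copy()
    path = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        Z = _rotate_all_to(Z, consensus)
        new = Z.mean(axis=0)
        new = new / np.linalg.norm(new)
        objective = float(np.sum((Z - new) ** 2))
        path.append(objective)
        # direct Frobenius step: cancellation-free near convergence
        step = float(np.linalg.norm(new - consensus))
        consensus = new
        if step < tol:
            converged = True
            break
    # canonical output frame: consensus principal axes with deterministic
    # signs, so the solution's (otherwise arbitrary) global orientation is
    # reproducible and GPA of an already-aligned sample is a no-op
    _, _, Vt = np.linalg.svd(consensus, full_matrices=False)
    V = Vt.T
    for j in range(2):
        col = consensus @ V[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            V[:, j] = -V[:, j]
    V[:, 2] = np.cross(V[:, 0], V[:, 1])
    consensus = consensus @ V
    # final pass so every specimen is optimally rotated onto the consensus
    Z = _rotate_all_to(Z, consensus)
    objective = float(np.sum((Z - consensus) ** 2))

    if project_tangent:
        flat = _tangent_project(Z.reshape(n, -1), consensus)
        Z = flat.reshape(n, -1, 3)

    return ProcrustesFit(
        aligned=Z, consensus=consensus, centroid_sizes=sizes,
        labels=labels, specimen_ids=ids, metadata=meta,
        iterations=iterations, converged=converged,
        objective=objective, objective_path=path,
    )


def mean_shape(fit: ProcrustesFit, subset=None) -> np.ndarray:
    """Mean shape of a specimen subset, re-superimposed onto the consensus.

    Coordinate-wise mean of the aligned coordinates, rescaled to unit
    centroid size and rotated onto the consensus.  With ``subset=None`` the
    full-sample mean equals the consensus to tolerance.
    """
    if subset is None:
        sel = fit.aligned
    else:
        idx = np.arange(fit.n)[np.asarray(subset)]
        if idx.size == 0:
            raise ValueError("empty subset")
        sel = fit.aligned[idx]
    m = sel.mean(axis=0)
    m = m - m.mean(axis=0)
    nrm = np.linalg.norm(m)
    if nrm == 0:
        raise ValueError("degenerate mean shape")
    m = m / nrm
    R = optimal_rotation(fit.consensus, m)
    return m @ R
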