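"""SUCRA-profile dimensionality reduction and regimen grouping.

Each regimen is described by its five-endpoint SUCRA profile (PFS, OS, ORR,
CR, safety — safety already oriented so higher means safer).  The profile
matrix is reduced by principal component analysis (correlation PCA by
default) and the regimens are grouped by partitioning around medoids (PAM,
BUILD + SWAP) on the retained component scores, with the number of groups
chosen by mean silhouette width unless fixed by the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "SucraProfile",
    "ClusterResult",
    "assemble_profile",
    "pca_scores",
    "pam_cluster",
    "choose_k",
    "mean_silhouette",
    "profile_and_cluster",
]

PROFILE_ENDPOINTS = ("PFS", "OS", "ORR", "CR", "safety")


@dataclass
class SucraProfile:
    """Treatments x endpoints matrix of SUCRA values in [0, 1]."""

    matrix: pd.DataFrame  # rows = treatments, columns = endpoints

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValidationError("SUCRA profile contains missing entries")
        if (vals < 0).any() or (vals > 1).any():
            raise ValidationError("SUCRA values must lie in [0, 1]")

    @property
    def treatments(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def endpoints(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class ClusterResult:
    """PCA scores/loadings plus (optionally) a PAM partition."""

    treatments: tuple[str, ...]
    scores: np.ndarray | None = None  # (n, n_pc)
    loadings: np.ndarray | None = None  # (n_endpoints, n_pc)
    explained_variance: np.ndarray | None = None  # fractions, sum to 1
    assignments: dict[str, int] | None = None
    medoids: tuple[str, ...] | None = None
    objective: float | None = None
    silhouette: dict[int, float] = field(default_factory=dict)
    k: int | None = None


def assemble_profile(chart: pd.DataFrame) -> SucraProfile:
    """Build the profile matrix from the mean-SUCRA chart.

    Rows keep the chart's (mean-SUCRA descending) order; columns are the
    five endpoints in canonical order.
    """
    missing = [ep for ep in PROFILE_ENDPOINTS if ep not in chart.columns]
    if missing:
        raise ValidationError(f"chart lacks endpoint column(s): {missing}")
    sub = chart.loc[:, list(PROFILE_ENDPOINTS)].copy()
    if sub.isna().any().any():
        bad = sorted(sub.index[sub.isna().any(axis=1)])
        raise ValidationError(f"missing endpoint SUCRA for treatment(s): {bad}")
    return SucraProfile(sub)


def pca_scores(
    profile: SucraProfile, center: bool = True, scale: bool = True
) -> ClusterResult:
    """Principal components of the SUCRA profile.

    Eigendecomposition of the covariance matrix (the correlation matrix when
    ``scale`` is on, matching R's ``prcomp(..., scale.=TRUE)``), components
    ordered by decreasing eigenvalue.  Sign convention: the largest-magnitude
    loading of each component is positive.
    """
    X = profile.matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValidationError("PCA needs at least 2 treatments")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = np.isclose(sd, 0.0)
        if zero.any():
            cols = [profile.endpoints[j] for j in np.flatnonzero(zero)]
            raise ValidationError(f"constant column(s) with scale on: {cols}")
        X = X / sd
    cov = X.T @ X / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest |loading| positive per component
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    scores = X @ eigvec
    total = eigval.sum()
    frac = eigval / total if total > 0 else np.full_like(eigval, 1.0 / len(eigval))
    return ClusterResult(
        treatments=tuple(profile.treatments),
        scores=scores,
        loadings=eigvec,
        explained_variance=frac,
    )


def _pam_objective(dist: np.ndarray, medoids: list[int]) -> float:
    return float(dist[:, medoids].min(axis=1).sum())


def _pam_build(dist: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD: start from the most central point, add by largest gain."""
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return medoids


def _pam_swap(dist: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    """SWAP until no (medoid, non-medoid) exchange reduces the objective."""
    n = dist.shape[0]
    improved = True
    best = _pam_objective(dist, medoids)
    while improved:
        improved = False
        for mi in range(len(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                obj = _pam_objective(dist, trial)
                if obj < best - 1e-12:
                    medoids, best, improved = trial, obj, True
    return medoids, best


def pam_cluster(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    labels: tuple[str, ...] | None = None,
    n_restarts: int = 10,
) -> ClusterResult:
    """Partitioning around medoids with Euclidean dissimilarity.

    BUILD greedily seeds the k medoids; SWAP exhaustively tries every
    (medoid, non-medoid) exchange until none reduces the total
    dissimilarity.  SWAP descends to a single-exchange local optimum, so it
    is additionally restarted from ``n_restarts`` seeded random medoid sets
    and the best final objective is kept (ties broken by lexicographic
    medoid order).  Deterministic given input order and seed.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k must lie in [1, {n}], got {k}")
    if labels is None:
        labels = tuple(str(i) for i in range(n))
    diff = points[:, None, :] - points[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))

    rng = np.random.default_rng(seed)
    starts = [_pam_build(dist, k)]
    for _ in range(n_restarts):
        starts.append(sorted(int(i) for i in rng.choice(n, size=k, replace=False)))
    medoids, best = None, math.inf
    for start in starts:
        cand, obj = _pam_swap(dist, start)
        cand = sorted(cand)
        if obj < best - 1e-12 or (abs(obj - best) <= 1e-12 and cand < medoids):
            medoids, best = cand, obj
    assign_idx = np.argmin(dist[:, medoids], axis=1)
    assignments = {labels[i]: int(assign_idx[i]) for i in range(n)}
    return ClusterResult(
        treatments=tuple(labels),
        assignments=assignments,
        medoids=tuple(labels[m] for m in medoids),
        objective=_pam_objective(dist, medoids),
        k=k,
    )


def mean_silhouette(points: np.ndarray, assignment: np.ndarray) -> float:
    """Mean silhouette width; points in singleton clusters contribute 0."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    assignment = np.asarray(assignment)
    n = len(assignment)
    diff = points[:, None, :] - points[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    widths = np.zeros(n)
    clusters = np.unique(assignment)
    for i in range(n):
        own = assignment[i]
        mask_own = (assignment == own)
        if mask_own.sum() == 1:
            widths[i] = 0.0
            continue
        a_i = dist[i, mask_own].sum() / (mask_own.sum() - 1)
        b_i = min(
            dist[i, assignment == c].mean() for c in clusters if c != own
        )
        denom = max(a_i, b_i)
        widths[i] = 0.0 if denom == 0 else (b_i - a_i) / denom
    return float(widths.mean())


def choose_k(
    points: np.ndarray,
    k_range: range | tuple[int, ...] = range(2, 7),
    seed: int = 0,
    labels: tuple[str, ...] | None = None,
) -> ClusterResult:
    """PAM over a range of k; keep the partition maximizing mean silhouette."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValidationError(f"no admissible k in {list(k_range)} for n={n}")
    results: dict[int, ClusterResult] = {}
    sil: dict[int, float] = {}
    for k in ks:
        res = pam_cluster(points, k, seed=seed, labels=labels)
        assignment = np.array([res.assignments[t] for t in res.treatments])
        sil[k] = mean_silhouette(points, assignment)
        results[k] = res
    best_k = max(ks, key=lambda k: sil[k])
    best = results[best_k]
    best.silhouette = sil
    return best


def profile_and_cluster(
    chart: pd.DataFrame,
    k: int | None = None,
    center: bool = True,
    scale: bool = True,
    var_explained: float = 0.80,
    seed: int = 0,
) -> ClusterResult:
    """Full profiling step: SUCRA chart -> PCA -> PAM on retained scores.

    The retained components are the smallest leading set explaining at least
    ``var_explained`` of the variance.  ``k`` fixes the group count; when
    omitted it is chosen by mean silhouette width over 2..6.
    """
    profile = assemble_profile(chart)
    pca = pca_scores(profile, center=center, scale=scale)
    cum = np.cumsum(pca.explained_variance)
    n_pc = int(np.searchsorted(cum, var_explained - 1e-12) + 1)
    pts = pca.scores[:, :n_pc]
    labels = pca.treatments
    if k is not None:
        res = pam_cluster(pts, k, seed=seed, labels=labels)
        assignment = np.array([res.assignments[t] for t in res.treatments])
        res.silhouette = {k: mean_silhouette(pts, assignment)}
    else:
        res = choose_k(pts, seed=seed, labels=labels)
    res.scores = pca.scores
    res.loadings = pca.loadings
    res.explained_variance = pca.explained_variance
    return res
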