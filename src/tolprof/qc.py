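"""Quantum Clustering of conservation profiles.

Quantum Clustering (QC) locates cluster centers at the minima of a
potential function V derived from a Parzen-window density estimate.
Given points x_i with weights w_i and a Gaussian width sigma, the
"wavefunction"

    psi(x) = sum_i w_i exp(-||x - x_i||^2 / (2 sigma^2))

is taken as the ground state of a time-independent Schrödinger equation

    (-sigma^2/2 Laplacian + V(x)) psi = E psi,

which determines the potential uniquely up to the constant E:

    V(x) = E - d/2 + (1 / (2 sigma^2 psi(x)))
           * sum_i w_i ||x - x_i||^2 exp(-||x - x_i||^2 / (2 sigma^2)).

E is fixed so that min_i V(x_i) = 0.  Cluster assignment follows
gradient-descent dynamics: every point slides down V until it stops
moving, and points whose final positions coincide (single-linkage at a
small merge tolerance) form one cluster.

Binary conservation profiles are preprocessed by uncentered SVD to a
low dimension (default 5) and projected on the unit sphere; unique
patterns enter psi once, weighted by their multiplicity.  Weighting is
equivalent to replicating duplicates: scaling the weights rescales psi
but leaves V, its gradient, and hence the clustering unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from .profiles import ProfileSet

__all__ = [
    "Embedding",
    "QCParams",
    "ClusterStats",
    "SchrodingerPotential",
    "embed_svd",
    "embed_matrix",
    "potential_at",
    "descend",
    "assign_clusters",
    "auto_sigma",
    "cluster_stats",
    "labels_for_proteins",
    "noise_stability",
    "QuantumClustering",
]


@dataclass
class Embedding:
    """Unit-sphere coordinates of unique profiles plus multiplicities."""

    points: np.ndarray  # n_patterns x d, rows unit-norm
    weights: np.ndarray  # per-pattern multiplicity >= 1
    variance_explained: float
    d: int
    patterns: np.ndarray | None = None  # the originating binary patterns

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != self.d:
            raise ValueError("points must be n x d")
        if len(self.weights) != len(self.points):
            raise ValueError("one weight per point required")


@dataclass
class QCParams:
    """Controls for the descent stage of Quantum Clustering.

    ``step`` defaults to sigma/10; descent stops once the largest point
    displacement in an iteration falls below ``merge_tol / 10``.
    """

    sigma: float
    step: float | None = None
    max_iter: int = 2000
    merge_tol: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.merge_tol <= 0 or self.max_iter <= 0:
            raise ValueError("sigma, merge_tol and max_iter must be positive")
        if self.step is None:
            self.step = self.sigma / 10.0
        if self.step <= 0:
            raise ValueError("step must be positive")


class SchrodingerPotential:
    """The QC potential V, its wavefunction psi, and the analytic gradient.

    The normalisation constant E (making min V over the data points
    zero) is computed once at construction.
    """

    def __init__(self, points: np.ndarray, weights: np.ndarray, sigma: float):
        self.X = np.asarray(points, dtype=float)
        self.w = np.asarray(weights, dtype=float)
        self.sigma = float(sigma)
        self.d = self.X.shape[1]
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        # fix the additive constant so min_i V(x_i) = 0
        self.E = float(-np.min(self._v_raw(self.X)))

    def psi(self, x: np.ndarray) -> np.ndarray:
        Y = np.atleast_2d(np.asarray(x, dtype=float))
        D = cdist(Y, self.X, "sqeuclidean")
        return np.exp(-D / (2 * self.sigma**2)) @ self.w

    def _terms(self, Y: np.ndarray):
        D = cdist(Y, self.X, "sqeuclidean")  # m x n
        G = self.w * np.exp(-D / (2 * self.sigma**2))
        psi = G.sum(axis=1)
        if np.any(psi == 0.0) or not np.all(np.isfinite(psi)):
            raise FloatingPointError(
                "wavefunction underflowed to zero at an evaluation point; "
                "increase sigma"
            )
        S = (G * D).sum(axis=1)
        return D, G, psi, S

    def _v_raw(self, Y: np.ndarray) -> np.ndarray:
        _, _, psi, S = self._terms(np.atleast_2d(Y))
        return -self.d / 2.0 + S / (2 * self.sigma**2 * psi)

    def V(self, x: np.ndarray) -> np.ndarray | float:
        """Normalised potential; scalar for a single point."""
        Y = np.atleast_2d(np.asarray(x, dtype=float))
        out = self.E + self._v_raw(Y)
        return float(out[0]) if np.asarray(x).ndim == 1 else out

    def gradV(self, x: np.ndarray) -> np.ndarray:
        """Analytic gradient of V, batched over rows of ``x``."""
        single = np.asarray(x).ndim == 1
        Y = np.atleast_2d(np.asarray(x, dtype=float))
        D, G, psi, S = self._terms(Y)
        diff = Y[:, None, :] - self.X[None, :, :]  # m x n x d
        s2 = self.sigma**2
        # dS = sum_i G_i (2 - D_i/s2) diff_i ; dpsi = -sum_i G_i diff_i / s2
        coef = G * (2.0 - D / s2)  # m x n
        dS = np.einsum("mn,mnd->md", coef, diff)
        dpsi = -np.einsum("mn,mnd->md", G, diff) / s2
        grad = (dS * psi[:, None] - S[:, None] * dpsi) / (2 * s2 * psi[:, None] ** 2)
        return grad[0] if single else grad


def embed_matrix(M: np.ndarray, weights: np.ndarray, d: int) -> Embedding:
    """SVD-embed the rows of an arbitrary real matrix onto the unit sphere.

    The matrix is not mean-centered (profile matrices are nonnegative);
    rows are projected on the top-``d`` right singular directions and
    renormalised to unit length.  ``variance_explained`` is the fraction
    of squared singular values captured by the first ``d``.
    """
    M = np.asarray(M, dtype=float)
    n, k = M.shape
    if not 1 <= d <= min(n, k):
        raise ValueError(f"d={d} out of range for a {n}x{k} matrix")
    _, s, Vt = np.linalg.svd(M, full_matrices=False)
    coords = M @ Vt[:d].T
    norms = np.linalg.norm(coords, axis=1)
    if np.any(norms == 0):
        raise ValueError(
            "a pattern projects to the zero vector and cannot be "
            "normalised to the unit sphere; increase d"
        )
    coords = coords / norms[:, None]
    total = float((s**2).sum())
    var = float((s[:d] ** 2).sum() / total) if total > 0 else 1.0
    return Embedding(
        points=coords,
        weights=np.asarray(weights, dtype=float),
        variance_explained=var,
        d=d,
    )


def embed_svd(ps: ProfileSet, d: int = 5) -> Embedding:
    """Embed the unique patterns of a profile set (weights = multiplicity)."""
    if len(ps) == 0:
        raise ValueError("empty ProfileSet")
    patterns, mult = ps.unique_patterns()
    emb = embed_matrix(patterns, mult, d)
    emb.patterns = patterns
    return emb


def potential_at(x: np.ndarray, emb: Embedding, sigma: float) -> float:
    """Evaluate the normalised QC potential at one point."""
    pot = SchrodingerPotential(emb.points, emb.weights, sigma)
    return float(pot.V(np.asarray(x, dtype=float)))


def descend(emb: Embedding, params: QCParams) -> np.ndarray:
    """Slide every embedded point down the potential to its basin minimum.

    Gradient descent with a per-point adaptive step: starting from
    ``params.step`` (default sigma/10), a move that lowers V is accepted
    and the point's step grows by 1.1; a move that raises V is reverted
    and the step halves.  Adaptivity is needed because the curvature of
    V scales like 1/sigma^2 — any fixed step is either unstable at
    small widths or hopelessly slow at large ones.  Per-iteration
    displacement is additionally capped at sigma/2 (a trust region; it
    never changes which basin a point descends into).  A point counts
    as converged once its next displacement would fall below
    merge_tol/10; non-convergence at ``max_iter`` warns with the number
    of still-moving points.  Fully deterministic given inputs.
    """
    pot = SchrodingerPotential(emb.points, emb.weights, params.sigma)
    Y = emb.points.copy()
    tol = params.merge_tol / 10.0
    cap = params.sigma / 2.0
    n = len(Y)
    step = np.full(n, float(params.step))
    V_cur = np.atleast_1d(pot.V(Y))
    converged = np.zeros(n, dtype=bool)
    for _ in range(params.max_iter):
        G = pot.gradV(Y)
        delta = step[:, None] * G
        norms = np.linalg.norm(delta, axis=1)
        too_big = norms > cap
        if too_big.any():
            delta[too_big] *= (cap / norms[too_big])[:, None]
            norms[too_big] = cap
        converged = norms < tol
        if converged.all():
            break
        trial = Y - delta
        V_new = np.atleast_1d(pot.V(trial))
        improved = V_new <= V_cur
        Y = np.where(improved[:, None], trial, Y)
        V_cur = np.where(improved, V_new, V_cur)
        step = np.where(improved, step * 1.1, step * 0.5)
    else:
        n_moving = int((~converged).sum())
        if n_moving:
            warnings.warn(
                f"quantum-clustering descent did not converge for {n_moving} "
                f"point(s) within {params.max_iter} iterations",
                RuntimeWarning,
                stacklevel=2,
            )
    return Y


def assign_clusters(
    converged: np.ndarray,
    params: QCParams,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Group converged points by single linkage at the merge tolerance.

    Returns 1-based labels per pattern; cluster 1 is the largest by
    total weight (protein count), following the convention that the
    biggest cluster is numbered first.  Ties in size break by first
    occurrence.
    """
    converged = np.asarray(converged, dtype=float)
    n = len(converged)
    if weights is None:
        weights = np.ones(n)
    D = cdist(converged, converged)
    adj = csr_matrix(D <= params.merge_tol)
    _, comp = connected_components(adj, directed=False)
    sizes = np.zeros(comp.max() + 1)
    first = np.full(comp.max() + 1, n)
    for i, c in enumerate(comp):
        sizes[c] += weights[i]
        first[c] = min(first[c], i)
    order = sorted(range(len(sizes)), key=lambda c: (-sizes[c], first[c]))
    rank = {c: r + 1 for r, c in enumerate(order)}
    return np.array([rank[c] for c in comp], dtype=np.int64)


def cluster_profiles(
    emb: Embedding, params: QCParams
) -> np.ndarray:
    """Full QC pass: descend then assign; labels per unique pattern."""
    return assign_clusters(descend(emb, params), params, emb.weights)


def auto_sigma(
    emb: Embedding,
    k_target: int,
    sigma_grid,
    *,
    step: float | None = None,
    max_iter: int = 2000,
    merge_tol: float = 1e-3,
) -> float:
    """Largest grid sigma whose QC run yields exactly ``k_target`` clusters.

    The Gaussian width controls granularity monotonically in practice —
    large sigma fuses everything into one basin, small sigma isolates
    every pattern — so scanning a grid from above finds the coarsest
    clustering at the requested resolution.
    """
    grid = sorted(set(float(s) for s in sigma_grid), reverse=True)
    if not grid:
        raise ValueError("empty sigma grid")
    achieved: dict[float, int] = {}
    for sigma in grid:
        params = QCParams(
            sigma=sigma, step=step, max_iter=max_iter, merge_tol=merge_tol
        )
        labels = cluster_profiles(emb, params)
        achieved[sigma] = int(labels.max())
        if achieved[sigma] == k_target:
            return sigma
    raise ValueError(
        f"no sigma in the grid gives {k_target} clusters; achieved {achieved}"
    )


@dataclass
class ClusterStats:
    """Summary of one cluster: size, pattern diversity, MAP, center of mass."""

    cluster_id: int
    n_proteins: int
    n_patterns: int
    map_profile: tuple[int, ...]
    map_count: int
    center_of_mass: np.ndarray

    def __post_init__(self) -> None:
        if self.map_count > self.n_proteins:
            raise ValueError("MAP multiplicity cannot exceed cluster size")


def labels_for_proteins(ps: ProfileSet, pattern_labels: np.ndarray) -> pd.Series:
    """Expand per-pattern cluster labels to one label per protein."""
    idx = ps.pattern_index
    if len(pattern_labels) != len(idx):
        raise ValueError("one label per unique pattern required")
    out: dict[str, int] = {}
    for label, members in zip(pattern_labels, idx.values()):
        for pid in members:
            out[pid] = int(label)
    return pd.Series(out, name="cluster").loc[ps.protein_ids]


def cluster_stats(ps: ProfileSet, labels: pd.Series) -> list[ClusterStats]:
    """Per-cluster statistics: protein/pattern counts, MAP, center of mass.

    The MAP (most abundant profile) ties break to the lexicographically
    smallest pattern for determinism.  The center of mass is the
    multiplicity-weighted mean of the cluster's binary patterns, one
    value in [0, 1] per species.
    """
    if set(labels.index) != set(ps.protein_ids):
        raise ValueError("labels must cover exactly the profile set's proteins")
    out: list[ClusterStats] = []
    for cid in sorted(labels.unique()):
        ids = labels.index[labels == cid]
        sub = ps.subset(list(ids))
        pats, mult = sub.unique_patterns()
        # tie-break: among max multiplicity, lexicographically smallest pattern
        top = mult.max()
        candidates = [i for i in range(len(pats)) if mult[i] == top]
        best = min(candidates, key=lambda i: tuple(int(b) for b in pats[i]))
        cm = (mult[:, None] * pats).sum(axis=0) / mult.sum()
        out.append(
            ClusterStats(
                cluster_id=int(cid),
                n_proteins=len(sub),
                n_patterns=len(pats),
                map_profile=tuple(int(b) for b in pats[best]),
                map_count=int(mult[best]),
                center_of_mass=cm,
            )
        )
    return out


def cluster_stats_frame(ps: ProfileSet, labels: pd.Series) -> pd.DataFrame:
    """Cluster statistics as a table (one CM column per species)."""
    rows = []
    for st in cluster_stats(ps, labels):
        row = {
            "cluster": st.cluster_id,
            "n_proteins": st.n_proteins,
            "n_patterns": st.n_patterns,
            "MAP": "".join(str(b) for b in st.map_profile),
            "MAP_count": st.map_count,
        }
        for sp, v in zip(ps.panel.targets, st.center_of_mass):
            row[f"CM_{sp}"] = round(float(v), 4)
        rows.append(row)
    return pd.DataFrame(rows)


def noise_stability(
    ps: ProfileSet,
    params: QCParams,
    noise_sd: float,
    seed: int,
    *,
    d: int = 5,
) -> float:
    """Adjusted Rand index between clean and noise-perturbed clusterings.

    Gaussian noise of standard deviation ``noise_sd`` is added to the
    full (per-protein) binary matrix before embedding; both the clean
    and the perturbed run therefore use the replicated matrix, so the
    comparison isolates the effect of the noise.  Deterministic given
    the seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    M = ps.matrix.astype(float)
    noisy = M + rng.normal(0.0, noise_sd, size=M.shape) if noise_sd > 0 else M
    w = np.ones(len(M))

    def run(mat: np.ndarray) -> np.ndarray:
        emb = embed_matrix(mat, w, d)
        return cluster_profiles(emb, params)

    return float(adjusted_rand_score(run(M), run(noisy)))


class QuantumClustering:
    """Estimator-style front end: embed, descend, assign, summarise.

    Parameters mirror :class:`QCParams`; ``sigma`` may be a number or
    ``("auto", k_target, grid)`` to select the width by target cluster
    count.  ``fit`` computes per-pattern and per-protein labels; the
    fitted object exposes ``labels_``, ``pattern_labels_``,
    ``embedding_`` and ``stats_frame()``.
    """

    def __init__(
        self,
        sigma: float | tuple = 0.5,
        d: int = 5,
        step: float | None = None,
        max_iter: int = 2000,
        merge_tol: float = 1e-3,
        seed: int = 0,
    ):
        self.sigma = sigma
        self.d = d
        self.step = step
        self.max_iter = max_iter
        self.merge_tol = merge_tol
        self.seed = seed

    def fit(self, ps: ProfileSet) -> "QuantumClustering":
        self.embedding_ = embed_svd(ps, self.d)
        if isinstance(self.sigma, tuple):
            _, k_target, grid = self.sigma
            sigma = auto_sigma(
                self.embedding_,
                k_target,
                grid,
                step=self.step,
                max_iter=self.max_iter,
                merge_tol=self.merge_tol,
            )
        else:
            sigma = float(self.sigma)
        self.sigma_ = sigma
        self.params_ = QCParams(
            sigma=sigma,
            step=self.step,
            max_iter=self.max_iter,
            merge_tol=self.merge_tol,
            seed=self.seed,
        )
        self.pattern_labels_ = cluster_profiles(self.embedding_, self.params_)
        self.labels_ = labels_for_proteins(ps, self.pattern_labels_)
        self._ps = ps
        return self

    @property
    def n_clusters_(self) -> int:
        return int(self.pattern_labels_.max())

    def stats(self) -> list[ClusterStats]:
        return cluster_stats(self._ps, self.labels_)

    def stats_frame(self) -> pd.DataFrame:
        return cluster_stats_frame(self._ps, self.labels_)

    def plot_profile_matrix(self, ax=None):
        """Presence/absence heat map with proteins grouped by cluster."""
        import matplotlib.pyplot as plt

        order = self.labels_.sort_values(kind="stable").index
        M = self._ps.subset(list(order)).matrix
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 8))
        ax.imshow(M, aspect="auto", interpolation="nearest", cmap="Blues")
        ax.set_xticks(range(self._ps.panel.k))
        ax.set_xticklabels(self._ps.panel.targets, rotation=90, fontsize=6)
        ax.set_ylabel("proteins (grouped by cluster)")
        return ax
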