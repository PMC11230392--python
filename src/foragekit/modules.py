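"""Foraging-module discovery.

Modules are stereotyped excursion types found by agglomerative (Ward)
clustering of the standardized 52-measure matrix.  The module count K is
chosen by split-half reproducibility: for each candidate K the data are
split in half many times, each half is clustered, clusters are matched
across halves by Hungarian assignment on centroid distances, and per-module
stability is the Jaccard overlap of the matched member sets after
nearest-centroid cross-assignment of all excursions.  The chosen K is the
largest candidate whose mean stability clears the threshold with all
modules at least ``min_size`` strong.

Embeddings (PCA or a diffusion-map variant) are presentation-layer only;
no statistics consume them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .geometry import PHASES


def cluster_excursions(X: np.ndarray, K: int, method: str = "ward") -> np.ndarray:
    """Ward/Euclidean agglomerative clustering cut at K clusters.

    Returns 1-based module ids.  Labels are canonicalised (decreasing
    cluster size, ties by lexicographic centroid) so the partition — and
    its labelling — is invariant to row permutation.
    """
    X = np.asarray(X, dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > len(X):
        raise ValueError(f"K={K} exceeds number of rows {len(X)}")
    if K == 1 or len(X) == 1:
        return np.ones(len(X), dtype=int)
    Z = linkage(X, method=method)
    raw = fcluster(Z, t=K, criterion="maxclust")
    return _canonical_labels(X, raw)


def _canonical_labels(X: np.ndarray, raw: np.ndarray) -> np.ndarray:
    ids = np.unique(raw)
    cent = np.array([X[raw == i].mean(axis=0) for i in ids])
    size = np.array([(raw == i).sum() for i in ids])
    order = sorted(range(len(ids)),
                   key=lambda j: (-size[j], tuple(np.round(cent[j], 9))))
    remap = {ids[j]: rank + 1 for rank, j in enumerate(order)}
    return np.array([remap[i] for i in raw], dtype=int)


def _centroids(X: np.ndarray, labels: np.ndarray, K: int) -> np.ndarray:
    return np.array([X[labels == k + 1].mean(axis=0) for k in range(K)])


@dataclass
class ModuleCatalog:
    """Fitted module catalog: centroids, assignments, stability scores."""

    K: int
    centroids: np.ndarray                 # K × p (standardized space)
    assignment: np.ndarray                # 1-based module id per excursion
    reproducibility: np.ndarray           # per-module stability in [0, 1]
    min_size: int
    linkage: str = "ward"
    selection: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "K": int(self.K),
            "centroids": self.centroids.tolist(),
            "reproducibility": self.reproducibility.tolist(),
            "min_size": int(self.min_size),
            "linkage": self.linkage,
            "selection": self.selection,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def assign_new(catalog: ModuleCatalog, vec: np.ndarray) -> int:
    """Nearest-centroid module id for a standardized vector (ties → lowest id)."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (catalog.centroids.shape[1],):
        raise ValueError(
            f"vector dimension {vec.shape} does not match centroids "
            f"({catalog.centroids.shape[1]},)")
    d = np.linalg.norm(catalog.centroids - vec, axis=1)
    return int(np.argmin(d)) + 1  # argmin takes the first (lowest id) on ties


def _nearest(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    return np.argmin(cdist(X, centroids), axis=1) + 1


def _split_stability(X: np.ndarray, K: int, n_splits: int,
                     rng: np.random.Generator, method: str,
                     final_centroids: np.ndarray) -> np.ndarray:
    """Per-module split-half stability at K, matched to the full-data fit.

    For each random half-split, both halves are clustered at K, matched to
    each other and to the full-data centroids by Hungarian assignment on
    centroid distances, and each final module's score for the split is the
    Jaccard overlap of the member sets obtained by nearest-centroid
    cross-assignment of *all* excursions to each half's centroids.
    Returns the per-module mean over splits.
    """
    n = len(X)
    per_module = np.zeros(K)
    for _ in range(n_splits):
        perm = rng.permutation(n)
        a, bb = perm[: n // 2], perm[n // 2:]
        la = cluster_excursions(X[a], K, method)
        lb = cluster_excursions(X[bb], K, method)
        ca = _centroids(X[a], la, K)
        cb = _centroids(X[bb], lb, K)
        fa = _nearest(X, ca)
        fb = _nearest(X, cb)
        ri, ci = linear_sum_assignment(cdist(ca, cb))
        match_ab = dict(zip(ri, ci))
        jac = np.empty(K)
        for i in range(K):
            A = fa == i + 1
            B = fb == match_ab[i] + 1
            union = (A | B).sum()
            jac[i] = (A & B).sum() / union if union else 1.0
        rf, cf = linear_sum_assignment(cdist(final_centroids, ca))
        for fi, ai in zip(rf, cf):
            per_module[fi] += jac[ai]
    return per_module / n_splits


def select_module_count(X: np.ndarray, K_range, n_splits: int = 20,
                        stability_threshold: float = 0.5, min_size: int = 5,
                        seed: int = 0, method: str = "ward") -> ModuleCatalog:
    """Choose K by split-half reproducibility and fit the final catalog.

    The chosen K is the largest candidate whose mean split-half stability
    is at least ``stability_threshold`` and whose full-data fit leaves no
    module smaller than ``min_size``.  Degenerate input (all rows
    identical) short-circuits to K = 1.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if np.allclose(X, X[0]):
        labels = np.ones(n, dtype=int)
        return ModuleCatalog(1, X[:1].copy(), labels, np.ones(1), min_size,
                             method, {"degenerate": True})
    rng_root = np.random.default_rng(seed)
    candidates = sorted(set(int(k) for k in K_range))
    if not candidates or candidates[0] < 2:
        raise ValueError("K_range must contain integers >= 2")
    scores = {}
    feasible = {}
    for K in candidates:
        if K > n // 2:
            continue
        labels_full = cluster_excursions(X, K, method)
        sizes = np.bincount(labels_full, minlength=K + 1)[1:]
        cents = _centroids(X, labels_full, K)
        rng = np.random.default_rng(np.random.SeedSequence([seed, K]))
        per_module = _split_stability(X, K, n_splits, rng, method, cents)
        scores[K] = {"mean_stability": float(per_module.mean()),
                     "min_stability": float(per_module.min()),
                     "min_module_size": int(sizes.min())}
        # every retained module must itself be reproducible
        if per_module.min() >= stability_threshold and sizes.min() >= min_size:
            feasible[K] = (labels_full, cents, per_module)
    if not feasible:
        raise ValueError(
            "no K in range meets the stability/min-size constraints; "
            "consider lowering stability_threshold or min_size. "
            f"Scores: {scores}")
    K = max(feasible)
    labels, cents, per_module = feasible[K]
    return ModuleCatalog(K, cents, labels, per_module, min_size, method,
                         {"candidates": scores, "chosen": K,
                          "stability_threshold": stability_threshold,
                          "n_splits": n_splits, "seed": seed})


# ---------------------------------------------------------------------------
# phase occupancy
# ---------------------------------------------------------------------------


@dataclass
class PhaseOccupancy:
    expressed: pd.DataFrame       # module × phase boolean
    shared: int
    exploration_only: int
    foraging_only: int

    @property
    def counts(self) -> dict:
        return {"shared": self.shared, "exploration_only": self.exploration_only,
                "foraging_only": self.foraging_only}


def phase_occupancy(assignment: np.ndarray, phases: np.ndarray,
                    occupancy_min: int = 1) -> PhaseOccupancy:
    """Which modules are expressed in which phase, and the Venn counts.

    A module is expressed in a phase iff at least ``occupancy_min`` of its
    excursions occur there.  shared + exploration_only + foraging_only = K
    always (a module seen in neither phase cannot exist by construction
    when occupancy_min == 1; with larger thresholds an under-threshold
    module counts toward the phase where it has more excursions).
    """
    df = pd.DataFrame({"module": assignment, "phase": phases})
    K = int(df["module"].max())
    tab = (df.groupby(["module", "phase"]).size().unstack(fill_value=0)
             .reindex(range(1, K + 1), fill_value=0))
    for ph in PHASES:
        if ph not in tab.columns:
            tab[ph] = 0
    expl = tab["Exploration"] >= occupancy_min
    forag = tab["Foraging"] >= occupancy_min
    neither = ~expl & ~forag
    if neither.any():  # degenerate threshold: side with the larger count
        bigger_expl = tab["Exploration"] >= tab["Foraging"]
        expl = expl | (neither & bigger_expl)
        forag = forag | (neither & ~bigger_expl)
    shared = int((expl & forag).sum())
    e_only = int((expl & ~forag).sum())
    f_only = int((forag & ~expl).sum())
    expressed = pd.DataFrame({"Exploration": expl, "Foraging": forag})
    return PhaseOccupancy(expressed, shared, e_only, f_only)


# ---------------------------------------------------------------------------
# embeddings (visualization only)
# ---------------------------------------------------------------------------


def embed_excursions(X: np.ndarray, method: str = "pca", n_components: int = 2,
                     seed: int = 0, knn: int = 15, diffusion_time: int = 3) -> np.ndarray:
    """Low-dimensional map of excursions for plotting.

    ``pca``: principal components with a deterministic sign convention.
    ``phate_like_diffusion``: diffusion map — adaptive-bandwidth gaussian
    kNN kernel, symmetrised, row-normalised, powered ``diffusion_time``
    steps, then the leading nontrivial spectral coordinates.  Both routes
    are deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    if len(X) < 3:
        raise ValueError("need at least 3 rows to embed")
    if method == "pca":
        from sklearn.decomposition import PCA
        emb = PCA(n_components=n_components,
                  random_state=seed, svd_solver="full").fit_transform(X)
        # sign convention: largest-magnitude loading of each component positive
        for j in range(emb.shape[1]):
            i = np.argmax(np.abs(emb[:, j]))
            if emb[i, j] < 0:
                emb[:, j] *= -1
        return emb
    if method == "phate_like_diffusion":
        n = len(X)
        k = min(knn, n - 1)
        D = cdist(X, X)
        sigma = np.sort(D, axis=1)[:, k]
        sigma[sigma <= 0] = np.finfo(float).tiny
        W = np.exp(-(D / sigma[:, None]) ** 2)
        W = 0.5 * (W + W.T)
        P = W / W.sum(axis=1, keepdims=True)
        P = np.linalg.matrix_power(P, diffusion_time)
        # spectral coordinates of the powered operator (skip the trivial one)
        vals, vecs = np.linalg.eig(P)
        order = np.argsort(-np.abs(vals))
        vals, vecs = np.real(vals[order]), np.real(vecs[:, order])
        emb = vecs[:, 1: n_components + 1] * vals[1: n_components + 1]
        for j in range(emb.shape[1]):
            i = np.argmax(np.abs(emb[:, j]))
            if emb[i, j] < 0:
                emb[:, j] *= -1
        return emb
    raise ValueError(f"unknown embedding method {method!r}; "
                     "use 'pca' or 'phate_like_diffusion'")
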