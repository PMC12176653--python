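"""PCA + t-SNE embedding, elbow-selected k-means phenotype clusters.

The chain mirrors image-based phenotype mapping practice: features are
reduced by PCA, visualized by 2-D t-SNE, and partitioned by k-means with
the number of clusters chosen by the elbow (maximum chord distance /
Kneedle) rule on the inertia curve.  Clustering operates in PCA space by
default; the t-SNE plane is for display and density overlays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE


@dataclass
class Embedding:
    coords: np.ndarray          # organoids x 2
    pca_dims: int
    tsne_perplexity: float
    seed: int
    pca_coords: np.ndarray | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite embedding coordinates")


@dataclass
class ClusterAssignment:
    labels: np.ndarray          # dense ids 0..k-1
    k: int
    inertia: float
    inertia_curve: dict[int, float] | None = None

    def __post_init__(self):
        present = np.unique(self.labels)
        if len(present) != self.k or present.min() != 0 or present.max() != self.k - 1:
            raise ValueError("cluster ids must be dense 0..k-1 and non-empty")


def _as_array(features) -> np.ndarray:
    X = getattr(features, "values", features)
    return np.asarray(X, float)


def pca_reduce(features, pca_dims: int = 50) -> np.ndarray:
    X = _as_array(features)
    d = int(min(pca_dims, X.shape[1], X.shape[0]))
    return PCA(n_components=d, svd_solver="full").fit_transform(X)


def embed(
    features,
    pca_dims: int = 50,
    perplexity: float = 30.0,
    seed: int = 0,
) -> Embedding:
    """PCA to ``pca_dims`` (capped at the feature count) then 2-D t-SNE."""
    X = _as_array(features)
    n = X.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(
            f"t-SNE with perplexity {perplexity} needs > {int(3 * perplexity)} "
            f"samples; got {n}")
    Xp = pca_reduce(X, pca_dims)
    ts = TSNE(
        n_components=2, perplexity=perplexity, init="pca",
        random_state=seed, method="barnes_hut" if n > 50 else "exact",
    )
    coords = ts.fit_transform(Xp)
    return Embedding(np.asarray(coords, float), Xp.shape[1], perplexity, seed,
                     pca_coords=Xp)


def choose_k_elbow(features, k_max: int = 12, seed: int = 0,
                   n_init: int = 10) -> tuple[int, dict[int, float]]:
    """Elbow (Kneedle-style chord) rule on the log-inertia curve.

    k-means is run for k = 1..k_max; the chosen k maximizes the
    perpendicular distance of the (normalized) log-inertia curve to its
    chord.  The log scale matters for hierarchically clustered data:
    raw inertia is dominated by the coarsest split, whereas the knee of
    the log curve sits at the finest persistent cluster scale.

    Guard for structureless data: when the whole inertia curve is
    consistent with the smooth power-law decay of k-means on a single
    blob (R-squared of a log-log linear fit >= 0.99), no elbow exists
    and k = 1 is returned.  The full inertia curve is always returned
    for audit.
    """
    X = _as_array(features)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if X.shape[0] <= k_max:
        raise ValueError("need more samples than k_max")
    inertia = {}
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        inertia[k] = float(km.inertia_)
    vals = np.array([inertia[k] for k in range(1, k_max + 1)])
    if np.any(np.diff(vals) > 1e-9 * max(vals[0], 1.0)):
        warnings.warn("inertia curve not monotone; consider more k-means restarts",
                      stacklevel=2)
    vals = np.maximum(vals, 1e-12 * max(vals[0], 1.0))

    # no-structure guard: featureless power-law decay
    lk = np.log(np.arange(1, k_max + 1, dtype=float))
    lv = np.log(vals)
    A = np.column_stack([lk, np.ones_like(lk)])
    _, res, *_ = np.linalg.lstsq(A, lv, rcond=None)
    ss_tot = float(((lv - lv.mean()) ** 2).sum())
    r2 = 1.0 - (float(res[0]) if len(res) else 0.0) / max(ss_tot, 1e-12)
    if r2 >= 0.99:
        return 1, inertia

    # chord rule on the normalized log curve (chord = line x + y = 1)
    ks = np.arange(1, k_max + 1, dtype=float)
    x = (ks - 1) / (k_max - 1)
    rng_v = lv[0] - lv[-1]
    y = (lv - lv[-1]) / (rng_v if rng_v > 0 else 1.0)
    dist = (1.0 - x - y) / np.sqrt(2.0)
    k_best = int(ks[int(np.argmax(dist))])
    return k_best, inertia


def cluster(features, k: int, seed: int = 0, n_init: int = 10) -> ClusterAssignment:
    """k-means with k-means++ init, best of ``n_init`` restarts."""
    X = _as_array(features)
    if k < 1:
        raise ValueError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    labels = km.labels_.astype(int)
    # densify ids in case a cluster came back empty (sklearn relocates, so
    # this is defensive)
    uniq = np.unique(labels)
    remap = {c: i for i, c in enumerate(uniq)}
    labels = np.array([remap[c] for c in labels])
    return ClusterAssignment(labels, len(uniq), float(km.inertia_))
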