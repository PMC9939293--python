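"""Neuronal ensemble detection from binary activity frames.

Pipeline: imaging frames with fewer than three coactive neurons are
excluded; single-linkage clustering on Jaccard distance discards frames
without any neighbor above 50% Jaccard similarity; the remaining frames are
clustered with Ward linkage and the tree is cut at the number of clusters
maximizing a within/between contrast index. Each ensemble j is summarized by
a binary vector V_j over all frames (1 when the ensemble is active).

Neuron membership: a neuron participates in ensemble j when (a) its binary
train is significantly correlated with V_j against circular-shift surrogates
(the participation correlation P_a), and (b) it has at least one significant
within-ensemble connection, where the pair weight W_ab = P_a * P_b * Co_ab
(Co_ab the Pearson correlation of the two trains) strictly exceeds the 95th
percentile of surrogate weights from independently shifted trains.

Correlations of binary trains are Pearson (phi) coefficients; under a
circular shift only the co-occurrence count changes, so surrogate
correlations are read from FFT cross-correlation tables (see
``connectivity``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .connectivity import _nearest_rank_percentile

__all__ = [
    "EnsembleSet",
    "filter_frames",
    "jaccard_filter",
    "cluster_ensembles",
    "membership_test",
    "ensembles_per_neuron",
    "detect_ensembles",
]


@dataclass
class EnsembleSet:
    """Detected ensembles of one session.

    retained_frames : frame indices surviving the coactivity and Jaccard
        filters (the clustered frames).
    ensemble_of_frame : ensemble label (0..k-1) per retained frame.
    V : k x n_frames binary activity vectors, one per ensemble.
    membership : neurons x k boolean participation matrix.
    contrast_by_k : contrast score per candidate cluster count.
    excluded_neurons : neurons with zero-variance trains (untestable).
    """

    retained_frames: np.ndarray
    ensemble_of_frame: np.ndarray
    V: np.ndarray
    membership: np.ndarray
    contrast_by_k: dict[int, float] = field(default_factory=dict)
    excluded_neurons: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_ensembles(self) -> int:
        return self.V.shape[0]

    @property
    def counts_per_neuron(self) -> np.ndarray:
        return self.membership.sum(axis=1)


def filter_frames(binary: np.ndarray, min_coactive: int = 3) -> np.ndarray:
    """Indices of frames with at least ``min_coactive`` coactive neurons."""
    b = np.asarray(binary)
    return np.flatnonzero((b > 0).sum(axis=0) >= min_coactive)


def jaccard_filter(frame_vectors: np.ndarray, min_similarity: float = 0.5) -> np.ndarray:
    """Indices (into ``frame_vectors`` rows) of frames that have a neighbor
    with Jaccard similarity strictly above ``min_similarity``.

    Equivalent to dropping frames whose single-linkage merge height on
    Jaccard distance is >= 1 - min_similarity: in single linkage a point's
    first merge height is its minimum distance to any other point.
    """
    fv = np.atleast_2d(np.asarray(frame_vectors, dtype=bool))
    if fv.shape[0] < 2:
        return np.array([], dtype=int)
    d = squareform(pdist(fv, metric="jaccard"))
    np.fill_diagonal(d, np.inf)
    return np.flatnonzero(d.min(axis=1) < 1.0 - min_similarity)


def _contrast(similarity: np.ndarray, labels: np.ndarray) -> float:
    """(mean within-cluster - mean between-cluster similarity) / (sum)."""
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(labels.size, k=1)
    within = similarity[iu][same[iu]]
    between = similarity[iu][~same[iu]]
    if within.size == 0 or between.size == 0:
        return -np.inf
    w, b = float(within.mean()), float(between.mean())
    if w + b == 0:
        return 0.0
    return (w - b) / (w + b)


def cluster_ensembles(
    frame_vectors: np.ndarray, max_k: int = 10
) -> tuple[np.ndarray, dict[int, float]]:
    """Ward-linkage clustering of similar frames on Jaccard distance.

    The tree is cut at the k in 2..min(max_k, n-1) maximizing the contrast
    index; all-identical frames collapse to a single ensemble. Returns
    (labels in 0..k-1, contrast_by_k).
    """
    fv = np.atleast_2d(np.asarray(frame_vectors, dtype=bool))
    n = fv.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames to cluster")
    dcond = pdist(fv, metric="jaccard")
    if np.max(dcond) == 0:  # degenerate: identical frames
        return np.zeros(n, dtype=int), {1: 1.0}
    Z = linkage(dcond, method="ward")
    sim = 1.0 - squareform(dcond)
    contrast_by_k: dict[int, float] = {}
    best_k, best_labels, best_score = None, None, -np.inf
    for k in range(2, min(max_k, n - 1) + 1):
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
        score = _contrast(sim, labels)
        contrast_by_k[k] = score
        if score > best_score:
            best_k, best_labels, best_score = k, labels, score
    if best_labels is None:  # n == 2
        best_labels = fcluster(Z, t=2, criterion="maxclust") - 1
        contrast_by_k[2] = _contrast(sim, best_labels)
    return best_labels, contrast_by_k


def _phi_tables(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson (phi) correlation of binary ``x`` with binary ``y`` at every
    relative circular lag; ``table[0]`` is the observed correlation."""
    T = x.size
    nx_, ny = int(x.sum()), int(y.sum())
    cc = np.rint(
        np.fft.irfft(np.conj(np.fft.rfft(x.astype(float)))
                     * np.fft.rfft(y.astype(float)), n=T)
    )
    denom = np.sqrt(float(nx_) * (T - nx_) * ny * (T - ny))
    if denom == 0:
        raise ValueError("zero-variance train")
    return (T * cc - nx_ * ny) / denom


def membership_test(
    binary: np.ndarray,
    V_j: np.ndarray,
    n_surrogates: int = 1000,
    percentile: float = 95.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Neurons participating in the ensemble with activity vector ``V_j``.

    Returns (member mask, excluded mask); excluded neurons have
    zero-variance trains and cannot be tested.
    """
    b = (np.asarray(binary) > 0).astype(np.int8)
    V = (np.asarray(V_j) > 0).astype(np.int8)
    if V.sum() == 0:
        raise ValueError("empty ensemble vector")
    n, T = b.shape
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 41]))
    na = b.sum(axis=1)
    excluded = (na == 0) | (na == T)
    testable = np.flatnonzero(~excluded)
    members = np.zeros(n, dtype=bool)
    if testable.size == 0:
        return members, excluded

    # stage 1: participation correlation P_a significant vs shifted-a surrogates
    shifts = rng.integers(1, T, size=(n, n_surrogates))
    P_obs = np.empty(n)
    significant = np.zeros(n, dtype=bool)
    P_tables: dict[int, np.ndarray] = {}
    for a in testable:
        tab = _phi_tables(b[a], V)
        P_tables[a] = tab
        P_obs[a] = tab[0]
        thr = _nearest_rank_percentile(tab[shifts[a]], percentile)
        significant[a] = tab[0] > thr
    cand = np.flatnonzero(significant)

    # stage 2: within-ensemble pair weights W = P_a * P_b * Co_ab
    for ii, a in enumerate(cand):
        for bn in cand[ii + 1 :]:
            if members[a] and members[bn]:
                continue
            co = _phi_tables(b[a], b[bn])
            W = P_obs[a] * P_obs[bn] * co[0]
            rel = (shifts[a] - shifts[bn]) % T
            SW = P_tables[a][shifts[a]] * P_tables[bn][shifts[bn]] * co[rel]
            if W > _nearest_rank_percentile(SW, percentile):
                members[a] = True
                members[bn] = True
    return members, excluded


def ensembles_per_neuron(membership: np.ndarray) -> dict:
    """Per-neuron ensemble counts and the no/one/multiple category fractions."""
    m = np.atleast_2d(np.asarray(membership, dtype=bool))
    counts = m.sum(axis=1)
    n = counts.size
    fractions = {
        "0": float(np.mean(counts == 0)),
        "1": float(np.mean(counts == 1)),
        "2": float(np.mean(counts == 2)),
        ">2": float(np.mean(counts > 2)),
    }
    per_ensemble = m.sum(axis=0)
    return {
        "counts": counts,
        "fractions": fractions,
        "mean_neurons_per_ensemble": float(per_ensemble.mean()) if m.shape[1] else 0.0,
    }


def detect_ensembles(
    binary: np.ndarray,
    min_coactive: int = 3,
    min_similarity: float = 0.5,
    max_k: int = 10,
    n_surrogates: int = 1000,
    percentile: float = 95.0,
    seed: int = 0,
) -> EnsembleSet:
    """Full ensemble pipeline: frame filtering, Jaccard filtering, Ward
    clustering, and surrogate-tested neuron membership."""
    b = (np.asarray(binary) > 0).astype(np.int8)
    n, T = b.shape
    coactive = filter_frames(b, min_coactive)
    empty = EnsembleSet(
        retained_frames=np.array([], dtype=int),
        ensemble_of_frame=np.array([], dtype=int),
        V=np.zeros((0, T), dtype=np.int8),
        membership=np.zeros((n, 0), dtype=bool),
    )
    if coactive.size < 2:
        return empty
    fv = b[:, coactive].T  # frames x neurons
    similar = jaccard_filter(fv, min_similarity)
    if similar.size < 2:
        return empty
    retained = coactive[similar]
    labels, contrast_by_k = cluster_ensembles(fv[similar], max_k=max_k)
    # an ensemble must be internally cohesive: clusters whose mean pairwise
    # Jaccard similarity does not exceed the similarity threshold are
    # chance-coincidence frame groups, not ensembles, and are excluded
    sim = 1.0 - squareform(pdist(fv[similar], metric="jaccard"))
    cohesive = []
    for j in range(int(labels.max()) + 1):
        idx = np.flatnonzero(labels == j)
        if idx.size < 2:
            continue
        iu = np.triu_indices(idx.size, k=1)
        if float(sim[np.ix_(idx, idx)][iu].mean()) > min_similarity:
            cohesive.append(j)
    if not cohesive:
        return empty
    keep_mask = np.isin(labels, cohesive)
    retained = retained[keep_mask]
    labels = np.searchsorted(np.array(cohesive), labels[keep_mask])
    k = int(labels.max()) + 1
    V = np.zeros((k, T), dtype=np.int8)
    for j in range(k):
        V[j, retained[labels == j]] = 1
    membership = np.zeros((n, k), dtype=bool)
    excluded = np.zeros(n, dtype=bool)
    for j in range(k):
        mem, exc = membership_test(
            b, V[j], n_surrogates=n_surrogates, percentile=percentile,
            seed=seed + j,
        )
        membership[:, j] = mem
        excluded |= exc
    return EnsembleSet(
        retained_frames=retained,
        ensemble_of_frame=labels,
        V=V,
        membership=membership,
        contrast_by_k=contrast_by_k,
        excluded_neurons=np.flatnonzero(excluded),
    )
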