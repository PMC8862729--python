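"""RNA family clustering from soft symmetric alignment (SSA) similarity.

The SSA similarity of two embedded sequences is the attention-weighted
mean of their pairwise cosine scores:

    s = (1/A) * sum_ij a_ij * w_ij,   a_ij = alpha_ij + beta_ij - alpha_ij*beta_ij

with alpha the row-softmax and beta the column-softmax of the cosine
matrix and A = sum_ij a_ij. s is symmetric under swapping the sequences.
All-pairs similarities form an N x N classification matrix whose rows are
treated as feature vectors for spectral clustering.

Clustering accuracy uses pair counting over all unordered sequence pairs:
RI = (TP+TN)/total, the expected index
E = ((TP+FP)(TP+FN) + (TN+FP)(TN+FN))/total and
ARI = ((TP+TN) - E)/(total - E), plus entropy-based homogeneity and
completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax
from sklearn.cluster import SpectralClustering
from sklearn.metrics import completeness_score, homogeneity_score

from .sal import omega

__all__ = [
    "SsaBreakdown",
    "ClusteringMetrics",
    "ssa_similarity",
    "similarity_matrix",
    "spectral_cluster",
    "clustering_metrics",
]


@dataclass
class SsaBreakdown:
    omega: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    a: np.ndarray
    A: float
    s_hat: float


@dataclass
class ClusteringMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    ri: float
    e: float
    ari: float
    homogeneity: float
    completeness: float


def ssa_similarity(z: np.ndarray, zp: np.ndarray) -> SsaBreakdown:
    """Soft symmetric alignment similarity with its intermediate fields."""
    om = omega(z, zp)
    alpha = softmax(om, axis=1)  # over j: each row sums to 1
    beta = softmax(om, axis=0)  # over i: each column sums to 1
    a = alpha + beta - alpha * beta
    total = float(a.sum())
    s_hat = float((a * om).sum() / total)
    return SsaBreakdown(omega=om, alpha=alpha, beta=beta, a=a, A=total, s_hat=s_hat)


def similarity_matrix(seqs, params: dict, config) -> tuple[np.ndarray, list[str]]:
    """All-pairs SSA similarities (the N x N classification matrix)."""
    from .model import embed

    if len(seqs) < 2:
        raise ValueError("need at least two sequences to build a similarity matrix")
    zs = [embed(s, params, config) for s in seqs]
    n = len(zs)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = ssa_similarity(zs[i], zs[j]).s_hat
            sim[i, j] = sim[j, i] = s
    return sim, [s.id for s in seqs]


def spectral_cluster(sim: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Cluster the rows of the classification matrix into k groups.

    Rows are feature vectors; a Gaussian kernel on their Euclidean
    distances (bandwidth = median nonzero pairwise distance) gives the
    nonnegative affinity required by normalised spectral clustering.
    """
    sim = np.asarray(sim, dtype=float)
    n = sim.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    if k == 1:
        return np.zeros(n, dtype=int)
    d2 = ((sim[:, None, :] - sim[None, :, :]) ** 2).sum(axis=-1)
    d = np.sqrt(d2)
    nz = d[d > 0]
    bw = float(np.median(nz)) if nz.size else 1.0
    affinity = np.exp(-d2 / (2.0 * bw * bw))
    sc = SpectralClustering(
        n_clusters=k, affinity="precomputed", random_state=seed, assign_labels="kmeans"
    )
    return sc.fit_predict(affinity)


def clustering_metrics(pred, ref) -> ClusteringMetrics:
    """Pair-count RI/E/ARI plus entropy-based homogeneity/completeness."""
    pred, ref = np.asarray(pred), np.asarray(ref)
    if len(pred) != len(ref):
        raise ValueError("label vectors differ in length")
    if len(pred) < 2:
        raise ValueError("need at least two items")
    tp = tn = fp = fn = 0
    n = len(pred)
    for i in range(n):
        for j in range(i + 1, n):
            same_ref = ref[i] == ref[j]
            same_pred = pred[i] == pred[j]
            if same_ref and same_pred:
                tp += 1
            elif not same_ref and not same_pred:
                tn += 1
            elif same_pred:
                fp += 1
            else:
                fn += 1
    total = tp + tn + fp + fn
    ri = (tp + tn) / total
    e = ((tp + fp) * (tp + fn) + (tn + fp) * (tn + fn)) / total
    ari = ((tp + tn) - e) / (total - e) if total != e else 1.0
    return ClusteringMetrics(
        tp=tp, tn=tn, fp=fp, fn=fn, ri=ri, e=e, ari=ari,
        homogeneity=float(homogeneity_score(ref, pred)),
        completeness=float(completeness_score(ref, pred)),
    )
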