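"""Similarity network fusion (SNF).

Per-modality subject affinities are built with a scaled exponential kernel on
squared Euclidean distances, then iteratively cross-diffused: each modality's
full transition kernel is propagated through the other modalities' sparse
(K-nearest-neighbour) kernels until the networks agree on a single fused
similarity matrix carrying shared and complementary structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import AffinityMatrix, FusedNetwork, ModalityMatrix

__all__ = [
    "SNFParams",
    "pairwise_sq_euclidean",
    "scaled_exp_kernel",
    "full_kernel",
    "sparse_kernel",
    "snf_fuse",
    "standardize_features",
    "affinity_from_modality",
]


@dataclass
class SNFParams:
    """Fusion hyperparameters.

    K : neighbours in the local kernels and kernel bandwidth estimate.
    mu : bandwidth weight of between-subject edges (positive).
    T : number of cross-diffusion iterations.
    standardize : z-score features (training statistics) before distances.
    """

    K: int = 30
    mu: float = 0.8
    T: int = 20
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.T < 1:
            raise ValueError("T must be >= 1")

    def clamped(self, n_subjects: int) -> "SNFParams":
        """Clamp K to n-1 for small cohorts (with a warning)."""
        if self.K >= n_subjects:
            warnings.warn(
                f"K={self.K} >= n_subjects={n_subjects}; clamping K to {n_subjects - 1}",
                stacklevel=2,
            )
            return SNFParams(n_subjects - 1, self.mu, self.T, self.standardize)
        return self


def pairwise_sq_euclidean(values: np.ndarray, subject_ids=None) -> np.ndarray:
    """Squared Euclidean distances D(i,j) = sum_k (x_ik - x_jk)^2."""
    X = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(X)):
        bad = np.where(~np.isfinite(X).all(axis=1))[0]
        names = [subject_ids[i] for i in bad] if subject_ids is not None else list(bad)
        raise ValueError(f"non-finite feature values for subjects {names[:5]}")
    sq = np.einsum("ij,ij->i", X, X)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(D, 0.0, out=D)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def _knn_order(metric: np.ndarray, descending: bool) -> np.ndarray:
    """Per-row neighbour order excluding self; ties broken by subject index."""
    n = metric.shape[0]
    m = metric.copy()
    # push self to the end of every ordering
    fill = -np.inf if descending else np.inf
    np.fill_diagonal(m, fill)
    key = -m if descending else m
    return np.argsort(key, axis=1, kind="stable")[:, : n - 1]


def scaled_exp_kernel(D: np.ndarray, params: SNFParams, subject_ids=None) -> np.ndarray:
    """Affinity W(i,j) = exp(-D(i,j) / (mu * eps_ij)).

    The local bandwidth eps_ij averages each subject's mean distance to its
    K nearest neighbours with the pair distance itself, on the same (squared
    Euclidean) scale as D, so affinities are invariant to a global feature
    rescaling.
    """
    D = np.asarray(D, dtype=float)
    if np.max(np.abs(D - D.T)) > 1e-8 or np.min(D) < 0:
        raise ValueError("D must be symmetric and nonnegative")
    n = D.shape[0]
    K = min(params.K, n - 1)
    order = _knn_order(D, descending=False)[:, :K]
    mean_knn = np.take_along_axis(D, order, axis=1).mean(axis=1)
    eps = (mean_knn[:, None] + mean_knn[None, :] + D) / 3.0
    floor = np.finfo(float).eps
    if np.any(eps <= 0):
        warnings.warn("zero kernel bandwidth for some pair; flooring at machine epsilon")
        eps = np.maximum(eps, floor)
    W = np.exp(-D / (params.mu * eps))
    return (W + W.T) / 2.0


def full_kernel(W: np.ndarray, subject_ids=None) -> np.ndarray:
    """Row-stochastic transition kernel: off-diagonal mass halved, diag 1/2."""
    W = np.asarray(W, dtype=float)
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rowsum = off.sum(axis=1)
    if np.any(rowsum <= 0):
        bad = np.where(rowsum <= 0)[0]
        names = [subject_ids[i] for i in bad] if subject_ids is not None else list(bad)
        raise ValueError(f"isolated subjects (zero off-diagonal row): {names[:5]}")
    P = off / (2.0 * rowsum[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def sparse_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """Local kernel: keep each subject's K most similar neighbours (self
    excluded, ties at the K-th neighbour broken by ascending subject index)
    and row-normalize over them."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if not (1 <= K < n):
        raise ValueError("K must satisfy 1 <= K < n_subjects")
    order = _knn_order(W, descending=True)[:, :K]
    S = np.zeros_like(W)
    rows = np.repeat(np.arange(n), K)
    S[rows, order.ravel()] = W[rows, order.ravel()]
    rowsum = S.sum(axis=1)
    if np.any(rowsum <= 0):
        raise ValueError("a subject has zero affinity to all K neighbours")
    return S / rowsum[:, None]


def _renormalize(P: np.ndarray) -> np.ndarray:
    """Symmetrize then restore the half-mass row-stochastic form."""
    P = (P + P.T) / 2.0
    return full_kernel(P)


def snf_fuse(affinities: list[AffinityMatrix], params: SNFParams) -> FusedNetwork:
    """Cross-diffusion fusion of one or more affinity networks.

    Each modality's full kernel is iteratively propagated through its own
    sparse kernel against the average of the other modalities' kernels:
    P_v <- S_v . mean_{u != v}(P_u) . S_v^T, renormalized each iteration.
    A single modality is diffused against itself.
    """
    if not affinities:
        raise ValueError("at least one affinity matrix required")
    ids = affinities[0].subject_ids
    for a in affinities[1:]:
        if a.subject_ids != ids:
            raise ValueError("affinity matrices have mismatched subject ids/order")
    n = len(ids)
    params = params.clamped(n)

    P = [full_kernel(a.W, ids) for a in affinities]
    S = [sparse_kernel(a.W, params.K) for a in affinities]
    m = len(P)

    for _ in range(params.T):
        if m == 1:
            P = [_renormalize(S[0] @ P[0] @ S[0].T)]
        else:
            new = []
            for v in range(m):
                others = sum(P[u] for u in range(m) if u != v) / (m - 1)
                new.append(_renormalize(S[v] @ others @ S[v].T))
            P = new

    M = sum(P) / m
    M = full_kernel(M)  # reset self-similarity / half-mass rows
    M = (M + M.T) / 2.0  # exact symmetry for the output network
    return FusedNetwork(subject_ids=list(ids), S_fused=M)


def standardize_features(values: np.ndarray, mean=None, sd=None):
    """Z-score columns; returns (standardized, mean, sd). Constant columns
    keep sd 1 so they standardize to zero offset rather than blowing up."""
    X = np.asarray(values, dtype=float)
    if mean is None:
        mean = X.mean(axis=0)
    if sd is None:
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd, mean, sd


def affinity_from_modality(mod: ModalityMatrix, params: SNFParams) -> AffinityMatrix:
    """Distance + kernel for one modality, honouring the standardize flag."""
    X = mod.values
    if params.standardize:
        X, _, _ = standardize_features(X)
    D = pairwise_sq_euclidean(X, mod.subject_ids)
    W = scaled_exp_kernel(D, params.clamped(mod.n_subjects), mod.subject_ids)
    return AffinityMatrix(subject_ids=list(mod.subject_ids), W=W)
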