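"""Diffusion map embedding of fused similarity networks.

The fused network is treated as a weighted graph; a density-corrected Markov
transition matrix is eigendecomposed and its non-trivial right eigenvectors
give each subject a coordinate on the dominant axes of inter-subject
similarity. Alignment across embedding spaces uses orthogonal Procrustes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .datatypes import EmbeddingComparison, EmbeddingResult, FusedNetwork, ModalityMatrix

__all__ = [
    "EmbeddingParams",
    "diffusion_map_embed",
    "procrustes_align",
    "compare_embeddings",
    "feature_loadings",
]


@dataclass
class EmbeddingParams:
    """n_components : embedding dimensions retained.
    t : diffusion time; t = 0 models the most global similarity structure
        and scales component k by lambda_k / (1 - lambda_k).
    alpha : anisotropy (density correction); 0.5 by convention.
    """

    n_components: int = 5
    t: float = 0.0
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if self.t < 0:
            raise ValueError("diffusion time must be nonnegative")


def _fix_signs(scores: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector signs: nonnegative skewness, falling back to
    a nonnegative first entry when skewness is numerically zero."""
    out = scores.copy()
    for k in range(out.shape[1]):
        sk = stats.skew(out[:, k])
        if abs(sk) > 1e-12:
            if sk < 0:
                out[:, k] = -out[:, k]
        elif out[0, k] < 0:
            out[:, k] = -out[:, k]
    return out


def diffusion_map_embed(net: FusedNetwork, params: EmbeddingParams | None = None) -> EmbeddingResult:
    """Embed a fused network.

    With degrees d_i = sum_j S(i,j): L = S / (d_i^alpha d_j^alpha) is
    row-normalized to a Markov matrix M whose right eigenvectors (computed
    through the symmetric conjugate D^{1/2} M D^{-1/2} for stability) give
    the embedding. The trivial constant eigenvector (lambda = 1) is dropped.
    """
    params = params or EmbeddingParams()
    S = net.S_fused
    n = net.n_subjects
    if params.n_components >= n - 1:
        raise ValueError("n_components must be < n_subjects - 1")

    d = S.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("fused network has a zero-degree subject")
    if params.alpha > 0:
        da = d ** params.alpha
        L = S / np.outer(da, da)
    else:
        L = S.copy()
    dL = L.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(dL)
    A = L * np.outer(inv_sqrt, inv_sqrt)
    A = (A + A.T) / 2.0

    evals, evecs = linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]

    if evals[1] > 1.0 - 1e-10:
        raise ValueError(
            "similarity graph appears disconnected (repeated unit eigenvalue); "
            "consider a larger K"
        )

    # right eigenvectors of the Markov matrix, normalized by the stationary one
    psi = evecs * inv_sqrt[:, None]
    psi = psi / psi[:, [0]]

    k = params.n_components
    lambdas = np.clip(evals[1 : k + 1], -1.0, 1.0 - 1e-12)
    if params.t == 0:
        scale = lambdas / (1.0 - lambdas)
    else:
        scale = lambdas ** params.t
    scores = _fix_signs(psi[:, 1 : k + 1] * scale)

    if np.any(np.ptp(scores, axis=0) == 0):
        warnings.warn("an embedding component is constant across subjects")
    return EmbeddingResult(subject_ids=list(net.subject_ids), scores=scores, eigenvalues=lambdas)


def procrustes_align(
    source_scores: np.ndarray,
    target_scores: np.ndarray,
    scaling: bool = False,
) -> np.ndarray:
    """Rotate/reflect (optionally isotropically scale) source scores onto the
    target scores, minimizing the Frobenius distance; subjects must
    correspond row-wise. For one component this reduces to a sign flip
    making the correlation nonnegative."""
    A = np.atleast_2d(np.asarray(source_scores, dtype=float))
    B = np.atleast_2d(np.asarray(target_scores, dtype=float))
    if A.ndim == 2 and A.shape[0] == 1:
        A, B = A.T, B.T
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    mu_a = A.mean(axis=0)
    mu_b = B.mean(axis=0)
    Ac, Bc = A - mu_a, B - mu_b
    R, s = linalg.orthogonal_procrustes(Ac, Bc)
    if scaling:
        denom = np.sum(Ac * Ac)
        factor = s / denom if denom > 0 else 1.0
    else:
        factor = 1.0
    out = factor * (Ac @ R) + mu_b
    return out if np.asarray(source_scores).ndim > 1 else out.ravel()


def compare_embeddings(predicted: np.ndarray, truth: np.ndarray) -> EmbeddingComparison:
    """RMSE, MAE, coefficient of determination and Pearson r between aligned
    score vectors."""
    yhat = np.asarray(predicted, dtype=float).ravel()
    y = np.asarray(truth, dtype=float).ravel()
    if yhat.shape != y.shape:
        raise ValueError("predicted and truth must have equal length")
    if np.ptp(y) == 0:
        raise ValueError("truth scores have zero variance; correlation undefined")
    resid = yhat - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    r = float(stats.pearsonr(yhat, y)[0])
    return EmbeddingComparison(rmse=rmse, mae=mae, r2=float(r2), pearson_r=r)


def feature_loadings(modality: ModalityMatrix, scores: np.ndarray) -> np.ndarray:
    """Pearson correlation of each feature with the first embedding score.

    Constant features get NaN (undefined), not zero.
    """
    s = np.asarray(scores, dtype=float).ravel()
    if len(s) != modality.n_subjects:
        raise ValueError("scores length must match number of subjects")
    X = modality.values
    Xc = X - X.mean(axis=0)
    sc = s - s.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (sc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * sc[:, None]).sum(axis=0) / denom
    r[np.isclose((Xc**2).sum(axis=0), 0.0)] = np.nan
    return r
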