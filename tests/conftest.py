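import numpy as np
import pytest

from fusemap.datatypes import AffinityMatrix, FusedNetwork
from fusemap.fusion import SNFParams, full_kernel, sparse_kernel
from fusemap.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_affinity(rng, n):
    """Random valid affinity: symmetric, nonnegative, unit diagonal."""
    A = rng.random((n, n))
    W = (A + A.T) / 2.0
    np.fill_diagonal(W, 1.0)
    return W


@pytest.fixture
def small_cohort():
    return generate_cohort(GeneratorConfig(n_subjects=40, seed=99, n_sites=2, site_offset_sd=0.2))


def naive_snf(Ws, K, T):
    """Loop-based reference SNF (no vectorization) for oracle checks."""
    n = Ws[0].shape[0]
    m = len(Ws)

    def naive_full(W):
        P = [[0.0] * n for _ in range(n)]
        for i in range(n):
            s = sum(W[i][j] for j in range(n) if j != i)
            for j in range(n):
                P[i][j] = 0.5 if i == j else W[i][j] / (2.0 * s)
        return P

    def naive_sparse(W):
        S = [[0.0] * n for _ in range(n)]
        for i in range(n):
            neigh = sorted((j for j in range(n) if j != i), key=lambda j: (-W[i][j], j))[:K]
            s = sum(W[i][j] for j in neigh)
            for j in neigh:
                S[i][j] = W[i][j] / s
        return S

    def matmul(A, B):
        return [[sum(A[i][k] * B[k][j] for k in range(n)) for j in range(n)] for i in range(n)]

    def sym(A):
        return [[(A[i][j] + A[j][i]) / 2.0 for j in range(n)] for i in range(n)]

    P = [naive_full(W.tolist()) for W in Ws]
    S = [naive_sparse(W.tolist()) for W in Ws]
    for _ in range(T):
        if m == 1:
            ST = [[S[0][j][i] for j in range(n)] for i in range(n)]
            P = [naive_full(sym(matmul(matmul(S[0], P[0]), ST)))]
        else:
            new = []
            for v in range(m):
                avg = [
                    [
                        sum(P[u][i][j] for u in range(m) if u != v) / (m - 1)
                        for j in range(n)
                    ]
                    for i in range(n)
                ]
                ST = [[S[v][j][i] for j in range(n)] for i in range(n)]
                new.append(naive_full(sym(matmul(matmul(S[v], avg), ST))))
            P = new
    M = [[sum(P[v][i][j] for v in range(m)) / m for j in range(n)] for i in range(n)]
    M = naive_full(M)
    M = sym(M)
    return np.array(M)
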