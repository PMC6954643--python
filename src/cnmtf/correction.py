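"""Ancestry kernel and Hilbert–Schmidt independence criterion (HSIC).

Population structure confounds genotype–phenotype clustering: allele
frequencies and phenotype prevalence can both differ between ancestral
subpopulations, so a clustering of subjects driven by ancestry looks like
a clustering driven by the trait.  The correction used here builds a
kernel ``A`` on subjects from genotype principal components (the standard
proxy for ancestry) and penalizes the factorization with the empirical
HSIC between the subject-cluster kernel ``K = V Vᵀ`` and ``A``:

    HSIC(K, A) = tr(K H A H) / (m − 1)²

where ``H = I − (1/m)·J`` is the centering matrix.  Small HSIC means the
subject clustering carries no linear information about ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def centering_matrix(m: int) -> np.ndarray:
    """Centering matrix H = I − (1/m)·J (idempotent, trace m−1)."""
    if m < 2:
        raise ValueError("centering matrix needs m >= 2")
    return np.eye(m) - np.full((m, m), 1.0 / m)


@dataclass
class AncestryKernel:
    """Subject-similarity kernel in principal-component space.

    A : m×m PSD similarity matrix (linear kernel on scaled PC scores)
    n_components : number of principal components used
    centered_product : precomputed H·A·H consumed by the factorization
    scores : the m×n_components PC score matrix the kernel was built from
    """

    A: np.ndarray
    n_components: int
    centered_product: np.ndarray
    scores: np.ndarray | None = None

    @classmethod
    def from_scores(cls, scores: np.ndarray, rescale: bool = True) -> "AncestryKernel":
        """Build the kernel from externally supplied PC scores (m×p)."""
        P = np.asarray(scores, dtype=float)
        if P.ndim != 2:
            raise ValueError("PC scores must be a 2-D (subjects × components) array")
        if rescale:
            sd = P.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            P = P / sd
        A = P @ P.T
        m = A.shape[0]
        H = centering_matrix(m)
        return cls(A=A, n_components=P.shape[1], centered_product=H @ A @ H, scores=P)


def ancestry_kernel(R: np.ndarray, n_pcs: int = 5) -> AncestryKernel:
    """Infer an ancestry kernel from the genotype matrix itself.

    SNV rows are standardized (zero-variance rows dropped), subjects are
    projected onto the top ``n_pcs`` principal components, each component
    is scaled to unit variance, and A is the linear kernel (Gram matrix)
    of the scaled scores.  A is PSD by construction.
    """
    R = np.asarray(R, dtype=float)
    n, m = R.shape
    if not 1 <= n_pcs < m:
        raise ValueError(f"need 1 <= n_pcs < m (got n_pcs={n_pcs}, m={m})")
    mu = R.mean(axis=1, keepdims=True)
    sd = R.std(axis=1, ddof=0, keepdims=True)
    keep = sd[:, 0] > 0
    if keep.sum() == 0:
        # no subject variation at all: a constant (uninformative) kernel,
        # whose centered product vanishes and disables the HSIC penalty
        H = centering_matrix(m)
        zero = np.zeros((m, m))
        return AncestryKernel(A=zero, n_components=0, centered_product=zero,
                              scores=np.zeros((m, n_pcs)))
    X = (R[keep] - mu[keep]) / sd[keep]
    # subject-space PCA via SVD of the standardized matrix
    # X is n×m with centered rows; subject scores are the right singular vectors
    Xc = X - X.mean(axis=1, keepdims=True)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_use = min(n_pcs, (s > 1e-12).sum())
    P = (Vt[:n_use].T) * s[:n_use]
    return AncestryKernel.from_scores(P, rescale=True)


def hsic(K: np.ndarray, A: np.ndarray) -> float:
    """Empirical HSIC: tr(K·H·A·H) / (m−1)².

    Symmetric in its arguments (trace cyclicity) and invariant to adding a
    constant to every entry of either kernel (H annihilates constants).
    For PSD kernels the value is non-negative up to round-off.
    """
    K = np.asarray(K, dtype=float)
    A = np.asarray(A, dtype=float)
    if K.shape != A.shape or K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"kernel shape mismatch: {K.shape} vs {A.shape}")
    m = K.shape[0]
    H = centering_matrix(m)
    return float(np.trace(K @ H @ A @ H)) / (m - 1) ** 2


def cluster_kernel(V: np.ndarray) -> np.ndarray:
    """Linear kernel on subject clustering weights: K = V Vᵀ."""
    V = np.asarray(V, dtype=float)
    return V @ V.T
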