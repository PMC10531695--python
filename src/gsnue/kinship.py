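"""Genomic relationship matrices and Gaussian kernels.

The GRM follows the standard allele-frequency-scaled cross-product
(VanRaden's first method): G = W W' / (2 * sum_k p_k (1 - p_k)) with W the
dosage matrix column-centered at 2 p_k.  Kernel and ensemble learners use a
Gaussian (RBF) kernel on Euclidean distances between centered coded rows,
with the median off-diagonal distance as the default bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform


@dataclass
class KinshipMatrix:
    """Symmetric genotype x genotype relationship or kernel matrix."""

    genotype_ids: list[str]
    values: np.ndarray
    construction: str  # "GRM" or "gaussian_kernel"
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genotype_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match genotype ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, idx: np.ndarray) -> "KinshipMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return KinshipMatrix(
            genotype_ids=[self.genotype_ids[i] for i in idx],
            values=self.values[np.ix_(idx, idx)].copy(),
            construction=self.construction,
            parameters=dict(self.parameters),
        )


def build_grm(
    dosage: np.ndarray, genotype_ids: list[str] | None = None
) -> KinshipMatrix:
    """Allele-frequency-scaled GRM from a complete dosage (or coded) matrix.

    Centering at twice the allele frequency makes the construction invariant
    to a constant shift of the coding, so {0,1,2} dosages and {-1,0,1} codes
    give the same matrix.
    """
    X = np.asarray(dosage, dtype=float)
    if np.isnan(X).any():
        raise ValueError("GRM requires a complete matrix")
    if X.shape[1] < 1:
        raise ValueError("GRM requires at least one marker")
    # a shifted coding only moves the column means, which centering removes
    col_mean = X.mean(axis=0)
    W = X - col_mean
    # recover the allele frequency from the column mean; {-1,0,1} codes sit
    # one unit below {0,1,2} dosages
    offset = -1.0 if X.min() < 0 else 0.0
    p = (col_mean - offset) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic; GRM denominator is zero")
    G = (W @ W.T) / denom
    ids = genotype_ids or [f"G{i + 1:03d}" for i in range(X.shape[0])]
    return KinshipMatrix(ids, G, "GRM", {"denominator": float(denom)})


def build_gaussian_kernel(
    coded: np.ndarray,
    bandwidth: float | str = "median",
    genotype_ids: list[str] | None = None,
) -> KinshipMatrix:
    """Gaussian kernel K_ij = exp(-d_ij^2 / (2 theta^2)) on centered rows.

    ``bandwidth="median"`` uses the median off-diagonal Euclidean distance.
    """
    X = np.asarray(coded, dtype=float)
    if np.isnan(X).any():
        raise ValueError("kernel requires a complete matrix")
    Xc = X - X.mean(axis=0)
    d = pdist(Xc, metric="euclidean")
    if isinstance(bandwidth, str):
        if bandwidth != "median":
            raise ValueError(f"unknown bandwidth sentinel {bandwidth!r}")
        theta = float(np.median(d))
        if theta <= 0:
            theta = 1.0  # all rows identical: any bandwidth gives the flat kernel
    else:
        theta = float(bandwidth)
        if theta <= 0:
            raise ValueError("bandwidth must be positive")
    K = squareform(np.exp(-(d**2) / (2.0 * theta**2)))
    np.fill_diagonal(K, 1.0)
    ids = genotype_ids or [f"G{i + 1:03d}" for i in range(X.shape[0])]
    return KinshipMatrix(ids, K, "gaussian_kernel", {"bandwidth": theta})


def cross_gaussian_kernel(
    coded_new: np.ndarray, coded_train: np.ndarray, bandwidth: float, center: np.ndarray
) -> np.ndarray:
    """Kernel rows of new genotypes against the training set."""
    from scipy.spatial.distance import cdist

    d = cdist(coded_new - center, coded_train - center)
    return np.exp(-(d**2) / (2.0 * bandwidth**2))


def regularized_inverse(
    K: KinshipMatrix | np.ndarray,
    jitter: float = 1e-6,
    max_escalations: int = 10,
) -> tuple[np.ndarray, dict]:
    """Inverse of (K + jitter * I), escalating jitter x10 until invertible.

    Returns the inverse and a log dict recording the jitter actually used and
    the number of escalations.
    """
    A = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("regularized_inverse expects a square symmetric matrix")
    n = A.shape[0]
    j = float(jitter)
    for step in range(max_escalations + 1):
        M = A + j * np.eye(n) if j > 0 else A
        try:
            inv = np.linalg.inv(M)
            resid = float(np.abs(M @ inv - np.eye(n)).max())
            if np.isfinite(resid) and resid < 1e-6:
                return inv, {"jitter": j, "escalations": step, "residual": resid}
        except np.linalg.LinAlgError:
            pass
        j = jitter * 10 ** (step + 1) if jitter > 0 else 10.0 ** (step - 6)
    raise np.linalg.LinAlgError(
        f"matrix not invertible after {max_escalations} jitter escalations"
    )
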