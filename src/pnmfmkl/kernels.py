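"""Sample × sample kernels from reconstructed relation blocks.

Each reconstructed (feature × sample) relation becomes a base kernel through
the inner-product map ``K = R_hat @ R_hat.T`` with samples on rows, followed
by cosine normalization, 2-D moving-average smoothing and a projection back
onto the positive semidefinite cone (smoothing perturbs eigenvalues).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["KernelSet", "kernel_from_reconstruction", "normalize_and_smooth"]


@dataclass
class KernelSet:
    """Ordered base kernels over one shared ordered sample list."""

    kernels: list[np.ndarray]
    names: list[str]
    sample_ids: list[str]
    y: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for K, name in zip(self.kernels, self.names):
            if K.shape != (n, n):
                raise ValueError(f"kernel {name!r} shape {K.shape} != ({n}, {n})")
            if not np.allclose(K, K.T, atol=1e-10):
                raise ValueError(f"kernel {name!r} is not symmetric")

    @property
    def n_kernels(self) -> int:
        return len(self.kernels)

    def subset(self, idx: np.ndarray) -> "KernelSet":
        """Restrict all kernels (and labels) to the sample positions *idx*."""
        idx = np.asarray(idx)
        return KernelSet(
            [K[np.ix_(idx, idx)] for K in self.kernels],
            list(self.names),
            [self.sample_ids[i] for i in idx],
            None if self.y is None else self.y[idx],
        )


def kernel_from_reconstruction(R_hat: np.ndarray) -> np.ndarray:
    """Inner-product kernel ``K = R_hat @ R_hat.T`` (samples on rows)."""
    R_hat = np.asarray(R_hat, dtype=float)
    if not np.isfinite(R_hat).all():
        raise ValueError("reconstruction contains non-finite entries")
    K = R_hat @ R_hat.T
    return 0.5 * (K + K.T)  # exact symmetry despite float round-off


def normalize_and_smooth(K: np.ndarray, window: int = 3) -> np.ndarray:
    """Cosine-normalize, box-smooth and PSD-project a kernel.

    Steps: (1) K'(a,b) = K(a,b) / sqrt(K(a,a) K(b,b)); (2) window × window
    moving average with edge replication (window=1 disables smoothing);
    (3) symmetrize and clip negative eigenvalues at zero.
    """
    K = np.asarray(K, dtype=float)
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kernel must be symmetric")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    diag = np.diag(K).copy()
    bad = np.flatnonzero(diag <= 0)
    if bad.size:
        raise ValueError(f"zero/negative kernel diagonal at sample index {int(bad[0])}")
    scale = 1.0 / np.sqrt(diag)
    M = K * np.outer(scale, scale)
    if window > 1:
        M = ndimage.uniform_filter(M, size=window, mode="nearest")
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    if w[0] < 0:
        M = (V * np.clip(w, 0.0, None)) @ V.T
        M = 0.5 * (M + M.T)
    return M
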