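"""Covariance PCA over the 7 joint-angle channels of a block.

The first principal component summarises the dominant mode of joint
coordination; its score series feeds the auto-recurrence analysis, and the
similarity of first eigenvectors across blocks/conditions quantifies
whether the coordination mode itself changed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCAResult", "pca_first_component", "loading_similarity"]


@dataclass
class PCAResult:
    loadings: np.ndarray  # unit 7-vector, hip-flexion loading >= 0
    vaf: float            # variance accounted for by the first component
    scores: np.ndarray    # frames, projection of centered data on loadings


def pca_first_component(angles: np.ndarray) -> PCAResult:
    """First component of the channel covariance (channels centered, not scaled).

    The eigenvector sign is fixed so the hip-flexion (first channel)
    loading is non-negative, making projections reproducible.
    """
    x = np.asarray(angles, dtype=float)
    if x.ndim != 2 or x.shape[1] != 7:
        raise ValueError("expected a frames x 7 angle block")
    if x.shape[0] < 8:
        raise ValueError("need at least 8 frames")
    centered = x - x.mean(axis=0)
    cov = np.cov(centered.T, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    total = float(evals.sum())
    if total <= 0:
        raise ValueError("rank-0 input: no variance in any channel")
    v = evecs[:, -1]
    if v[0] < 0:
        v = -v
    return PCAResult(loadings=v, vaf=float(evals[-1] / total), scores=centered @ v)


def loading_similarity(v1: np.ndarray, v2: np.ndarray, tol: float = 1e-8) -> float:
    """|v1 · v2| for unit vectors; 1 = identical mode up to sign."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    for v in (v1, v2):
        if abs(np.linalg.norm(v) - 1.0) > max(tol, 1e-6):
            raise ValueError("loading vectors must be unit length")
    return float(abs(v1 @ v2))
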