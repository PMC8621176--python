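"""Stage two: turn the smooth stage-one output into a label map by
thresholding.  Re-thresholding never touches stage one."""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "apply_thresholds",
    "kmeans_thresholds",
    "threshold_binary",
]


def threshold_binary(g: np.ndarray, tau: float) -> np.ndarray:
    """Binary label map: 1 where ``g >= tau`` (ties go to foreground), else 0."""
    g = np.asarray(g, dtype=float)
    return (g >= tau).astype(np.int32)


def kmeans_thresholds(g: np.ndarray, K: int, seed: int = 0) -> np.ndarray:
    """Derive K-1 threshold cuts from 1-D k-means on the intensity values.

    Clusters the pixel intensities into ``K`` groups (k-means++ init, 10
    restarts, seeded) and returns the midpoints between consecutive sorted
    cluster centres.  Deterministic for a fixed seed.
    """
    g = np.asarray(g, dtype=float)
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    values = g.reshape(-1, 1)
    n_distinct = np.unique(values).size
    if n_distinct < K:
        raise ValueError(
            f"degenerate input: {n_distinct} distinct values < K = {K} clusters"
        )
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    km.fit(values)
    centres = np.sort(km.cluster_centers_.ravel())
    cuts = 0.5 * (centres[:-1] + centres[1:])
    return cuts


def apply_thresholds(g: np.ndarray, cuts) -> np.ndarray:
    """Multi-phase label map: label = number of cuts <= the pixel value.

    With a single cut this is bit-identical to :func:`threshold_binary`.
    """
    g = np.asarray(g, dtype=float)
    cuts = np.atleast_1d(np.asarray(cuts, dtype=float))
    if cuts.size == 0:
        raise ValueError("need at least one threshold cut")
    if not np.all(np.isfinite(cuts)):
        raise ValueError("threshold cuts must be finite")
    if cuts.size > 1 and not np.all(np.diff(cuts) > 0):
        raise ValueError(f"threshold cuts must be strictly increasing, got {cuts}")
    labels = np.searchsorted(cuts, g.ravel(), side="right")
    return labels.reshape(g.shape).astype(np.int32)
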