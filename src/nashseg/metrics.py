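"""Binary segmentation overlap scores."""

from __future__ import annotations

import numpy as np

__all__ = ["UndefinedScoreError", "dice", "jaccard"]


class UndefinedScoreError(ValueError):
    """Both masks are empty: the overlap score is undefined, not 0."""


def _as_masks(seg: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    seg = np.asarray(seg)
    gt = np.asarray(gt)
    if seg.shape != gt.shape:
        raise ValueError(f"shape mismatch: seg {seg.shape} vs gt {gt.shape}")
    for name, m in (("seg", seg), ("gt", gt)):
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} must be binary (values in {{0,1}}), got {vals}")
    return seg.astype(bool), gt.astype(bool)


def dice(seg: np.ndarray, gt: np.ndarray) -> float:
    """DICE coefficient 2|A∩B| / (|A|+|B|) of two binary masks."""
    a, b = _as_masks(seg, gt)
    denom = a.sum() + b.sum()
    if denom == 0:
        raise UndefinedScoreError("both masks are empty; DICE is undefined")
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def jaccard(seg: np.ndarray, gt: np.ndarray) -> float:
    """Jaccard index |A∩B| / |A∪B| of two binary masks."""
    a, b = _as_masks(seg, gt)
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise UndefinedScoreError("both masks are empty; Jaccard is undefined")
    return float(np.logical_and(a, b).sum() / union)
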