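"""Synthetic piecewise-smooth test images.

The generator produces the statistical structure the model targets: regions
with smooth random boundaries (including one thin elongated band, standing
in for vessel/"tail" structures), per-region base intensities with a smooth
low-frequency drift, and additive Gaussian noise on the 8-bit scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["PhantomSpec", "add_noise", "make_phantom"]


@dataclass
class PhantomSpec:
    """Recipe for a piecewise-smooth phantom.

    ``intensity_levels`` are region base intensities on the 0-255 scale,
    one per phase; consecutive sorted levels must be separated by at least
    ``contrast_gap``.  ``gradient_amplitude`` bounds the peak-to-peak
    within-region smooth intensity drift.
    """

    shape: tuple[int, int] = (128, 128)
    n_phases: int = 2
    intensity_levels: tuple[float, ...] = (90.0, 150.0)
    gradient_amplitude: float = 10.0
    contrast_gap: float = 30.0
    seed: int = 0
    thin_structure: bool = True

    def __post_init__(self) -> None:
        if len(self.shape) != 2 or min(self.shape) < 8:
            raise ValueError(f"shape must be 2-D and at least 8x8, got {self.shape}")
        if self.n_phases < 2:
            raise ValueError(f"n_phases must be >= 2, got {self.n_phases}")
        levels = tuple(float(v) for v in self.intensity_levels)
        if len(levels) != self.n_phases:
            raise ValueError(
                f"need {self.n_phases} intensity levels, got {len(levels)}"
            )
        if min(levels) < 0 or max(levels) > 255:
            raise ValueError(f"intensity levels must lie in [0, 255], got {levels}")
        gaps = np.diff(np.sort(levels))
        if self.contrast_gap > 0 and np.any(gaps < self.contrast_gap):
            raise ValueError(
                f"consecutive intensity levels must differ by >= contrast_gap "
                f"({self.contrast_gap}); sorted gaps are {gaps}"
            )
        if self.gradient_amplitude < 0:
            raise ValueError("gradient_amplitude must be >= 0")


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean unit-range smooth random field (low-frequency blobs)."""
    s = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    s -= s.mean()
    peak = np.abs(s).max()
    return s / peak if peak > 0 else s


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate (clean image, ground-truth label map) from a spec.

    Regions are level sets of a smooth random field split at intensity
    quantiles, so boundaries are smooth closed curves; one thin sinusoidal
    band is carved into the top phase to emulate elongated structures.
    The image is ``level[label] + drift`` with a global smooth drift whose
    peak-to-peak range is ``gradient_amplitude``, so the intensity range
    within any region is bounded by ``gradient_amplitude``.  Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.shape
    K = spec.n_phases

    base = _smooth_noise(rng, (H, W), sigma=min(H, W) / 8.0)
    qs = np.quantile(base, np.linspace(0, 1, K + 1)[1:-1])
    labels = np.searchsorted(qs, base.ravel(), side="right").reshape(H, W)

    if spec.thin_structure:
        # thin elongated band (~3 px) along a random sinusoidal path,
        # assigned to the brightest phase
        jj = np.arange(W)
        amp = 0.08 * H * (1.0 + rng.uniform(-0.3, 0.3))
        phase = rng.uniform(0, 2 * np.pi)
        cycles = rng.uniform(1.0, 2.0)
        centre = 0.25 * H + amp * np.sin(2 * np.pi * cycles * jj / W + phase)
        ii = np.arange(H)[:, None]
        band = np.abs(ii - centre[None, :]) <= 1.5
        labels = labels.copy()
        labels[band] = K - 1

    levels = np.sort(np.asarray(spec.intensity_levels, dtype=float))
    clean = levels[labels]

    if spec.gradient_amplitude > 0:
        drift = _smooth_noise(rng, (H, W), sigma=min(H, W) / 4.0)
        clean = clean + 0.5 * spec.gradient_amplitude * drift

    return clean, labels.astype(np.int32)


def add_noise(
    img: np.ndarray, sigma: float, seed: int = 0, clip: bool = False
) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise of standard deviation ``sigma``.

    No clipping by default (strong noise on near-binary images would be
    severely censored otherwise); pass ``clip=True`` to clamp to [0, 255].
    """
    img = np.asarray(img, dtype=float)
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    out = img + rng.normal(0.0, sigma, size=img.shape)
    if clip:
        out = np.clip(out, 0.0, 255.0)
    return out
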