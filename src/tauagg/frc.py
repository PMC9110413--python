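"""Fourier ring correlation resolution estimation.

Localizations are split randomly into two statistically independent halves,
each rendered as a 2-D histogram, and the ring-averaged normalized
cross-spectrum is computed as a function of spatial frequency.  The image
resolution is the inverse of the first spatial frequency at which the curve
drops below the fixed 1/7 threshold; if the curve never crosses, resolution is
reported as not determined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FRC_THRESHOLD = 1.0 / 7.0


@dataclass
class FrcResult:
    spatial_frequency: np.ndarray   # 1/nm
    correlation: np.ndarray
    resolution_nm: float | None     # None when the curve never crosses 1/7
    threshold: float = FRC_THRESHOLD

    @property
    def determined(self) -> bool:
        return self.resolution_nm is not None


def _render(x: np.ndarray, y: np.ndarray, x0: float, y0: float,
            pixel_nm: float, n: int) -> np.ndarray:
    cols = np.clip(((x - x0) / pixel_nm).astype(int), 0, n - 1)
    rows = np.clip(((y - y0) / pixel_nm).astype(int), 0, n - 1)
    img = np.zeros((n, n))
    np.add.at(img, (rows, cols), 1.0)
    return img


def frc_curve(img1: np.ndarray, img2: np.ndarray, pixel_nm: float
              ) -> tuple[np.ndarray, np.ndarray]:
    """Ring-averaged normalized cross-spectrum of two equal-shape images.

    Ring width is one frequency bin.  Returns (spatial frequency in 1/nm,
    correlation); the zero-frequency bin equals 1 for non-empty images.
    """
    if img1.shape != img2.shape or img1.ndim != 2:
        raise ValueError("images must be 2-D with identical shape")
    n = img1.shape[0]
    f1 = np.fft.fftshift(np.fft.fft2(img1))
    f2 = np.fft.fftshift(np.fft.fft2(img2))
    cy = cx = n // 2
    yy, xx = np.indices(img1.shape)
    ring = np.round(np.hypot(yy - cy, xx - cx)).astype(int)
    n_rings = n // 2
    cross = np.zeros(n_rings)
    p1 = np.zeros(n_rings)
    p2 = np.zeros(n_rings)
    flat = ring.ravel()
    valid = flat < n_rings
    np.add.at(cross, flat[valid], (f1 * np.conj(f2)).real.ravel()[valid])
    np.add.at(p1, flat[valid], (np.abs(f1) ** 2).ravel()[valid])
    np.add.at(p2, flat[valid], (np.abs(f2) ** 2).ravel()[valid])
    denom = np.sqrt(p1 * p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cross / denom, 0.0)
    freq = np.arange(n_rings) / (n * pixel_nm)
    return freq, corr


def frc_resolution(locs: pd.DataFrame, pixel_nm: float = 10.0,
                   split_seed: int = 0, n_pixels: int | None = None,
                   halves: tuple[np.ndarray, np.ndarray] | None = None
                   ) -> FrcResult:
    """FRC resolution of a localization dataset.

    The table is split into random halves (``split_seed``), each rendered at
    ``pixel_nm``, and the resolution is 1 / (first frequency where the curve
    drops below 1/7), linearly interpolated between frequency bins.  Passing
    ``halves`` overrides the split with two pre-made images (used e.g. for the
    self-correlation identity).
    """
    if halves is not None:
        img1, img2 = halves
    else:
        if len(locs) < 2:
            raise ValueError("need at least 2 localizations")
        rng = np.random.default_rng(split_seed)
        pick = rng.random(len(locs)) < 0.5
        x = locs["x_nm"].to_numpy()
        y = locs["y_nm"].to_numpy()
        x0, y0 = x.min(), y.min()
        if n_pixels is None:
            span = max(x.max() - x0, y.max() - y0)
            n_pixels = int(np.ceil(span / pixel_nm)) + 1
            n_pixels += n_pixels % 2  # even size
        img1 = _render(x[pick], y[pick], x0, y0, pixel_nm, n_pixels)
        img2 = _render(x[~pick], y[~pick], x0, y0, pixel_nm, n_pixels)
    freq, corr = frc_curve(img1, img2, pixel_nm)
    resolution = None
    for k in range(1, len(corr)):
        if corr[k] < FRC_THRESHOLD:
            # linear interpolation of the crossing between bins k-1 and k
            c0, c1 = corr[k - 1], corr[k]
            frac = (c0 - FRC_THRESHOLD) / (c0 - c1) if c0 != c1 else 0.0
            q = freq[k - 1] + frac * (freq[k] - freq[k - 1])
            if q > 0:
                resolution = float(1.0 / q)
            break
    return FrcResult(spatial_frequency=freq, correlation=corr,
                     resolution_nm=resolution)
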