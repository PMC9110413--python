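"""Diffraction-limited aggregate morphometry.

Time-averaged TIRF images of dye-positive tau aggregates are band-pass
filtered, blurred, and thresholded at 2 % above the image median; connected
foreground components are the particles.  Each particle's apparent length is
measured by thinning its footprint to a one-pixel skeleton and summing
8-connectivity step distances along the longest geodesic path, at 107.2 nm per
pixel.  Intensities are background-corrected per pixel as the
signal-to-background ratio SBR = (intensity - background) / background, with
the background taken as the median of the whole image; a particle's corrected
intensity is the sum of its pixels' SBR values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, gaussian_filter
from skimage.measure import label, regionprops

from .io import ImageStack
from .morphology import mask_length_px

logger = logging.getLogger("tauagg")


@dataclass
class ParticleMask:
    """Pixel support of one segmented particle."""

    pixels: np.ndarray          # (n, 2) array of (row, col)
    shape: tuple[int, int]      # full-image shape
    background_level: float     # median of the whole (processed) image

    def to_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m

    @property
    def boundary(self) -> np.ndarray:
        """Outline pixels: mask minus its 4-neighbourhood erosion."""
        m = self.to_mask()
        interior = binary_erosion(m, structure=np.array([[0, 1, 0],
                                                         [1, 1, 1],
                                                         [0, 1, 0]]))
        return np.argwhere(m & ~interior)


@dataclass
class ParticleMeasurement:
    length_nm: float
    total_skeleton_nm: float
    corrected_intensity: float
    n_pixels: int


def average_stack(stack: ImageStack) -> np.ndarray:
    """Per-pixel mean over all frames."""
    return stack.data.mean(axis=0)


def segment_particles(image: np.ndarray,
                      bandpass: tuple[float, float] = (1.0, 20.0),
                      blur_sigma_px: float = 1.0,
                      threshold_frac: float = 0.02,
                      min_particle_px: int = 3) -> list[ParticleMask]:
    """Segment aggregates from a time-averaged image.

    The image is band-passed with a difference of Gaussians (sigmas
    ``bandpass``, in pixels) with its DC level restored, blurred, and
    thresholded at ``median * (1 + threshold_frac)``.  Connected components
    (8-connectivity) of the foreground with at least ``min_particle_px``
    pixels are returned.  Because the threshold is multiplicative in the
    median, segmentation is invariant to rescaling the image by any c > 0.
    """
    if blur_sigma_px <= 0:
        raise ValueError("blur sigma must be positive")
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    low, high = bandpass
    bandpassed = (gaussian_filter(image, low) - gaussian_filter(image, high)
                  + np.median(image))
    processed = gaussian_filter(bandpassed, blur_sigma_px)
    background = float(np.median(processed))
    foreground = processed > background * (1.0 + threshold_frac)
    labels = label(foreground, connectivity=2)
    particles = []
    for region in regionprops(labels):
        if region.num_pixels < min_particle_px:
            continue
        particles.append(ParticleMask(pixels=region.coords, shape=image.shape,
                                      background_level=background))
    logger.info("segment_particles: %d particles (threshold_frac=%.3g, "
                "min_particle_px=%d)", len(particles), threshold_frac,
                min_particle_px)
    return particles


def particle_length(mask: ParticleMask, pixel_size_nm: float = 107.2
                    ) -> tuple[float, float]:
    """(longest-geodesic, total) skeleton length of one particle, in nm.

    The mask is thinned to a single-pixel-wide skeleton; steps along the
    skeleton count 1 pixel axially and sqrt(2) diagonally.  A single-pixel
    skeleton has length 0.
    """
    geo_px, tot_px = mask_length_px(mask.to_mask())
    return geo_px * pixel_size_nm, tot_px * pixel_size_nm


def sbr_intensity(mask: ParticleMask, image: np.ndarray,
                  background: float | None = None) -> float:
    """Sum over mask pixels of (pixel - background) / background.

    ``background`` defaults to the median of ``image``.
    """
    image = np.asarray(image, dtype=float)
    if background is None:
        background = float(np.median(image))
    if background <= 0:
        raise ValueError("undefined SBR: background must be positive")
    values = image[mask.pixels[:, 0], mask.pixels[:, 1]]
    return float(np.sum((values - background) / background))


def measure_particles(image: np.ndarray, particles: list[ParticleMask],
                      pixel_size_nm: float = 107.2) -> list[ParticleMeasurement]:
    out = []
    for mask in particles:
        geo, tot = particle_length(mask, pixel_size_nm)
        out.append(ParticleMeasurement(
            length_nm=geo, total_skeleton_nm=tot,
            corrected_intensity=sbr_intensity(mask, image),
            n_pixels=len(mask.pixels)))
    return out


def field_summary(measurements: list[ParticleMeasurement],
                  bin_edges_nm=(0.0, 500.0, 1000.0, float("inf"))) -> dict:
    """Per-field ensemble summary: count, mean length, length histogram.

    ``mean_length_nm`` is ``None`` when there are no particles.  Histogram bin
    edges default to the 500/1000 nm thresholds used to classify small vs
    fibrillar aggregates.
    """
    lengths = np.array([m.length_nm for m in measurements])
    edges = np.asarray(bin_edges_nm, dtype=float)
    hist, _ = np.histogram(lengths, bins=edges)
    summary = {
        "count": len(measurements),
        "mean_length_nm": float(lengths.mean()) if len(lengths) else None,
        "bin_edges_nm": edges.tolist(),
        "histogram": hist.tolist(),
        "fractions": (hist / len(lengths)).tolist() if len(lengths) else None,
    }
    return summary


def analyze_stack(stack: ImageStack, **segment_kwargs) -> pd.DataFrame:
    """Full diffraction-limited pipeline: average, segment, measure.

    Returns a per-particle table (length_nm, total_skeleton_nm,
    corrected_intensity, n_pixels).
    """
    image = average_stack(stack)
    particles = segment_particles(image, **segment_kwargs)
    measurements = measure_particles(image, particles, stack.pixel_size_nm)
    return pd.DataFrame([m.__dict__ for m in measurements])
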