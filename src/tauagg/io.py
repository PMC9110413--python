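"""Readers and writers for the on-disk formats the pipeline consumes and emits.

Conventions used throughout the package:

* x = column, y = row, both in nanometres, origin at the centre of pixel
  (0, 0); frames are 0-based; the time of frame ``f`` is
  ``f * frame_interval_ms``.
* Localization tables are plain :class:`pandas.DataFrame` objects with the
  canonical columns ``frame, t_ms, x_nm, y_nm, intensity, precision_nm``,
  sorted by frame then x.
* Spectra are two-column text (mass in Da, intensity), strictly increasing
  mass axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("tauagg")

#: Canonical localization-table columns, in order.
LOC_COLUMNS = ["frame", "t_ms", "x_nm", "y_nm", "intensity", "precision_nm"]

#: Camera pixel pitch of the TIRF setup, nm.
DEFAULT_PIXEL_NM = 107.2

#: Named column mappings for common SMLM table layouts.  Keys are dialect
#: names; values map canonical names to the column names found in the file.
LOC_DIALECTS = {
    "canonical": {c: c for c in LOC_COLUMNS},
    # GDSC/Peak-Fit style export (positions already in nm)
    "peakfit": {
        "frame": "Frame",
        "x_nm": "X",
        "y_nm": "Y",
        "intensity": "Signal",
        "precision_nm": "Precision (nm)",
    },
}


@dataclass
class ImageStack:
    """A (frame, row, col) intensity stack in arbitrary detector units."""

    data: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_NM
    frame_interval_ms: float = 50.0
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3 or self.data.shape[0] == 0:
            raise ValueError("image stack must be (frame, row, col) with >= 1 frame")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("intensities must be finite and >= 0")
        if self.pixel_size_nm <= 0 or self.frame_interval_ms <= 0:
            raise ValueError("pixel_size_nm and frame_interval_ms must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def frame_time_ms(self, f: int) -> float:
        return f * self.frame_interval_ms


@dataclass
class MassSpectrum:
    """A deconvolved (zero-charge) native mass spectrum."""

    mass_da: np.ndarray
    intensity: np.ndarray
    mass_range: tuple[float, float] = (40_000.0, 44_000.0)

    def __post_init__(self) -> None:
        self.mass_da = np.asarray(self.mass_da, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mass_da.ndim != 1 or self.mass_da.shape != self.intensity.shape:
            raise ValueError("mass and intensity must be 1-D and equal length")
        if self.mass_da.size >= 2 and not np.all(np.diff(self.mass_da) > 0):
            raise ValueError("non-monotone mass axis")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")

    @property
    def total_area(self) -> float:
        if self.mass_da.size < 2:
            return 0.0
        return float(np.trapezoid(self.intensity, self.mass_da))


def read_image_stack(path, pixel_size_nm: float = DEFAULT_PIXEL_NM,
                     frame_interval_ms: float = 50.0,
                     channel_label: str = "") -> ImageStack:
    """Read a multi-page TIFF (or single image) into an :class:`ImageStack`.

    Metadata absent from the file is populated from the arguments.
    """
    try:
        data = tifffile.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / non-raster content
        raise ValueError(f"unreadable stack: {path}") from exc
    data = np.asarray(data)
    if data.ndim not in (2, 3) or data.size == 0:
        raise ValueError(f"unreadable stack: {path} (not a 2-D/3-D raster)")
    return ImageStack(data.astype(float), pixel_size_nm=pixel_size_nm,
                      frame_interval_ms=frame_interval_ms,
                      channel_label=channel_label)


def write_image_stack(path, stack: ImageStack) -> None:
    tifffile.imwrite(path, np.asarray(stack.data, dtype=np.float32))


def empty_localizations() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in LOC_COLUMNS})


def as_localization_table(df: pd.DataFrame, frame_interval_ms: float = 20.0,
                          default_precision_nm: float = 20.0) -> pd.DataFrame:
    """Coerce a frame/x/y table into the canonical localization layout."""
    out = pd.DataFrame()
    out["frame"] = np.asarray(df["frame"], dtype=int)
    out["x_nm"] = np.asarray(df["x_nm"], dtype=float)
    out["y_nm"] = np.asarray(df["y_nm"], dtype=float)
    out["intensity"] = (np.asarray(df["intensity"], dtype=float)
                        if "intensity" in df else np.ones(len(df)))
    if "precision_nm" in df:
        out["precision_nm"] = np.asarray(df["precision_nm"], dtype=float)
    else:
        logger.warning("precision column absent; filling with default %.1f nm",
                       default_precision_nm)
        out["precision_nm"] = default_precision_nm
    if "t_ms" in df:
        out["t_ms"] = np.asarray(df["t_ms"], dtype=float)
    else:
        out["t_ms"] = out["frame"] * float(frame_interval_ms)
    if np.any(out["frame"] < 0):
        raise ValueError("frames must be non-negative")
    if np.any(out["precision_nm"] < 0):
        raise ValueError("negative precision")
    out = out[LOC_COLUMNS].sort_values(["frame", "x_nm"], kind="stable")
    return out.reset_index(drop=True)


def read_localizations(path, dialect: str = "canonical",
                       frame_interval_ms: float = 20.0,
                       default_precision_nm: float = 20.0,
                       column_map: dict | None = None) -> pd.DataFrame:
    """Read a delimited localization table into the canonical layout.

    ``dialect`` selects a named column mapping (:data:`LOC_DIALECTS`);
    ``column_map`` overrides it with an explicit canonical→file mapping.
    """
    mapping = column_map if column_map is not None else LOC_DIALECTS.get(dialect)
    if mapping is None:
        raise ValueError(f"unknown localization dialect: {dialect!r}")
    raw = pd.read_csv(path)
    if raw.empty:
        return empty_localizations()
    renamed = pd.DataFrame()
    for canonical, col in mapping.items():
        if col in raw.columns:
            renamed[canonical] = raw[col]
    for required in ("frame", "x_nm", "y_nm"):
        if required not in renamed:
            raise ValueError(
                f"unmappable columns: need {required!r} via dialect {dialect!r}")
    table = as_localization_table(renamed, frame_interval_ms=frame_interval_ms,
                                  default_precision_nm=default_precision_nm)
    logger.info("read %d localizations from %s (dialect=%s)", len(table), path, dialect)
    return table


def write_localizations(path, locs: pd.DataFrame) -> None:
    locs[LOC_COLUMNS].to_csv(path, index=False)


def read_spectrum(path, mass_range: tuple[float, float] = (40_000.0, 44_000.0)
                  ) -> MassSpectrum:
    """Read two-column (mass Da, intensity) text; comma or whitespace separated."""
    try:
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError:
        arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] < 2:
        raise ValueError("spectrum file must have two columns (mass, intensity)")
    return MassSpectrum(arr[:, 0], arr[:, 1], mass_range=mass_range)


def write_spectrum(path, spectrum: MassSpectrum) -> None:
    np.savetxt(path, np.column_stack([spectrum.mass_da, spectrum.intensity]),
               delimiter=",", fmt="%.8g")
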