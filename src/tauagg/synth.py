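"""Synthetic-data generators with known ground truth.

Every input the analysis stages consume can be generated here: blinking-emitter
localization streams from aggregates of known geometry (fibrillar segments vs
amorphous blobs) plus persistent fiducial markers, EMCCD-like images of
PSF-blurred aggregates at the camera's 107.2 nm pixel pitch, deconvolved-style
mass spectra built on the 80 Da phosphate / 23 Da adduct ladder, per-cell
calcium/ROS traces and movies, and vesicle-influx fluorescence triplets.

All generators are pure functions of (parameters, seed).  Defaults follow the
imaging conditions of the study being emulated: 20 ms SMLM exposure, 20 nm
localization precision, 107.2 nm camera pixels, 1 s cell-movie frames, 85 %
of cells responding with calcium transients, ROS ramping to +18 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ImageStack, MassSpectrum, as_localization_table, empty_localizations

SEGMENT = "segment"
BLOB = "blob"


@dataclass
class Aggregate:
    """One ground-truth aggregate: a line segment (fibril) or isotropic blob."""

    shape: str                     # "segment" or "blob"
    anchor_nm: tuple[float, float]  # (x, y) of segment start / blob centre
    size_nm: float                 # segment length or blob radius
    orientation_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in (SEGMENT, BLOB):
            raise ValueError(f"unknown aggregate shape {self.shape!r}")
        if self.size_nm <= 0:
            raise ValueError("aggregate size must be positive")

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n points uniform on the support (along segment / inside blob), nm."""
        ax, ay = self.anchor_nm
        if self.shape == SEGMENT:
            t = rng.uniform(0.0, 1.0, n)
            dx = np.cos(self.orientation_rad) * self.size_nm
            dy = np.sin(self.orientation_rad) * self.size_nm
            return np.column_stack([ax + t * dx, ay + t * dy])
        r = self.size_nm * np.sqrt(rng.uniform(0.0, 1.0, n))
        theta = rng.uniform(0.0, 2.0 * np.pi, n)
        return np.column_stack([ax + r * np.cos(theta), ay + r * np.sin(theta)])


@dataclass
class GroundTruth:
    """Generator parameters recorded for recovery tests."""

    aggregates: list[Aggregate] = field(default_factory=list)
    fiducials: list[tuple[float, float]] = field(default_factory=list)
    spike_times: list[list[int]] = field(default_factory=list)
    responders: list[bool] = field(default_factory=list)
    state_weights: dict[tuple[int, int], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state_weights:
            total = sum(self.state_weights.values())
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError("state_weights must sum to 1")


@dataclass
class EmitterModel:
    """Blinking statistics of the transiently binding dye."""

    burst_rate: float = 4.0          # bursts per aggregate per 1000 frames
    burst_duration_frames: float = 3.0  # geometric mean
    locs_per_frame: float = 1.0
    precision_nm: float = 20.0
    exposure_ms: float = 20.0

    def __post_init__(self) -> None:
        for name in ("burst_rate", "burst_duration_frames", "locs_per_frame",
                     "precision_nm", "exposure_ms"):
            if getattr(self, name) < 0 or (name != "precision_nm"
                                           and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")


def gen_smlm_stream(truth: GroundTruth, emitter: EmitterModel | None = None,
                    n_frames: int = 10_000, seed: int | None = None,
                    bursts_per_aggregate: int | None = None) -> pd.DataFrame:
    """Generate a localization table from blinking emitters on aggregates.

    Each burst is a run of consecutive frames during which one dye molecule
    sits at a fixed point of the aggregate support; every frame of the burst
    yields localizations at that point plus isotropic Gaussian noise of s.d.
    ``precision_nm``.  Fiducials emit in every frame at a fixed position with
    5x better precision.  ``bursts_per_aggregate`` pins the burst count per
    aggregate exactly; otherwise it is Poisson with mean
    ``burst_rate * n_frames / 1000``.
    """
    if emitter is None:
        emitter = EmitterModel()
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not truth.aggregates and not truth.fiducials:
        raise ValueError("empty ground truth: no aggregates and no fiducials")
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    frames, xs, ys, intens, precs = [], [], [], [], []
    p_stop = 1.0 / emitter.burst_duration_frames

    for agg in truth.aggregates:
        if bursts_per_aggregate is not None:
            n_bursts = bursts_per_aggregate
        else:
            n_bursts = rng.poisson(emitter.burst_rate * n_frames / 1000.0)
        sites = agg.sample_points(n_bursts, rng)
        for b in range(n_bursts):
            duration = max(2, int(rng.geometric(p_stop)))
            start = int(rng.integers(0, max(1, n_frames - duration)))
            for f in range(start, min(start + duration, n_frames)):
                k = max(1, int(rng.poisson(emitter.locs_per_frame)))
                pos = sites[b] + rng.normal(0.0, emitter.precision_nm, (k, 2))
                for x, y in pos:
                    frames.append(f)
                    xs.append(x)
                    ys.append(y)
                    intens.append(rng.gamma(5.0, 200.0))
                    precs.append(emitter.precision_nm)

    fid_precision = max(emitter.precision_nm / 5.0, 1e-9)
    for fx, fy in truth.fiducials:
        for f in range(n_frames):
            frames.append(f)
            xs.append(fx + rng.normal(0.0, fid_precision))
            ys.append(fy + rng.normal(0.0, fid_precision))
            intens.append(rng.gamma(50.0, 200.0))
            precs.append(fid_precision)

    if not frames:
        return empty_localizations()
    table = pd.DataFrame({"frame": frames, "x_nm": xs, "y_nm": ys,
                          "intensity": intens, "precision_nm": precs})
    return as_localization_table(table, frame_interval_ms=emitter.exposure_ms)


def render_dl_stack(truth: GroundTruth, psf_sigma_nm: float = 150.0,
                    noise: tuple[float, float, float] = (1.0, 2.0, 20.0),
                    n_frames: int = 100, fov_px: tuple[int, int] = (128, 128),
                    pixel_size_nm: float = 107.2, amplitude: float = 200.0,
                    seed: int | None = None) -> ImageStack:
    """Render aggregates as PSF-blurred structures in an EMCCD-like stack.

    ``noise = (gain, read_sd, background)``: the signal plus background is
    Poisson-sampled, multiplied by ``gain`` and given Gaussian read noise.
    ``gain = 0`` disables both noise sources (noise-free rendering at unit
    gain), leaving ``signal + background`` exactly.
    """
    from scipy.ndimage import gaussian_filter

    if psf_sigma_nm <= 0:
        raise ValueError("psf_sigma_nm must be positive")
    gain, read_sd, background = noise
    if background < 0:
        raise ValueError("background must be >= 0")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    h, w = fov_px

    support = np.zeros((h, w), dtype=float)
    step_nm = pixel_size_nm / 4.0
    for agg in truth.aggregates:
        ax, ay = agg.anchor_nm
        if agg.shape == SEGMENT:
            n_pts = max(2, int(np.ceil(agg.size_nm / step_nm)) + 1)
            t = np.linspace(0.0, 1.0, n_pts)
            px = ax + t * np.cos(agg.orientation_rad) * agg.size_nm
            py = ay + t * np.sin(agg.orientation_rad) * agg.size_nm
        else:
            n_pts = max(4, int(np.ceil(np.pi * agg.size_nm**2 / step_nm**2)))
            r = agg.size_nm * np.sqrt(np.linspace(0.0, 1.0, n_pts))
            theta = np.linspace(0.0, 2.0 * np.pi * n_pts / 7.0, n_pts)  # sunflower
            px = ax + r * np.cos(theta)
            py = ay + r * np.sin(theta)
        cols = np.round(px / pixel_size_nm).astype(int)
        rows = np.round(py / pixel_size_nm).astype(int)
        if np.any((cols < 0) | (cols >= w) | (rows < 0) | (rows >= h)):
            raise ValueError("aggregate outside field of view")
        np.add.at(support, (rows, cols), 1.0 / n_pts)

    if support.max() > 0:
        support = support / support.max()
    signal = gaussian_filter(support, psf_sigma_nm / pixel_size_nm) * amplitude

    frames = np.empty((n_frames, h, w), dtype=float)
    for f in range(n_frames):
        if gain == 0:
            frames[f] = signal + background
        else:
            shot = rng.poisson(np.clip(signal + background, 0, None)).astype(float)
            frames[f] = np.clip(gain * shot + rng.normal(0.0, read_sd, (h, w)),
                                0.0, None)
    return ImageStack(frames, pixel_size_nm=pixel_size_nm)


def gen_spectrum(base_mass_da: float, state_weights: dict[tuple[int, int], float],
                 peak_fwhm_da: float = 8.0, noise_sd: float = 0.0,
                 grid: tuple[float, float, float] = (39_000.0, 44_000.0, 0.5),
                 phosphate_da: float = 80.0, adduct_da: float = 23.0,
                 seed: int = 0) -> MassSpectrum:
    """Mixture of Gaussian peaks on the phosphate/adduct mass ladder.

    Each state (p, a) contributes a unit-area Gaussian of the given FWHM at
    ``base + 80 p + 23 a`` scaled by its weight; truncated-at-zero Gaussian
    noise of s.d. ``noise_sd`` is added pointwise.
    """
    total = sum(state_weights.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError("state weights must be normalized")
    lo, hi, step = grid
    mass = np.arange(lo, hi + step / 2.0, step)
    sigma = peak_fwhm_da / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    intensity = np.zeros_like(mass)
    for (p, a), wt in state_weights.items():
        centre = base_mass_da + phosphate_da * p + adduct_da * a
        if not (lo <= centre <= hi):
            raise ValueError(f"state ({p},{a}) mass {centre} outside grid")
        intensity += wt * np.exp(-0.5 * ((mass - centre) / sigma) ** 2) \
            / (sigma * np.sqrt(2.0 * np.pi))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = np.clip(intensity + rng.normal(0.0, noise_sd, mass.shape), 0, None)
    return MassSpectrum(mass, intensity, mass_range=(lo, hi))


def gen_calcium_trace(n_frames: int, spike_times: list[int], amplitude: float = 0.10,
                      rise_frames: int = 2, decay_tau: float = 10.0,
                      baseline: float = 1.0, noise_sd: float = 0.02,
                      drift_amp: float = 0.0,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Baseline + slow drift + peak-shaped spikes + white noise.

    A spike rises linearly over ``rise_frames`` frames to ``amplitude`` above
    baseline, then decays exponentially with time constant ``decay_tau``
    frames.  Amplitude units are fractions of the baseline.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    t = np.arange(n_frames, dtype=float)
    trace = np.full(n_frames, baseline, dtype=float)
    if drift_amp:
        trace += drift_amp * baseline * np.sin(2.0 * np.pi * t / max(n_frames, 1))
    for onset in spike_times:
        if not 0 <= onset < n_frames:
            raise ValueError("spike time outside movie duration")
        rel = t - onset
        kernel = np.where(
            rel < 0, 0.0,
            np.where(rel < rise_frames, rel / max(rise_frames, 1),
                     np.exp(-(rel - rise_frames) / decay_tau)))
        trace += amplitude * baseline * kernel
    if noise_sd > 0:
        trace += rng.normal(0.0, noise_sd * baseline, n_frames)
    return trace


def gen_cell_movie(n_cells: int = 20, cell_radius_px: float = 10.0,
                   spike_model: tuple[float, int, float] = (0.10, 2, 10.0),
                   ros_ramp: float = 4.6e-4, n_frames: int = 600,
                   frame_shape: tuple[int, int] = (256, 256),
                   responding_frac: float = 0.85, stimulus_frame: int = 100,
                   ionomycin_frame: int = 550, spikes_per_responder: float = 3.0,
                   trace_noise_sd: float = 0.02, pixel_noise_sd: float = 1.0,
                   seed: int = 0) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Dual-channel cell movie: calcium spikes (ch. 1) and a ROS ramp (ch. 2).

    Responding cells (fraction ``responding_frac``, rounded to whole cells)
    receive >= 1 calcium spike after ``stimulus_frame`` and a linear ROS ramp
    of fractional slope ``ros_ramp`` per frame from the stimulus on.  The
    default ramp is chosen so the *rendered* per-cell readout (disk-mean
    trace over the cell plus image background) rises by ~18 % between the
    50-frame windows before stimulus and before ionomycin at the default
    timing.
    """
    rng = np.random.default_rng(seed)
    amplitude, rise_frames, decay_tau = spike_model
    h, w = frame_shape

    # place cells on a jittered grid with a safe margin — no overlap by design
    pitch = int(np.ceil(4 * cell_radius_px))
    margin = int(np.ceil(2 * cell_radius_px))
    grid_r = np.arange(margin, h - margin, pitch)
    grid_c = np.arange(margin, w - margin, pitch)
    slots = [(r, c) for r in grid_r for c in grid_c]
    if len(slots) < n_cells:
        raise ValueError("cells do not fit in frame without overlap")
    order = rng.permutation(len(slots))[:n_cells]
    centres = [(slots[i][0] + rng.uniform(-2, 2), slots[i][1] + rng.uniform(-2, 2))
               for i in order]

    n_resp = int(round(responding_frac * n_cells))
    responders = [i < n_resp for i in range(n_cells)]

    spike_times: list[list[int]] = []
    ca_traces = np.empty((n_cells, n_frames))
    ros_traces = np.empty((n_cells, n_frames))
    t = np.arange(n_frames, dtype=float)
    for i in range(n_cells):
        if responders[i]:
            n_spk = max(1, rng.poisson(spikes_per_responder))
            lo = stimulus_frame + 5
            hi = max(lo + 1, ionomycin_frame - 6 * int(decay_tau))
            times = sorted(rng.integers(lo, hi, n_spk).tolist())
            # enforce separation so spikes are individually resolvable
            cleaned = []
            for s in times:
                if not cleaned or s - cleaned[-1] >= 4 * decay_tau:
                    cleaned.append(int(s))
            times = cleaned
        else:
            times = []
        spike_times.append(times)
        ca_traces[i] = gen_calcium_trace(
            n_frames, times, amplitude=amplitude, rise_frames=rise_frames,
            decay_tau=decay_tau, noise_sd=trace_noise_sd, rng=rng)
        ramp = np.where(t > stimulus_frame,
                        ros_ramp * (t - stimulus_frame), 0.0)
        ros = 1.0 + (ramp if responders[i] else 0.0)
        ros_traces[i] = ros + rng.normal(0.0, trace_noise_sd, n_frames)

    # render both channels: smooth disk profile per cell
    rr, cc = np.mgrid[0:h, 0:w]
    ca = np.zeros((n_frames, h, w))
    ros = np.zeros((n_frames, h, w))
    cell_amp, background = 150.0, 10.0
    profiles = []
    for (r0, c0) in centres:
        d = np.hypot(rr - r0, cc - c0)
        profiles.append(1.0 / (1.0 + np.exp((d - cell_radius_px) / 1.5)))
    for f in range(n_frames):
        ca_f = np.full((h, w), background)
        ros_f = np.full((h, w), background)
        for i, prof in enumerate(profiles):
            ca_f = ca_f + cell_amp * ca_traces[i, f] * prof
            ros_f = ros_f + cell_amp * ros_traces[i, f] * prof
        if pixel_noise_sd > 0:
            ca_f = ca_f + rng.normal(0.0, pixel_noise_sd, (h, w))
            ros_f = ros_f + rng.normal(0.0, pixel_noise_sd, (h, w))
        ca[f] = np.clip(ca_f, 0, None)
        ros[f] = np.clip(ros_f, 0, None)

    truth = GroundTruth(spike_times=spike_times, responders=responders, seed=seed)
    truth.cell_centres_px = centres  # (row, col) per cell
    stack_kw = dict(pixel_size_nm=1000.0, frame_interval_ms=1000.0)
    return (ImageStack(ca, channel_label="calcium", **stack_kw),
            ImageStack(ros, channel_label="ros", **stack_kw), truth)


def gen_vesicle_frames(n_vesicles: int, influx_fracs,
                       f_background: float = 100.0, f_ionomycin: float = 1100.0,
                       noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Per-vesicle fluorescence triplets for the membrane-permeabilization assay.

    Constructed so that the influx formula inverts exactly at zero noise:
    ``F_sample = F_background + frac * (F_ionomycin - F_background)``.
    """
    influx_fracs = np.asarray(influx_fracs, dtype=float)
    if influx_fracs.size != n_vesicles:
        influx_fracs = np.resize(influx_fracs, n_vesicles)
    if np.any((influx_fracs < 0) | (influx_fracs > 1)):
        raise ValueError("influx fractions must be in [0, 1]")
    if f_ionomycin <= f_background:
        raise ValueError("F_ionomycin must exceed F_background")
    rng = np.random.default_rng(seed)
    f_sample = f_background + influx_fracs * (f_ionomycin - f_background)
    out = pd.DataFrame({
        "vesicle": np.arange(n_vesicles),
        "f_background": np.full(n_vesicles, f_background),
        "f_sample": f_sample,
        "f_ionomycin": np.full(n_vesicles, f_ionomycin),
    })
    if noise_sd > 0:
        for col in ("f_background", "f_sample", "f_ionomycin"):
            out[col] += rng.normal(0.0, noise_sd, n_vesicles)
    return out
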