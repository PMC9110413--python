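"""Declarative analysis configuration with round-trippable YAML serialization.

Each stage of the pipeline has a named parameter group whose defaults are the
values used throughout the study this package operationalizes (DBSCAN radii,
quality cut-offs, MCMC schedule, ...).  A single global seed drives every
stochastic stage.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import yaml

logger = logging.getLogger("tauagg")

DEFAULTS: dict = {
    "seed": 0,
    "io": {
        "pixel_size_nm": 107.2,
        "frame_interval_ms": 20.0,
        "default_precision_nm": 20.0,
    },
    "dl": {
        "bandpass_low_px": 1.0,
        "bandpass_high_px": 20.0,
        "blur_sigma_px": 1.0,
        "threshold_frac": 0.02,
        "min_particle_px": 3,
        "length_bins_nm": [0.0, 500.0, 1000.0, float("inf")],
    },
    "smlm": {
        "min_signal_strength": 3.0,
        "max_precision_nm": 30.0,
        "fiducial_min_frames": 500,
        "fiducial_radius_nm": 15.0,
        "spatial_eps_nm": 15.0,
        "spatial_minpts": 3,
        "temporal_eps_ms": 21.0,
        "temporal_min_frames": 2,
        "cluster_eps_nm": 200.0,
        "cluster_min_bursts": 20,
        "superres_pixel_nm": 107.2,
        "scale_factor": 8,
        "closing_radius": 2,
        "frc_pixel_nm": 10.0,
    },
    "ms": {
        "base_mass_da": 39_900.0,
        "phosphate_da": 80.0,
        "adduct_da": 23.0,
        "max_phos": 50,
        "max_adduct": 50,
        "window_da": 10.0,
        "chains": 6,
        "steps": 3000,
        "burn_in": 800,
        "thin": 100,
        "denoise": True,
    },
    "cells": {
        "background_percentile": 5.0,
        "blur_sigma_px": 1.0,
        "cell_radius_px": 10.0,
        "trace_smooth_sigma": 2.0,
        "min_track_fraction": 0.25,
        "refractory_frames": 3,
        "min_spike_duration": 2,
        "ros_window": 50,
    },
}


@dataclass
class AnalysisConfig:
    """Nested parameter groups plus a global random seed."""

    params: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __getitem__(self, group: str) -> dict:
        return self.params[group]

    @property
    def seed(self) -> int:
        return int(self.params["seed"])

    def with_updates(self, updates: dict) -> "AnalysisConfig":
        """Return a new config with ``updates`` merged over the defaults."""
        merged = copy.deepcopy(self.params)
        for group, values in updates.items():
            if isinstance(values, dict):
                merged.setdefault(group, {}).update(values)
            else:
                merged[group] = values
        return AnalysisConfig(merged)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.params, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        cfg = cls().with_updates(loaded)
        logger.info("loaded config from %s", path)
        return cfg
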