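"""Configuration objects for simulation and pipeline runs.

All physical quantities are micrometres (µm) and seconds. Array axis order is
``(t, channel, y, x)`` for live movies and ``(channel, z, y, x)`` for fixed
volumes; position vectors follow the array order, i.e. ``(y, x)`` or
``(z, y, x)``. Voxel centres sit at integer indices.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import yaml


class ParameterError(ValueError):
    """A configuration value is outside its valid domain."""


def tether_sd_for_contact_fraction(threshold_um: float, fraction: float) -> float:
    """Per-axis stationary SD of an isotropic 2D tether such that the
    stationary probability of centre distance ≤ ``threshold_um`` equals
    ``fraction`` (Rayleigh radial law: P(R ≤ r) = 1 − exp(−r²/2σ²))."""
    if not 0 < fraction < 1:
        raise ParameterError("fraction must be in (0, 1)")
    if threshold_um <= 0:
        raise ParameterError("threshold_um must be > 0")
    return threshold_um / math.sqrt(-2.0 * math.log1p(-fraction))


@dataclass
class LiveSimConfig:
    """Parameters of a synthetic two-channel live-cell movie.

    A stationary RNA transcriptional burst sits at ``tether_center_um`` and a
    mobile protein condensate performs mean-reverting (Ornstein-Uhlenbeck)
    motion tethered to it, making transient sub-``contact_threshold_um``
    contacts during which intensity flows from the RNA to the protein channel.
    """

    n_frames: int = 300
    frame_interval_s: float = 1.04
    pixel_size_um: float = 0.1
    field_shape: tuple[int, int] = (64, 64)  # (Y, X) pixels
    tether_center_um: tuple[float, float] = (3.2, 3.2)  # (y, x)
    tether_relaxation_s: float = 5.0
    tether_sd_um: float = 0.2964  # per-axis; ~30% of frames within 0.25 µm
    contact_threshold_um: float = 0.25
    burst_mean_intensity: float = 2000.0
    gag_mean_intensity: float = 1000.0
    exchange_rate: float = 0.02  # fraction of RNA intensity per contact frame
    intensity_noise_sd: float = 0.0  # per-frame fluctuation, A.U.
    psf_sigma_um: float = 0.15
    noise_gaussian_sd: float = 0.0
    noise_poisson: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ParameterError("n_frames must be ≥ 2")
        for name in ("frame_interval_s", "pixel_size_um", "psf_sigma_um"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.tether_relaxation_s <= 0:
            raise ParameterError("tether_relaxation_s must be > 0")
        if self.tether_sd_um < 0:
            raise ParameterError("tether_sd_um must be ≥ 0")
        if not 0.0 <= self.exchange_rate <= 1.0:
            raise ParameterError("exchange_rate must lie in [0, 1]")
        if self.contact_threshold_um <= 0:
            raise ParameterError("contact_threshold_um must be > 0")


@dataclass
class FixedSimConfig:
    """Parameters of a synthetic fixed-cell 3D multi-channel z-stack.

    One ellipsoidal nucleus (nuclear-stain channel) containing RNA foci — the
    brightest of which is the transcriptional burst — and protein condensate
    foci placed at known analytic distances from the nuclear boundary.
    The 0.3 µm default z-step matches typical confocal z-stack acquisition.
    """

    volume_shape: tuple[int, int, int] = (40, 144, 144)  # (Z, Y, X) voxels
    voxel_size_um: tuple[float, float, float] = (0.3, 0.1, 0.1)  # (z, y, x)
    nucleus_semiaxes_um: tuple[float, float, float] = (4.2, 5.5, 5.5)
    nucleus_center_um: Optional[tuple[float, float, float]] = None  # default: volume centre
    n_bursts: int = 1
    burst_rim_distance_um: float | Sequence[float] = 0.31
    n_gag_foci: int = 20
    gag_rim_mean_um: float = 0.4  # mean of truncated-exponential rim distances
    gag_rim_max_um: float = 2.5
    gag_rim_distance_sampler: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None
    burst_intensity: float = 6000.0
    rna_other_intensity: float = 2000.0
    gag_mean_intensity: float = 2500.0
    nuclear_stain_intensity: float = 300.0
    focus_sigma_um: tuple[float, float, float] = (0.35, 0.12, 0.12)  # (z, y, x)
    noise_gaussian_sd: float = 0.0
    noise_poisson: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_size_um):
            raise ParameterError("voxel sizes must be > 0")
        if any(a <= 0 for a in self.nucleus_semiaxes_um):
            raise ParameterError("nucleus semi-axes must be > 0")
        if self.n_bursts < 0 or self.n_gag_foci < 0:
            raise ParameterError("focus counts must be ≥ 0")
        rims = np.atleast_1d(np.asarray(self.burst_rim_distance_um, dtype=float))
        if np.any(rims <= 0) or np.any(rims >= min(self.nucleus_semiaxes_um)):
            raise ParameterError(
                "burst rim distances must lie in (0, smallest nuclear semi-axis)"
            )

    @property
    def center_um(self) -> np.ndarray:
        if self.nucleus_center_um is not None:
            return np.asarray(self.nucleus_center_um, dtype=float)
        return (
            (np.asarray(self.volume_shape, dtype=float) - 1.0)
            * np.asarray(self.voxel_size_um, dtype=float)
            / 2.0
        )


@dataclass
class PipelineConfig:
    """End-to-end analysis parameters shared by the live and fixed pipelines."""

    pixel_size_um: float = 0.1
    voxel_size_um: tuple[float, float, float] = (0.3, 0.1, 0.1)
    frame_interval_s: float = 1.04
    channels: dict = field(
        default_factory=lambda: {"rna": 0, "gag": 1, "nuclear": 2, "eu": 3}
    )
    detect_scale_um: float = 0.15  # expected focus radius for LoG detection
    detect_threshold: Optional[float] = None  # None → noise-adaptive
    detect_k_sigma: float = 6.0
    min_spot_px: int = 2
    min_spot_vox: int = 4
    max_disp_um: float = 0.5  # per-frame linking gate
    max_gap: int = 2
    kissing_threshold_um: float = 0.25
    rim_cutoff_um: float = 1.0
    coloc_radius_um: float = 0.25
    nucleus_smooth_um: float = 0.3
    nucleus_min_volume_um3: float = 5.0
    outlier_k: float = 3.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ParameterError("spacing and frame interval must be > 0")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ParameterError("voxel sizes must be > 0")
        if self.kissing_threshold_um <= 0 or self.rim_cutoff_um <= 0:
            raise ParameterError("thresholds must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if "voxel_size_um" in known:
            cfg.voxel_size_um = tuple(known["voxel_size_um"])
        return cfg

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
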