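"""Synthetic contrast-weighted images computed from quantitative maps.

Given R1, R2 and PD maps, any spin-echo contrast can be synthesized by
evaluating the signal equation at a chosen TE/TR (and optionally TI). The
default use is a T2-weighted image (TE = 100 ms, TR = 4500 ms) that serves as
the registration source and display background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .relaxometry import MS_PER_S, QuantMaps

__all__ = ["ContrastSettings", "synthesize", "smooth"]


@dataclass(frozen=True)
class ContrastSettings:
    """Virtual scanner settings for contrast synthesis (times in ms)."""

    echo_time_ms: float = 100.0
    repetition_time_ms: float = 4500.0
    inversion_time_ms: float | None = None

    def __post_init__(self) -> None:
        if self.echo_time_ms < 0:
            raise ValueError("echo time must be non-negative")
        if self.repetition_time_ms <= self.echo_time_ms:
            raise ValueError("repetition time must exceed the echo time")
        if self.inversion_time_ms is not None and not (
            0 < self.inversion_time_ms < self.repetition_time_ms
        ):
            raise ValueError("inversion time must lie inside the repetition time")


def synthesize(maps: QuantMaps, settings: ContrastSettings = ContrastSettings()) -> np.ndarray:
    """Evaluate the spin-echo signal equation voxelwise.

    Without an inversion time:  S = PD * (1 - exp(-TR*R1)) * exp(-TE*R2).
    With one (inversion recovery): the recovery factor becomes
    |1 - 2*exp(-TI*R1) + exp(-TR*R1)|.

    Invalid voxels map to 0; the output shares the maps' grid and is >= 0.
    """
    te = settings.echo_time_ms / MS_PER_S
    tr = settings.repetition_time_ms / MS_PER_S
    with np.errstate(invalid="ignore"):
        if settings.inversion_time_ms is None:
            recovery = 1.0 - np.exp(-tr * maps.r1)
        else:
            ti = settings.inversion_time_ms / MS_PER_S
            recovery = np.abs(1.0 - 2.0 * np.exp(-ti * maps.r1) + np.exp(-tr * maps.r1))
        signal = maps.pd * recovery * np.exp(-te * maps.r2)
    signal = np.where(maps.valid & np.isfinite(signal), signal, 0.0)
    return np.clip(signal, 0.0, None)


def smooth(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_sizes_mm,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian smoothing with the kernel width given in millimetres.

    The FWHM is converted to a per-axis sigma in voxels, so anisotropic grids
    are honored. Boundaries use edge replication to avoid artificial darkening
    at the brain edge. If ``valid`` is given, invalid voxels are excluded via
    normalized masked convolution (no NaN bleed); voxels with no valid support
    come back as NaN. ``fwhm_mm = 0`` returns an identical copy.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    volume = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return volume.copy()
    sigmas = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / np.asarray(voxel_sizes_mm, dtype=float)

    if valid is None:
        return ndimage.gaussian_filter(volume, sigma=sigmas, mode="nearest")

    w = np.asarray(valid, dtype=float)
    num = ndimage.gaussian_filter(np.where(valid, volume, 0.0), sigma=sigmas, mode="nearest")
    den = ndimage.gaussian_filter(w, sigma=sigmas, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 1e-6, num / den, np.nan)
    return out
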