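"""Single-subject deviation mapping against a normative reference atlas.

Per parameter, the normalized difference (z) map is

    z_p = (subject_p - mean_p) / sd_p

with the sign convention that positive means the subject lies above the
reference mean. Voxelwise significance uses the two-sided critical value of
Student's t with (group size - 1) degrees of freedom — 2.04 for a reference
group of 31 at alpha = 0.05, approaching the Gaussian 1.96 for large groups.

The three z maps are combined into the vector-sum magnitude

    S = sqrt(z_R1^2 + z_R2^2 + z_PD^2)

which is thresholded (default S > 5) to display only extreme combined
deviations. Under an independent-Gaussian null, S follows a chi distribution
with 3 degrees of freedom; both the single-component Gaussian tail and the
3-df chi tail are available for calibrating that threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats

from .reference_atlas import PARAMETERS, ReferenceAtlas
from .relaxometry import QuantMaps

__all__ = [
    "DeviationResult",
    "z_maps",
    "significance_threshold",
    "vector_sum",
    "combined_mask",
    "expected_false_positives",
    "vector_sum_tail",
    "deviate",
]


def significance_threshold(n_ref: float, alpha: float = 0.05) -> float:
    """Two-sided critical value for a subject-vs-reference-group z map.

    For a reference group of ``n_ref`` subjects the null is Student's t with
    n_ref - 1 degrees of freedom; ``n_ref = inf`` gives the Gaussian limit.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_ref is None or math.isinf(n_ref):
        return float(stats.norm.ppf(1.0 - alpha / 2.0))
    if n_ref < 2:
        raise ValueError(f"reference group must have at least 2 subjects, got {n_ref}")
    return float(stats.t.ppf(1.0 - alpha / 2.0, df=n_ref - 1))


def z_maps(subject: QuantMaps, atlas: ReferenceAtlas) -> dict[str, np.ndarray]:
    """Per-parameter normalized difference maps (subject - mean)/sd.

    Defined where the subject voxel is valid, the atlas covers the voxel with
    at least 2 subjects and sd > 0; NaN elsewhere. Where the cohort shows no
    variation *and* the subject does not deviate, z is 0 by continuity.
    """
    if subject.shape != atlas.shape or not np.allclose(subject.affine, atlas.affine, atol=1e-6):
        raise ValueError("subject maps are not on the atlas grid")
    out = {}
    covered = atlas.coverage >= 2
    for p in PARAMETERS:
        delta = np.where(subject.valid, subject.parameter(p), np.nan) - atlas.mean[p]
        sd = atlas.sd[p]
        # a floor at the float rounding scale of the mean: a cohort whose
        # spread is pure summation dust counts as zero-variation
        floor = 1e-9 * np.maximum(np.abs(atlas.mean[p]), 1e-30)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(covered & (sd > floor), delta / sd, np.nan)
        exact = covered & ~(sd > floor) & (np.abs(delta) <= floor)
        z[exact] = 0.0
        out[p] = z
    return out


def vector_sum(z_r1: np.ndarray, z_r2: np.ndarray, z_pd: np.ndarray) -> np.ndarray:
    """Combined deviation magnitude S = sqrt(z_R1^2 + z_R2^2 + z_PD^2).

    NaN in any component propagates to S.
    """
    return np.sqrt(z_r1 ** 2 + z_r2 ** 2 + z_pd ** 2)


def combined_mask(s: np.ndarray, threshold: float = 5.0) -> np.ndarray:
    """Binary mask of voxels whose combined deviation exceeds the threshold
    (strict inequality; NaN never passes)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    with np.errstate(invalid="ignore"):
        return np.asarray(s) > threshold


def vector_sum_tail(threshold: float, df: int = 3) -> float:
    """P(S > threshold) under independent standard-normal z components
    (chi distribution with ``df`` degrees of freedom)."""
    return float(stats.chi.sf(threshold, df))


def expected_false_positives(
    n_pixels: int,
    threshold: float | None = None,
    alpha: float | None = None,
    null: str = "gaussian",
    df: int | None = None,
) -> float:
    """Expected count of pixels exceeding a two-sided threshold by chance.

    Either give ``alpha`` directly (the expected count is then
    ``n_pixels * alpha`` regardless of null) or a ``threshold`` plus a null:
    ``"gaussian"`` or ``"t"`` (with ``df``). At a 5% level a 256x256 image is
    expected to show over 3000 spuriously significant pixels, while a
    threshold of 5 under a Gaussian null leaves fewer than 0.5.
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be at least 1")
    if (threshold is None) == (alpha is None):
        raise ValueError("give exactly one of threshold or alpha")
    if alpha is not None:
        if not (0.0 < alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {alpha}")
        return n_pixels * alpha
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if null == "gaussian":
        tail = 2.0 * stats.norm.sf(threshold)
    elif null == "t":
        if df is None or df < 1:
            raise ValueError("the t null requires df >= 1")
        tail = 2.0 * stats.t.sf(threshold, df)
    else:
        raise ValueError(f"unknown null {null!r}; use 'gaussian' or 't'")
    return float(n_pixels * tail)


@dataclass
class DeviationResult:
    """z maps, combined S map and significance masks for one subject."""

    z: dict[str, np.ndarray]
    s: np.ndarray
    masks: dict[str, np.ndarray]
    combined: np.ndarray
    alpha: float
    s_threshold: float
    n_ref: int
    affine: np.ndarray

    def summary(self) -> pd.DataFrame:
        """Counts of supra-threshold voxels per parameter and combined."""
        rows = [
            {"map": p, "threshold": significance_threshold(self.n_ref, self.alpha),
             "suprathreshold_voxels": int(self.masks[p].sum())}
            for p in PARAMETERS
        ]
        rows.append(
            {"map": "S", "threshold": self.s_threshold,
             "suprathreshold_voxels": int(self.combined.sum())}
        )
        return pd.DataFrame(rows)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for p in PARAMETERS:
            nib.save(nib.Nifti1Image(self.z[p].astype(np.float32), self.affine),
                     str(directory / f"z_{p}.nii.gz"))
            nib.save(nib.Nifti1Image(self.masks[p].astype(np.uint8), self.affine),
                     str(directory / f"mask_{p}.nii.gz"))
        nib.save(nib.Nifti1Image(self.s.astype(np.float32), self.affine),
                 str(directory / "S.nii.gz"))
        nib.save(nib.Nifti1Image(self.combined.astype(np.uint8), self.affine),
                 str(directory / "mask_S.nii.gz"))
        self.summary().to_csv(directory / "summary.tsv", sep="\t", index=False)


def deviate(
    subject: QuantMaps,
    atlas: ReferenceAtlas,
    alpha: float = 0.05,
    s_threshold: float = 5.0,
) -> DeviationResult:
    """Full deviation analysis of one normalized subject against an atlas.

    Per-parameter masks use the per-voxel t critical value with degrees of
    freedom = coverage - 1 (equal to n_ref - 1 wherever the atlas has full
    coverage), so edge voxels seen by fewer subjects get honestly wider
    thresholds. Thresholding is two-sided on |z|; signed z values and the
    unthresholded S map are retained in the result.
    """
    z = z_maps(subject, atlas)
    s = vector_sum(z["R1"], z["R2"], z["PD"])

    thr = np.full(atlas.shape, np.nan)
    for cov_n in np.unique(atlas.coverage):
        if cov_n >= 2:
            thr[atlas.coverage == cov_n] = significance_threshold(int(cov_n), alpha)
    masks = {}
    for p in PARAMETERS:
        with np.errstate(invalid="ignore"):
            masks[p] = np.abs(z[p]) > thr
    combined = combined_mask(s, s_threshold)
    return DeviationResult(
        z=z, s=s, masks=masks, combined=combined,
        alpha=alpha, s_threshold=s_threshold, n_ref=atlas.n, affine=atlas.affine.copy(),
    )
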