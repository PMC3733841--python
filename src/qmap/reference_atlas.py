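"""Voxelwise normative reference maps from a cohort of normalized subjects.

For each parameter (R1, R2, PD) the atlas holds the per-voxel sample mean,
sample standard deviation (n-1 denominator, matching the t-distributed
thresholds used downstream) and coefficient of variation CoV = sigma/mean,
plus the per-voxel count of contributing subjects ("coverage": voxels near
the brain edge are not covered by every subject after normalization).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .relaxometry import QuantMaps

__all__ = ["ReferenceAtlas", "build_reference", "cov_map"]

PARAMETERS = ("R1", "R2", "PD")


@dataclass
class ReferenceAtlas:
    """Voxelwise mean/SD/CoV maps for R1, R2 and PD plus group size."""

    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    cov: dict[str, np.ndarray]
    coverage: np.ndarray
    n: int
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        for p in PARAMETERS:
            if p not in self.mean or p not in self.sd or p not in self.cov:
                raise ValueError(f"atlas is missing parameter {p}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.coverage.shape

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for p in PARAMETERS:
            for kind, store in (("mean", self.mean), ("sd", self.sd), ("cov", self.cov)):
                nib.save(
                    nib.Nifti1Image(store[p].astype(np.float32), self.affine),
                    str(directory / f"{kind}_{p}.nii.gz"),
                )
        nib.save(
            nib.Nifti1Image(self.coverage.astype(np.int16), self.affine),
            str(directory / "coverage.nii.gz"),
        )
        (directory / "atlas.json").write_text(
            json.dumps({"n": self.n, "parameters": list(PARAMETERS), "shape": list(self.shape)}, indent=2)
        )

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceAtlas":
        directory = Path(directory)
        meta = json.loads((directory / "atlas.json").read_text())
        mean, sd, cov = {}, {}, {}
        affine = None
        for p in PARAMETERS:
            for kind, store in (("mean", mean), ("sd", sd), ("cov", cov)):
                img = nib.load(str(directory / f"{kind}_{p}.nii.gz"))
                store[p] = np.asarray(img.dataobj, dtype=float)
                affine = np.asarray(img.affine)
        coverage = np.asarray(nib.load(str(directory / "coverage.nii.gz")).dataobj).astype(int)
        return cls(mean=mean, sd=sd, cov=cov, coverage=coverage, n=int(meta["n"]), affine=affine)


def _cov_from(mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """CoV = sd/mean where the mean is meaningfully positive, NaN elsewhere.

    The guard threshold is 1% of the median in-brain mean, so background
    voxels never explode the map.
    """
    finite = mean[np.isfinite(mean) & (mean > 0)]
    eps = 0.01 * float(np.median(finite)) if finite.size else np.inf
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(np.isfinite(mean) & (mean > eps), sd / mean, np.nan)


def build_reference(subjects: list[QuantMaps]) -> ReferenceAtlas:
    """Aggregate normalized subjects into voxelwise mean/SD/CoV maps.

    All subjects must be on the identical template grid. The mean is computed
    over subjects whose validity mask covers the voxel; SD uses the n-1
    denominator and is defined where coverage >= 2.
    """
    if len(subjects) < 2:
        raise ValueError(f"at least 2 subjects are required, got {len(subjects)}")
    ref = subjects[0]
    for i, s in enumerate(subjects[1:], start=1):
        if not ref.same_grid(s):
            raise ValueError(f"subject {i} is not on the same grid as subject 0")

    coverage = np.zeros(ref.shape, dtype=int)
    mean, sd, cov = {}, {}, {}
    for p in PARAMETERS:
        stack = np.stack([np.where(s.valid, s.parameter(p), np.nan) for s in subjects])
        count = np.isfinite(stack).sum(axis=0)
        with np.errstate(invalid="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                m = np.nanmean(stack, axis=0)
                v = np.nanstd(stack, axis=0, ddof=1)
        m = np.where(count >= 1, m, np.nan)
        v = np.where(count >= 2, v, np.nan)
        mean[p], sd[p] = m, v
        cov[p] = _cov_from(m, v)
        coverage = np.maximum(coverage, count)
    return ReferenceAtlas(
        mean=mean, sd=sd, cov=cov, coverage=coverage, n=len(subjects), affine=ref.affine.copy()
    )


def cov_map(atlas: ReferenceAtlas, parameter: str) -> np.ndarray:
    """The coefficient-of-variation map for one parameter (data unclipped;
    any display windowing happens at render time only)."""
    if parameter not in PARAMETERS:
        raise KeyError(f"unknown parameter {parameter!r}; expected one of {PARAMETERS}")
    return atlas.cov[parameter]
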