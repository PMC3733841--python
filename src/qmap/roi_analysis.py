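"""Atlas-ROI summaries, age regression and brain/ventricle volume fractions.

Per-subject ROI means of the normalized R1/R2/PD maps are aggregated across a
cohort into a reference table (mean +/- across-subject SD per region) and
regressed on age by ordinary least squares. Rule-based tissue classification
on the calibrated maps yields the brain parenchymal fraction (BPF, brain
volume / intracranial volume) and — with a ventricle label — the lateral
ventricle fraction (LVF).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage

from .reference_atlas import PARAMETERS
from .relaxometry import QuantMaps

__all__ = [
    "LabelAtlas",
    "roi_means",
    "cohort_roi_table",
    "tissue_masks",
    "volume_fractions",
]


@dataclass
class LabelAtlas:
    """Integer label volume plus a code -> name table; 0 is background."""

    labels: np.ndarray
    table: dict[int, str]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        self.affine = np.asarray(self.affine, dtype=float)
        present = set(int(c) for c in np.unique(self.labels)) - {0}
        missing = present - set(self.table)
        if missing:
            raise ValueError(f"label codes {sorted(missing)} are not in the label table")

    @property
    def codes(self) -> list[int]:
        return sorted(set(int(c) for c in np.unique(self.labels)) - {0})

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    def save(self, nifti_path: str | Path, tsv_path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), self.affine), str(nifti_path))
        pd.DataFrame(
            sorted(self.table.items()), columns=["code", "name"]
        ).to_csv(tsv_path, sep="\t", index=False)

    @classmethod
    def load(cls, nifti_path: str | Path, tsv_path: str | Path) -> "LabelAtlas":
        img = nib.load(str(nifti_path))
        labels = np.asarray(img.dataobj).astype(np.int32)
        df = pd.read_csv(tsv_path, sep="\t")
        table = {int(r.code): str(r.name) for r in df.itertuples(index=False)}
        return cls(labels=labels, table=table, affine=np.asarray(img.affine))


def roi_means(maps: QuantMaps, atlas: LabelAtlas) -> pd.DataFrame:
    """Mean R1/R2/PD over the valid voxels of each ROI of one subject.

    Empty ROIs (present in the table but with no valid voxels) come back as a
    flagged row with NaN means, never a silently dropped one.
    """
    if maps.shape != atlas.labels.shape:
        raise ValueError("maps are not on the label atlas grid")
    rows = []
    for code in sorted(atlas.table):
        sel = (atlas.labels == code) & maps.valid
        row = {"code": code, "name": atlas.table[code], "n_voxels": int(sel.sum()),
               "empty": not sel.any()}
        for p in PARAMETERS:
            row[p] = float(np.nanmean(maps.parameter(p)[sel])) if sel.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_roi_table(
    cohort: pd.DataFrame,
    atlas: LabelAtlas,
    maps: list[QuantMaps] | None = None,
) -> pd.DataFrame:
    """Cohort ROI summary: across-subject mean, SD, and OLS age slope.

    ``cohort`` needs columns ``subject_id``, ``age_years`` and (unless
    ``maps`` is supplied in the same row order) ``maps_prefix`` pointing at
    saved map volumes. ROI means are computed per subject and then
    aggregated, so the SDs are between-subject SDs; the slope per year and
    its two-sided p-value come from ordinary least squares of the per-subject
    ROI means on age, flagged significant at p < 0.05.
    """
    required = {"subject_id", "age_years"}
    if not required <= set(cohort.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    if len(cohort) < 3:
        raise ValueError("at least 3 subjects are required for the age regression")
    ages = cohort["age_years"].to_numpy(dtype=float)
    if np.any(ages <= 0):
        raise ValueError("ages must be positive")
    if not cohort["subject_id"].is_unique:
        raise ValueError("subject ids must be unique")
    constant_ages = np.ptp(ages) == 0

    if maps is None:
        maps = [QuantMaps.load(p) for p in cohort["maps_prefix"]]
    if len(maps) != len(cohort):
        raise ValueError("one QuantMaps per cohort row is required")

    per_subject = [roi_means(m, atlas) for m in maps]
    rows = []
    for i, code in enumerate(sorted(atlas.table)):
        row = {"code": code, "name": atlas.table[code]}
        for p in PARAMETERS:
            vals = np.array([t[p].iloc[i] for t in per_subject])
            ok = np.isfinite(vals)
            row[f"{p}_mean"] = float(vals[ok].mean()) if ok.any() else np.nan
            row[f"{p}_sd"] = float(vals[ok].std(ddof=1)) if ok.sum() >= 2 else np.nan
            if constant_ages or ok.sum() < 3:
                row[f"{p}_slope"] = np.nan
                row[f"{p}_slope_p"] = np.nan
                row[f"{p}_slope_flagged"] = True
            else:
                fit = sm.OLS(vals[ok], sm.add_constant(ages[ok])).fit()
                row[f"{p}_slope"] = float(fit.params[1])
                row[f"{p}_slope_p"] = float(fit.pvalues[1])
                ci = fit.conf_int(alpha=0.05)
                row[f"{p}_slope_ci_low"] = float(ci[1][0])
                row[f"{p}_slope_ci_high"] = float(ci[1][1])
                row[f"{p}_slope_flagged"] = False
            row[f"{p}_slope_significant"] = (
                bool(row.get(f"{p}_slope_p", np.nan) < 0.05)
                if np.isfinite(row.get(f"{p}_slope_p", np.nan))
                else False
            )
        rows.append(row)
    return pd.DataFrame(rows)


def tissue_masks(
    maps: QuantMaps,
    pd_csf_threshold: float = 85.0,
    r1_csf_threshold: float = 0.6,
    foreground_pd_threshold: float = 30.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rule-based (parenchyma, CSF, intracranial) masks from calibrated maps.

    The intracranial mask is the largest connected foreground component
    (PD above ``foreground_pd_threshold``) after morphological closing; CSF is
    the intracranial voxels with PD above ``pd_csf_threshold`` (%) and R1
    below ``r1_csf_threshold`` (s^-1); parenchyma is the remainder. Boundary
    voxels are assigned deterministically by the same thresholds.
    """
    fg = maps.valid & (np.nan_to_num(maps.pd, nan=0.0) > foreground_pd_threshold)
    fg = ndimage.binary_closing(fg, structure=ndimage.generate_binary_structure(3, 2), iterations=2)
    labeled, n_comp = ndimage.label(fg)
    if n_comp == 0:
        raise ValueError("empty intracranial mask: no foreground voxels found")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n_comp + 1))
    intracranial = labeled == (1 + int(np.argmax(sizes)))

    with np.errstate(invalid="ignore"):
        csf = (
            intracranial
            & maps.valid
            & (maps.pd > pd_csf_threshold)
            & (maps.r1 < r1_csf_threshold)
        )
    parenchyma = intracranial & ~csf
    return parenchyma, csf, intracranial


def volume_fractions(
    parenchyma: np.ndarray,
    lateral_ventricles: np.ndarray,
    intracranial: np.ndarray,
) -> tuple[float, float]:
    """Brain parenchymal fraction and lateral ventricle fraction, in percent.

    BPF = 100 * |parenchyma| / |intracranial|; LVF likewise for the ventricle
    mask. All masks share one grid so the voxel volume cancels.
    """
    icv = int(np.asarray(intracranial, dtype=bool).sum())
    if icv == 0:
        raise ValueError("empty intracranial mask")
    bpf = 100.0 * int(np.asarray(parenchyma, dtype=bool).sum()) / icv
    lvf = 100.0 * int(np.asarray(lateral_ventricles, dtype=bool).sum()) / icv
    return bpf, lvf
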