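"""Stage orchestration: run one subject or a whole reference cohort.

The per-subject chain is fit -> (optional PD calibration) -> synthesize ->
normalize -> (optional deviation against an atlas); the cohort chain runs the
subject chain for every row of a cohort table and aggregates the normalized
maps into a reference atlas. Every output directory carries a provenance
record (package version, effective configuration, config hash, seed) from
which the run can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .deviation import deviate
from .reference_atlas import ReferenceAtlas, build_reference
from .registration import TemplateSpace, normalize_subject
from .relaxometry import AcquisitionProtocol, AcquisitionSeries, QuantMaps, calibrate_pd, fit_volume
from .synthesis import ContrastSettings

log = logging.getLogger("qmap")

__all__ = ["RunConfig", "run_subject", "run_reference", "load_template"]


@dataclass
class RunConfig:
    """Fixed constants of the pipeline plus file locations.

    Defaults are the standard operating point: 8 mm smoothing of the
    registration source, TE = 100 ms / TR = 4500 ms for the synthetic
    T2-weighted image, a 2 mm isotropic target grid (the template's own
    grid), alpha = 0.05 and a combined-map display threshold of 5.
    """

    template_path: str | None = None
    protocol_path: str | None = None
    atlas_dir: str | None = None
    water_mask_path: str | None = None
    alpha: float = 0.05
    s_threshold: float = 5.0
    smoothing_fwhm_mm: float = 8.0
    synth_te_ms: float = 100.0
    synth_tr_ms: float = 4500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.s_threshold <= 0:
            raise ValueError("s_threshold must be positive")
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing fwhm must be non-negative")

    def validate_paths(self, require: tuple[str, ...]) -> None:
        for name in require:
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"config path {name} = {p!r} does not exist")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_provenance(directory: Path, config: RunConfig, stage: str, extra: dict | None = None) -> None:
    record = {
        "tool": "qmap",
        "version": __version__,
        "stage": stage,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    if extra:
        record.update(extra)
    (directory / "provenance.json").write_text(json.dumps(record, indent=2))


def load_template(path: str | Path) -> TemplateSpace:
    import nibabel as nib

    img = nib.load(str(path))
    return TemplateSpace(data=np.asarray(img.dataobj, dtype=float), affine=np.asarray(img.affine))


def run_subject(
    series_path: str | Path,
    config: RunConfig,
    out_dir: str | Path,
    subject_id: str = "subject",
) -> Path:
    """Run the full single-subject chain, writing all stage outputs.

    Stages: fit the acquisition series, optionally calibrate PD against a
    water reference mask, synthesize the T2-weighted source, normalize to the
    template, and — if a reference atlas directory is configured — compute
    the deviation maps. Any stage failure raises with the stage name and
    subject id.
    """
    config.validate_paths(("template_path",))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    template = load_template(config.template_path)

    stage = "fit"
    try:
        series = AcquisitionSeries.load(series_path, config.protocol_path)
        log.info("[%s] fit: %d voxels, %d images per slice", subject_id,
                 int(np.prod(series.shape)), series.images_per_slice)
        maps = fit_volume(series)
        maps.save(out_dir / f"{subject_id}")

        if config.water_mask_path:
            stage = "calibrate"
            import nibabel as nib

            wmask = np.asarray(nib.load(config.water_mask_path).dataobj) > 0.5
            maps = calibrate_pd(maps, wmask)

        stage = "normalize"
        contrast = ContrastSettings(config.synth_te_ms, config.synth_tr_ms)
        normalized, transform = normalize_subject(
            maps, template, contrast=contrast, smoothing_fwhm_mm=config.smoothing_fwhm_mm
        )
        normalized.save(out_dir / f"{subject_id}_mni")
        transform.to_json(out_dir / f"{subject_id}_transform.json")

        if config.atlas_dir:
            stage = "deviate"
            atlas = ReferenceAtlas.load(config.atlas_dir)
            result = deviate(normalized, atlas, alpha=config.alpha, s_threshold=config.s_threshold)
            result.save(out_dir / "deviation")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed for subject {subject_id}: {exc}") from exc

    _write_provenance(out_dir, config, "run-subject", {"subject_id": subject_id})
    return out_dir


def run_reference(
    cohort_path: str | Path,
    config: RunConfig,
    out_dir: str | Path,
    series_column: str = "series_path",
) -> Path:
    """Build a reference atlas from a cohort of acquisition series.

    The cohort CSV needs ``subject_id`` and a series path column; each subject
    runs through fit + normalize, then the normalized maps are aggregated.
    Grid mismatches are impossible by construction (all subjects land on the
    template grid); cohorts of fewer than 2 subjects are rejected.
    """
    config.validate_paths(("template_path",))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(cohort_path)
    if len(cohort) < 2:
        raise ValueError(f"reference cohort needs at least 2 subjects, got {len(cohort)}")
    template = load_template(config.template_path)
    contrast = ContrastSettings(config.synth_te_ms, config.synth_tr_ms)

    normalized = []
    for row in cohort.itertuples(index=False):
        sid = str(row.subject_id)
        try:
            series = AcquisitionSeries.load(getattr(row, series_column), config.protocol_path)
            maps = fit_volume(series)
            norm, _ = normalize_subject(
                maps, template, contrast=contrast, smoothing_fwhm_mm=config.smoothing_fwhm_mm
            )
        except Exception as exc:
            raise RuntimeError(f"reference build failed for subject {sid}: {exc}") from exc
        log.info("[%s] normalized (%.0f%% coverage)", sid, 100.0 * norm.valid.mean())
        normalized.append(norm)

    atlas = build_reference(normalized)
    atlas.save(out_dir)
    _write_provenance(out_dir, config, "run-reference", {"n_subjects": atlas.n})
    return out_dir
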