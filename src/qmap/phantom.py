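"""Digital brain phantom: parametric anatomy, ground-truth maps, simulated
acquisitions and whole cohorts.

The anatomy is parametric-geometric — nested ellipsoids plus a sinusoidally
folded cortical ribbon — rather than a resampled real atlas, so every volume
has an analytic oracle and nothing is redistributed. Tissue classes carry
literature-typical (R1, R2, PD) values for healthy brain at 1.5 T together
with between-subject standard deviations; per subject, class values are drawn
from those Gaussians, optional age slopes are injected, and the anatomy is
warped by a random small affine ("jitter") emulating head size/shape
variability. Acquisitions are simulated from the ground-truth maps through
the saturation-recovery signal model with Gaussian or Rician noise.

All randomness flows from explicit seeds; there is no hidden global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .registration import AffineTransform, TemplateSpace
from .relaxometry import AcquisitionProtocol, AcquisitionSeries, QuantMaps, model_signal
from .roi_analysis import LabelAtlas
from .synthesis import ContrastSettings, synthesize

__all__ = [
    "TissueClass",
    "PhantomSpec",
    "CohortSpec",
    "DEFAULT_TISSUES",
    "make_phantom",
    "simulate_acquisition",
    "make_cohort",
    "default_template",
    "random_jitter",
]


@dataclass(frozen=True)
class TissueClass:
    """One tissue class: mean (R1, R2, PD) and between-subject SDs.

    R1/R2 in s^-1, PD in percent of pure water at 37 C.
    """

    name: str
    code: int
    r1: float
    r2: float
    pd: float
    sd_r1: float = 0.0
    sd_r2: float = 0.0
    sd_pd: float = 0.0


# Healthy-brain values at 1.5 T (means and between-subject SDs). The CSF
# values reflect ventricular ROIs in vivo, whose spread is dominated by
# partial-volume contamination, hence the large SDs.
DEFAULT_TISSUES: tuple[TissueClass, ...] = (
    TissueClass("csf", 1, 0.38, 3.89, 94.3, 0.32, 2.35, 8.8),
    TissueClass("cortical_gm", 2, 1.04, 9.87, 75.1, 0.09, 0.44, 2.4),
    TissueClass("white_matter", 3, 1.38, 11.79, 70.0, 0.05, 0.26, 1.0),
    TissueClass("lateral_ventricles", 4, 0.38, 3.89, 94.3, 0.32, 2.35, 8.8),
    TissueClass("caudate", 5, 1.00, 10.61, 80.3, 0.15, 1.51, 2.8),
    TissueClass("putamen", 6, 1.25, 13.07, 75.2, 0.05, 0.42, 1.6),
    TissueClass("thalamus", 7, 1.33, 12.81, 72.5, 0.07, 0.21, 1.9),
    # MS-like lesion: R1/R2 below and PD above white matter
    TissueClass("lesion", 8, 0.95, 9.0, 82.0, 0.05, 0.30, 1.0),
)

# physiological floors applied to drawn values (free water bounds the rates)
_MIN_R1, _MIN_R2, _MIN_PD = 0.05, 0.3, 5.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue content of the phantom head.

    The head is an ellipsoid of ``head_radii_mm``; the brain surface sits at
    the normalized radius that leaves ``1 - target_bpf`` of the intracranial
    volume as outer CSF, decorated with a sinusoidal folding of the cortical
    ribbon. Two ventricle ellipsoids are sized analytically to occupy
    ``ventricle_fraction`` of the intracranial volume. Overlapping primitives
    are resolved by a fixed priority: lesions > ventricles > deep grey nuclei
    > cortical ribbon > white matter > CSF shell.
    """

    shape: tuple[int, int, int] = (64, 80, 64)
    voxel_size_mm: float = 2.0
    head_radii_mm: tuple[float, float, float] = (52.0, 66.0, 46.0)
    cortical_thickness_mm: float = 4.0
    fold_amplitude: float = 0.03
    fold_frequency: int = 6
    target_bpf: float = 0.90
    ventricle_fraction: float = 0.011
    lesion_count: int = 0
    lesion_radius_mm: tuple[float, float] = (3.0, 6.0)
    tissues: tuple[TissueClass, ...] = DEFAULT_TISSUES

    def tissue(self, name: str) -> TissueClass:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(f"no tissue class named {name!r}")

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-world (mm, RAS), grid centered on the world origin."""
        a = np.eye(4)
        a[:3, :3] = np.eye(3) * self.voxel_size_mm
        a[:3, 3] = -0.5 * (np.asarray(self.shape) - 1) * self.voxel_size_mm
        return a

    def to_json(self, path: str | Path) -> None:
        payload = {
            "shape": list(self.shape),
            "voxel_size_mm": self.voxel_size_mm,
            "head_radii_mm": list(self.head_radii_mm),
            "cortical_thickness_mm": self.cortical_thickness_mm,
            "fold_amplitude": self.fold_amplitude,
            "fold_frequency": self.fold_frequency,
            "target_bpf": self.target_bpf,
            "ventricle_fraction": self.ventricle_fraction,
            "lesion_count": self.lesion_count,
            "lesion_radius_mm": list(self.lesion_radius_mm),
            "tissues": [vars(t) for t in self.tissues],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        payload = json.loads(Path(path).read_text())
        tissues = tuple(TissueClass(**t) for t in payload.pop("tissues"))
        payload["shape"] = tuple(payload["shape"])
        payload["head_radii_mm"] = tuple(payload["head_radii_mm"])
        payload["lesion_radius_mm"] = tuple(payload["lesion_radius_mm"])
        return cls(tissues=tissues, **payload)


@dataclass(frozen=True)
class CohortSpec:
    """A simulated study population.

    ``age_slopes`` injects a linear age dependence into named tissue classes
    as (dR1/year, dR2/year, dPD/year), centered on the cohort mean age.
    ``jitter_*`` set the SDs of the per-subject anatomical affine; zero
    disables anatomical variability. ``noise_sigma`` is the acquisition noise
    SD in M0 units (PD percent; 1.4 is ~2% of white-matter signal, SNR ~50).
    """

    n_subjects: int = 31
    age_range: tuple[float, float] = (26.0, 67.0)
    jitter_rotation_deg: float = 2.0
    jitter_translation_mm: float = 3.0
    jitter_log_zoom: float = 0.03
    jitter_shear: float = 0.01
    noise_sigma: float = 1.4
    noise_model: str = "gaussian"
    tissue_variation: bool = True
    age_slopes: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")


def _ellipsoid_rho(world: np.ndarray, center, radii) -> np.ndarray:
    """Normalized radial coordinate: <1 inside the ellipsoid."""
    c = np.asarray(center, dtype=float).reshape(3, 1)
    r = np.asarray(radii, dtype=float).reshape(3, 1)
    u = (world.reshape(3, -1) - c) / r
    return np.sqrt((u ** 2).sum(axis=0))


def _build_labels(spec: PhantomSpec, world: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Label volume on the (possibly jittered) world coordinates.

    Returns (labels, lesion_mask). Assignment order implements the priority
    ordering documented on :class:`PhantomSpec`.
    """
    shape = world.shape[1:]
    head_r = np.asarray(spec.head_radii_mm)
    flat = world.reshape(3, -1)

    rho = _ellipsoid_rho(world, (0.0, 0.0, 0.0), head_r)
    # brain surface: outer CSF shell holds 1 - BPF - LVF of intracranial volume
    csf_shell_frac = max(1.0 - spec.target_bpf - spec.ventricle_fraction, 0.0)
    rho_brain = (1.0 - csf_shell_frac) ** (1.0 / 3.0)
    mean_r = float(np.exp(np.log(head_r).mean()))
    rho_wm = rho_brain - spec.cortical_thickness_mm / mean_r

    # sinusoidal cortical folding riding on both surfaces
    u = flat / head_r[:, None]
    theta = np.arctan2(u[1], u[0])
    phi = np.arctan2(np.sqrt(u[0] ** 2 + u[1] ** 2), u[2])
    fold = spec.fold_amplitude * np.sin(spec.fold_frequency * theta) * np.cos(
        spec.fold_frequency * phi
    )

    labels = np.zeros(flat.shape[1], dtype=np.int16)
    inside_head = rho < 1.0
    labels[inside_head] = spec.tissue("csf").code
    gm = rho < (rho_brain + fold)
    labels[gm] = spec.tissue("cortical_gm").code
    wm = rho < (rho_wm + fold)
    labels[wm] = spec.tissue("white_matter").code

    # deep grey nuclei (bilateral ellipsoids, mm)
    deep = {
        "caudate": (((14.0, 14.0, 8.0), (5.0, 10.0, 5.0)), ((-14.0, 14.0, 8.0), (5.0, 10.0, 5.0))),
        "putamen": (((24.0, 2.0, 0.0), (6.0, 10.0, 6.0)), ((-24.0, 2.0, 0.0), (6.0, 10.0, 6.0))),
        "thalamus": (((10.0, -12.0, 2.0), (7.0, 10.0, 7.0)), ((-10.0, -12.0, 2.0), (7.0, 10.0, 7.0))),
    }
    for name, sides in deep.items():
        code = spec.tissue(name).code
        for center, radii in sides:
            labels[(_ellipsoid_rho(world, center, radii) < 1.0) & wm] = code

    # lateral ventricles: two ellipsoids sized to the requested fraction
    if spec.ventricle_fraction > 0:
        icv_mm3 = 4.0 / 3.0 * np.pi * np.prod(head_r)
        vent_each = spec.ventricle_fraction * icv_mm3 / 2.0
        a = (vent_each / (4.0 / 3.0 * np.pi * 2.5)) ** (1.0 / 3.0)
        vent_radii = (a, 2.5 * a, a)
        vent_code = spec.tissue("lateral_ventricles").code
        for cx in (9.0, -9.0):
            vent = _ellipsoid_rho(world, (cx, 6.0, 6.0), vent_radii) < 1.0
            labels[vent & inside_head] = vent_code

    # lesions: spheres placed in deep white matter, away from the ventricles
    lesion_mask = np.zeros(flat.shape[1], dtype=bool)
    if spec.lesion_count > 0:
        lesion_code = spec.tissue("lesion").code
        wm_code = spec.tissue("white_matter").code
        candidates = np.where((labels == wm_code) & (rho < 0.7))[0]
        placed = 0
        guard = 0
        while placed < spec.lesion_count and guard < 1000:
            guard += 1
            center = flat[:, rng.choice(candidates)]
            radius = rng.uniform(*spec.lesion_radius_mm)
            sphere = _ellipsoid_rho(world, center, (radius,) * 3) < 1.0
            if (labels[sphere] == wm_code).all() and not lesion_mask[sphere].any():
                labels[sphere] = lesion_code
                lesion_mask |= sphere
                placed += 1
        if placed < spec.lesion_count:
            raise RuntimeError(
                f"could not place {spec.lesion_count} non-overlapping lesions "
                f"in white matter (placed {placed})"
            )
    return labels.reshape(shape), lesion_mask.reshape(shape)


def _draw_values(
    spec: PhantomSpec,
    rng: np.random.Generator,
    vary: bool,
    shifts: dict[str, tuple[float, float, float]] | None,
) -> dict[int, tuple[float, float, float]]:
    """Per-class (R1, R2, PD) for one subject, clipped to physiological floors.

    Classes are drawn in the fixed order of ``spec.tissues`` so the stream of
    random numbers — hence the phantom — is reproducible for a given seed.
    """
    values = {}
    for t in spec.tissues:
        dr1 = dr2 = dpd = 0.0
        if shifts and t.name in shifts:
            dr1, dr2, dpd = shifts[t.name]
        if vary:
            r1 = rng.normal(t.r1 + dr1, t.sd_r1)
            r2 = rng.normal(t.r2 + dr2, t.sd_r2)
            pdv = rng.normal(t.pd + dpd, t.sd_pd)
        else:
            r1, r2, pdv = t.r1 + dr1, t.r2 + dr2, t.pd + dpd
        values[t.code] = (max(r1, _MIN_R1), max(r2, _MIN_R2), max(pdv, _MIN_PD))
    return values


def make_phantom(
    spec: PhantomSpec,
    seed: int | np.random.Generator = 0,
    jitter: AffineTransform | None = None,
    value_shifts: dict[str, tuple[float, float, float]] | None = None,
    tissue_variation: bool = True,
) -> tuple[LabelAtlas, QuantMaps]:
    """Build one phantom subject: label volume plus ground-truth maps.

    ``jitter`` warps the anatomy: the subject's volume at world point x shows
    the canonical anatomy at jitter(x), so spatial normalization of a subject
    generated with jitter A should recover the transform A^-1 (resampling the
    subject through A^-1 restores the canonical anatomy). ``value_shifts`` adds
    per-class mean offsets (used for age-slope injection). Deterministic for
    a given seed. The label volume doubles as the ROI atlas.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    affine = spec.affine
    idx = np.indices(spec.shape, dtype=float).reshape(3, -1)
    world = (affine[:3, :3] @ idx + affine[:3, 3:4])
    if jitter is not None:
        m = jitter.matrix
        world = m[:3, :3] @ world + m[:3, 3:4]
    world = world.reshape((3,) + spec.shape)

    labels, _ = _build_labels(spec, world, rng)
    values = _draw_values(spec, rng, tissue_variation, value_shifts)

    r1 = np.zeros(spec.shape)
    r2 = np.zeros(spec.shape)
    pdv = np.zeros(spec.shape)
    for code, (v1, v2, v3) in values.items():
        sel = labels == code
        r1[sel], r2[sel], pdv[sel] = v1, v2, v3
    valid = labels > 0
    r1[~valid] = np.nan
    r2[~valid] = np.nan
    pdv[~valid] = np.nan

    table = {t.code: t.name for t in spec.tissues}
    atlas = LabelAtlas(labels=labels.astype(np.int16), table=table, affine=affine)
    maps = QuantMaps(r1=r1, r2=r2, pd=pdv, valid=valid, affine=affine, pd_calibrated=True)
    return atlas, maps


def simulate_acquisition(
    true_maps: QuantMaps,
    protocol: AcquisitionProtocol = AcquisitionProtocol(),
    noise_sigma: float = 0.0,
    noise_model: str = "gaussian",
    seed: int | np.random.Generator = 0,
) -> AcquisitionSeries:
    """Simulate the multi-delay multi-echo series from ground-truth maps.

    Each (delay, echo) image is the forward signal model evaluated voxelwise;
    the default protocol produces 4 x 5 = 20 images per slice. Noise is
    additive Gaussian or Rician (magnitude of a complex signal with Gaussian
    noise in both channels) with SD ``noise_sigma`` in M0 units. Voxels
    outside the head contribute zero signal (plus noise).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    if noise_model not in ("gaussian", "rician"):
        raise ValueError(f"unknown noise model {noise_model!r}; use 'gaussian' or 'rician'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    r1 = np.nan_to_num(true_maps.r1, nan=0.0)
    r2 = np.nan_to_num(true_maps.r2, nan=0.0)
    m0 = np.nan_to_num(true_maps.pd, nan=0.0)
    nd, ne = protocol.n_delays, protocol.n_echoes
    data = np.empty((nd, ne) + true_maps.shape)
    for i, td in enumerate(protocol.saturation_delays_ms):
        for j, te in enumerate(protocol.echo_times_ms):
            data[i, j] = model_signal(r1, r2, m0, td, te)
    if noise_sigma > 0:
        if noise_model == "gaussian":
            data = data + rng.normal(0.0, noise_sigma, size=data.shape)
        else:
            re = data + rng.normal(0.0, noise_sigma, size=data.shape)
            im = rng.normal(0.0, noise_sigma, size=data.shape)
            data = np.sqrt(re ** 2 + im ** 2)
    # float32 halves the cohort memory footprint and matches scanner
    # magnitude-image precision
    return AcquisitionSeries(data=data.astype(np.float32), protocol=protocol, affine=true_maps.affine)


def random_jitter(cohort: CohortSpec, rng: np.random.Generator) -> AffineTransform:
    """Draw one subject's anatomical affine from the cohort jitter model."""
    rot = np.deg2rad(rng.normal(0.0, cohort.jitter_rotation_deg, 3))
    trans = rng.normal(0.0, cohort.jitter_translation_mm, 3)
    zoom = np.exp(rng.normal(0.0, cohort.jitter_log_zoom, 3))
    shear = rng.normal(0.0, cohort.jitter_shear, 3)
    return AffineTransform(
        translation=tuple(trans), rotation=tuple(rot), zoom=tuple(zoom), shear=tuple(shear)
    )


@dataclass
class PhantomSubject:
    """Ground truth and (optionally) simulated data for one cohort member."""

    subject_id: str
    age_years: float
    sex: str
    true_maps: QuantMaps
    labels: LabelAtlas
    jitter: AffineTransform
    series: AcquisitionSeries | None = None


def make_cohort(
    spec: PhantomSpec,
    cohort: CohortSpec,
    protocol: AcquisitionProtocol = AcquisitionProtocol(),
    simulate: bool = True,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[PhantomSubject]]:
    """Generate a whole simulated cohort, optionally writing it to disk.

    Per subject: draw an age (uniform over ``age_range``), tissue values
    (between-subject Gaussians, plus any injected age slopes centered on the
    mean age), an anatomical jitter affine, and — if ``simulate`` — a noisy
    acquisition series. All ground truth is kept so recovery can be checked.
    Returns the cohort table and the subject objects; the directory layout
    written by ``out_dir`` is consumed by the reference/ROI pipelines. The
    output is byte-identical across runs for a fixed master seed.
    """
    rng = np.random.default_rng(cohort.master_seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=(cohort.n_subjects, 3))
    age_mid = 0.5 * (cohort.age_range[0] + cohort.age_range[1])

    subjects = []
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for i in range(cohort.n_subjects):
        sid = f"sub-{i + 1:03d}"
        srng = np.random.default_rng(seeds[i, 0])
        age = float(srng.uniform(*cohort.age_range))
        sex = "F" if srng.uniform() < 0.5 else "M"
        shifts = {
            name: tuple(s * (age - age_mid) for s in slopes)
            for name, slopes in cohort.age_slopes.items()
        }
        any_jitter = (
            cohort.jitter_rotation_deg > 0
            or cohort.jitter_translation_mm > 0
            or cohort.jitter_log_zoom > 0
            or cohort.jitter_shear > 0
        )
        jitter = (
            random_jitter(cohort, np.random.default_rng(seeds[i, 1]))
            if any_jitter
            else AffineTransform.identity()
        )
        labels, true_maps = make_phantom(
            spec,
            seed=np.random.default_rng(seeds[i, 2]),
            jitter=None if not any_jitter else jitter,
            value_shifts=shifts or None,
            tissue_variation=cohort.tissue_variation,
        )
        series = None
        if simulate:
            series = simulate_acquisition(
                true_maps,
                protocol,
                noise_sigma=cohort.noise_sigma,
                noise_model=cohort.noise_model,
                seed=np.random.default_rng(seeds[i, 2] + 1),
            )
        prefix = str(out_dir / sid) if out_dir is not None else ""
        if out_dir is not None:
            true_maps.save(prefix + "_truth", compress=False)
            labels.save(prefix + "_labels.nii", out_dir / (sid + "_labels.tsv"))
            jitter.to_json(prefix + "_jitter.json")
            if series is not None:
                series.save(prefix + "_series.nii")
        subjects.append(
            PhantomSubject(
                subject_id=sid, age_years=age, sex=sex,
                true_maps=true_maps, labels=labels, jitter=jitter, series=series,
            )
        )
        # prefixes are relative to the cohort directory so the layout is
        # relocatable (and byte-identical across runs)
        rows.append(
            {"subject_id": sid, "age_years": age, "sex": sex,
             "maps_prefix": (sid + "_truth") if out_dir is not None else ""}
        )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        table.to_csv(out_dir / "cohort.csv", index=False)
    return table, subjects


def default_template(spec: PhantomSpec = PhantomSpec()) -> TemplateSpace:
    """The shipped normalization target: the noise-free synthetic T2-weighted
    image of the canonical phantom (mean tissue values, no jitter) on the
    2 mm grid. Generated by code, so nothing binary ships with the package;
    any user-supplied template volume can be used instead.
    """
    _, maps = make_phantom(spec, seed=0, tissue_variation=False)
    t2w = synthesize(maps, ContrastSettings(echo_time_ms=100.0, repetition_time_ms=4500.0))
    return TemplateSpace(data=t2w, affine=spec.affine)
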