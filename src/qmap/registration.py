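"""Affine spatial normalization to a template.

A 12-parameter affine (translation, rotation, zoom, shear) is estimated by
minimizing the sum of squared differences (SSD) between an intensity-
standardized source image and the template, over a multi-resolution pyramid
(8 / 4 / 2 mm). The optimizer is deterministic: L-BFGS with an analytic image
gradient, initialized at identity plus a center-of-mass translation — no
random restarts. The same transform is then applied to the quantitative maps,
re-gridding them to the template's isotropic grid.

Conventions (also recorded in the transform JSON):

* world coordinates are mm, RAS; voxel indices 0-based;
* ``matrix = Translation @ Rz @ Ry @ Rx @ Shear @ Zoom``;
* the transform maps *template-space world coordinates to source-space world
  coordinates* (the resampling pull-back): ``apply_transform(vol, t, target)``
  fills each target voxel x with ``vol(t(x))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu

from .relaxometry import QuantMaps
from .synthesis import ContrastSettings, smooth, synthesize

__all__ = [
    "AffineTransform",
    "TemplateSpace",
    "estimate_affine",
    "apply_transform",
    "invert",
    "compose",
    "normalize_subject",
]

CONVENTION = "matrix = T @ Rz @ Ry @ Rx @ Shear @ Zoom; world mm RAS; maps target world -> source world"


def _rot_z(g):
    c, s = np.cos(g), np.sin(g)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(b):
    c, s = np.cos(b), np.sin(b)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


@dataclass(frozen=True)
class AffineTransform:
    """12-parameter affine world-space mapping.

    ``rotation`` holds Euler angles (x, y, z) in radians applied as
    Rz @ Ry @ Rx; ``shear`` holds the unit upper-triangular entries
    (xy, xz, yz). Zooms must be positive.
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    zoom: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shear: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("translation", "rotation", "zoom", "shear"):
            v = tuple(float(x) for x in getattr(self, name))
            if len(v) != 3 or not all(np.isfinite(v)):
                raise ValueError(f"{name} must be three finite numbers")
            object.__setattr__(self, name, v)
        if any(z <= 0 for z in self.zoom):
            raise ValueError("zooms must be positive")

    @property
    def matrix(self) -> np.ndarray:
        """The 4x4 homogeneous matrix, T @ Rz @ Ry @ Rx @ Shear @ Zoom."""
        ax, ay, az = self.rotation
        rot = _rot_z(az) @ _rot_y(ay) @ _rot_x(ax)
        sh = np.eye(3)
        sh[0, 1], sh[0, 2], sh[1, 2] = self.shear
        m = np.eye(4)
        m[:3, :3] = rot @ sh @ np.diag(self.zoom)
        m[:3, 3] = self.translation
        return m

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "AffineTransform":
        """Decompose a 4x4 matrix into the 12 parameters (QR-based).

        Requires positive determinant (proper rotation + positive zooms).
        Round-trips with :attr:`matrix` to ~1e-12.
        """
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise ValueError("matrix must be 4x4")
        m3 = matrix[:3, :3]
        if abs(np.linalg.det(m3)) < 1e-12:
            raise ValueError("matrix is singular")
        if np.linalg.det(m3) < 0:
            raise ValueError("matrix has negative determinant; reflections are not representable")
        q, r = np.linalg.qr(m3)
        signs = np.sign(np.diag(r))
        signs[signs == 0] = 1.0
        q = q * signs[None, :]
        r = r * signs[:, None]
        zoom = np.diag(r).copy()
        sh = r / zoom[:, None]          # unit upper triangular: R = Sh @ diag(zoom) row-scaled
        # R = Sh @ Z with Sh unit upper triangular: Sh[i,j] = R[i,j]/zoom[j]
        sh = r / zoom[None, :]
        beta = np.arcsin(np.clip(-q[2, 0], -1.0, 1.0))
        if abs(np.cos(beta)) > 1e-12:
            alpha = np.arctan2(q[2, 1], q[2, 2])
            gamma = np.arctan2(q[1, 0], q[0, 0])
        else:  # gimbal lock: fold everything into alpha
            alpha = np.arctan2(-q[1, 2], q[1, 1])
            gamma = 0.0
        return cls(
            translation=tuple(matrix[:3, 3]),
            rotation=(float(alpha), float(beta), float(gamma)),
            zoom=tuple(zoom),
            shear=(float(sh[0, 1]), float(sh[0, 2]), float(sh[1, 2])),
        )

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) world points through the transform."""
        points = np.asarray(points, dtype=float)
        return points @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "translation_mm": list(self.translation),
            "rotation_rad": list(self.rotation),
            "zoom": list(self.zoom),
            "shear": list(self.shear),
            "matrix_row_major": [list(row) for row in self.matrix],
            "convention": CONVENTION,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform":
        payload = json.loads(Path(path).read_text())
        return cls(
            translation=tuple(payload["translation_mm"]),
            rotation=tuple(payload["rotation_rad"]),
            zoom=tuple(payload["zoom"]),
            shear=tuple(payload["shear"]),
        )


def invert(transform: AffineTransform) -> AffineTransform:
    """Inverse transform; ``compose(invert(t), t)`` is the identity."""
    return AffineTransform.from_matrix(np.linalg.inv(transform.matrix))


def compose(a: AffineTransform, b: AffineTransform) -> AffineTransform:
    """Composition: ``compose(a, b)`` applied to x equals ``a(b(x))``."""
    return AffineTransform.from_matrix(a.matrix @ b.matrix)


@dataclass
class TemplateSpace:
    """A template volume with its grid; defines the normalization target."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("template must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def world_coordinates(self, step: int = 1) -> np.ndarray:
        """World (mm) coordinates of the voxel grid, shape (3, ...)."""
        idx = np.meshgrid(
            *(np.arange(0, n, step) for n in self.shape), indexing="ij"
        )
        vox = np.stack([i.ravel() for i in idx])
        world = self.affine[:3, :3] @ vox + self.affine[:3, 3:4]
        return world.reshape((3,) + idx[0].shape)


def apply_transform(
    volume: np.ndarray,
    volume_affine: np.ndarray,
    transform: AffineTransform,
    target: TemplateSpace,
    interpolation: str = "trilinear",
) -> np.ndarray:
    """Resample ``volume`` onto the target grid through the transform.

    Each target voxel x (world) takes ``volume(transform(x))``. Voxels that
    map outside the source field of view become NaN (floats) or 0 (integer
    labels/masks with nearest interpolation).
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}; use 'trilinear' or 'nearest'")
    volume = np.asarray(volume)
    order = 1 if interpolation == "trilinear" else 0

    # target voxel -> target world -> source world -> source voxel
    full = np.linalg.inv(np.asarray(volume_affine, dtype=float)) @ transform.matrix @ target.affine
    coords_shape = target.shape
    idx = np.indices(coords_shape, dtype=float).reshape(3, -1)
    src_vox = full[:3, :3] @ idx + full[:3, 3:4]

    is_int = np.issubdtype(volume.dtype, np.integer) or volume.dtype == bool
    if is_int and interpolation == "nearest":
        out = ndimage.map_coordinates(volume, src_vox, order=0, mode="constant", cval=0)
        return out.reshape(coords_shape).astype(volume.dtype)
    cval = np.nan
    out = ndimage.map_coordinates(
        volume.astype(float), src_vox, order=order, mode="constant", cval=cval
    )
    return out.reshape(coords_shape)


def _standardize(volume: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Background-anchored intensity standardization for SSD.

    Scales by the Otsu-foreground standard deviation and shifts so the
    background (air) median sits at 0 — out-of-field samples (filled with 0)
    then blend into air instead of creating spurious SSD. Returns the scaled
    image and the foreground mask.
    """
    vol = np.nan_to_num(np.asarray(volume, dtype=float), nan=0.0)
    finite = vol[np.isfinite(vol)]
    if finite.size == 0 or finite.max() == finite.min():
        raise ValueError("degenerate (constant) image; cannot standardize for registration")
    thr = threshold_otsu(finite)
    fg = vol > thr
    if fg.sum() < 8:
        fg = vol > np.percentile(finite, 75)
    sd = float(vol[fg].std())
    if sd == 0:
        raise ValueError("degenerate foreground; cannot standardize for registration")
    bg = float(np.median(vol[~fg])) if (~fg).any() else 0.0
    return (vol - bg) / sd, fg


def _centroid_world(volume: np.ndarray, affine: np.ndarray) -> np.ndarray:
    w = np.clip(np.nan_to_num(volume, nan=0.0), 0.0, None)
    w = w - w.min()
    tot = w.sum()
    if tot == 0:
        return affine[:3, :3] @ (np.asarray(volume.shape) / 2.0) + affine[:3, 3]
    idx = np.indices(volume.shape, dtype=float).reshape(3, -1)
    c_vox = (idx * w.ravel()[None, :]).sum(axis=1) / tot
    return affine[:3, :3] @ c_vox + affine[:3, 3]


_PARAM_SCALE = np.array([10.0, 10.0, 10.0, 0.1, 0.1, 0.1, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05])


def _params_to_vector(t: AffineTransform) -> np.ndarray:
    return np.array(t.translation + t.rotation + t.zoom + t.shear, dtype=float)


def _vector_to_params(v: np.ndarray) -> AffineTransform:
    return AffineTransform(
        translation=tuple(v[0:3]),
        rotation=tuple(v[3:6]),
        zoom=tuple(np.clip(v[6:9], 0.2, 5.0)),
        shear=tuple(v[9:12]),
    )


def _matrix_and_derivs(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """4x4 matrix of the parameter vector plus d(matrix)/d(param) by central
    differences (cheap relative to image resampling, exact to ~1e-10)."""
    m = _vector_to_params(v).matrix
    dm = np.zeros((12, 4, 4))
    h = 1e-6
    for j in range(12):
        vp, vm = v.copy(), v.copy()
        vp[j] += h
        vm[j] -= h
        dm[j] = (_vector_to_params(vp).matrix - _vector_to_params(vm).matrix) / (2 * h)
    return m, dm


def _ssd_cost_grad(
    v: np.ndarray,
    src: np.ndarray,
    src_grad: list[np.ndarray],
    src_world_to_vox: np.ndarray,
    tpl: np.ndarray,
    tpl_world_h: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Masked mean SSD and its analytic gradient wrt the 12 parameters.

    ``tpl_world_h``: (4, N) homogeneous world coordinates of the template
    voxels used for the cost. Out-of-field source samples contribute the
    background value 0 (both images are standardized so air ~ constant).
    """
    m, dm = _matrix_and_derivs(v)
    src_world = m @ tpl_world_h                     # (4, N)
    src_vox = src_world_to_vox @ src_world          # (4, N)
    coords = src_vox[:3]

    vals = ndimage.map_coordinates(src, coords, order=1, mode="constant", cval=0.0)
    resid = vals - tpl
    n = resid.size
    cost = float(resid @ resid) / n

    g_vox = np.stack(
        [ndimage.map_coordinates(g, coords, order=1, mode="constant", cval=0.0) for g in src_grad]
    )                                               # (3, N) gradient wrt source voxel coords
    b = src_world_to_vox[:3, :3]
    g_world = b.T @ g_vox                           # gradient wrt source world coords
    # dcost/dM[r, c] = (2/n) * sum_i resid_i * g_world[r, i] * X[c, i]
    dc_dm = (2.0 / n) * np.einsum("i,ri,ci->rc", resid, g_world, tpl_world_h)  # (3, 4)
    grad = np.array([np.sum(dc_dm * dm[j][:3, :]) for j in range(12)])
    return cost, grad


def estimate_affine(
    source: np.ndarray,
    source_affine: np.ndarray,
    template: np.ndarray,
    template_affine: np.ndarray,
    init: AffineTransform | None = None,
    levels_mm: tuple[float, ...] = (8.0, 4.0, 2.0),
    max_iter_per_level: tuple[int, ...] = (120, 60, 25),
    polish: bool = False,
) -> AffineTransform:
    """Estimate the 12-parameter affine from source to template by SSD.

    Both images are intensity-standardized inside an Otsu foreground before
    the comparison (signal units on both sides are arbitrary). The returned
    transform satisfies ``source(t(x)) ~ template(x)`` and locally minimizes
    the SSD; optimization proceeds coarse-to-fine over ``levels_mm`` and is
    fully deterministic.
    """
    src, _ = _standardize(source)
    tpl, tpl_fg = _standardize(template)
    source_affine = np.asarray(source_affine, dtype=float)
    template_affine = np.asarray(template_affine, dtype=float)
    tpl_vox = np.sqrt((template_affine[:3, :3] ** 2).sum(axis=0))
    src_vox_size = np.sqrt((source_affine[:3, :3] ** 2).sum(axis=0))
    # evaluate the SSD only on the template head plus a margin wide enough to
    # see the misaligned brain edge (~14 mm)
    margin_vox = max(1, int(round(14.0 / float(tpl_vox.min()))))
    cost_mask = ndimage.binary_dilation(tpl_fg, iterations=margin_vox)

    if init is None:
        t0 = _centroid_world(src, source_affine) - _centroid_world(tpl, template_affine)
        current = AffineTransform(translation=tuple(t0))
    else:
        current = init

    src_world_to_vox = np.linalg.inv(source_affine)

    first_level = True
    for level_mm, max_iter in zip(levels_mm, max_iter_per_level):
        # anti-alias both images for this level, then subsample the template grid
        extra = np.sqrt(np.clip((level_mm / 2.0) ** 2 - src_vox_size ** 2, 0.0, None))
        src_l = ndimage.gaussian_filter(src, sigma=extra / src_vox_size, mode="nearest")
        extra_t = np.sqrt(np.clip((level_mm / 2.0) ** 2 - tpl_vox ** 2, 0.0, None))
        tpl_l = ndimage.gaussian_filter(tpl, sigma=extra_t / tpl_vox, mode="nearest")
        step = max(1, int(round(level_mm / float(tpl_vox.max()))))
        sl = tuple(slice(None, None, step) for _ in range(3))
        keep = cost_mask[sl].ravel()
        tpl_sub = tpl_l[sl].ravel()[keep]
        idx = np.indices(tpl.shape)[(slice(None),) + sl].reshape(3, -1).astype(float)[:, keep]
        world = template_affine[:3, :3] @ idx + template_affine[:3, 3:4]
        tpl_world_h = np.vstack([world, np.ones(world.shape[1])])

        src_grad = list(np.gradient(src_l))

        def full_cost_grad(v, src_l=src_l, src_grad=src_grad, tpl_flat=tpl_sub, xw=tpl_world_h):
            return _ssd_cost_grad(v, src_l, src_grad, src_world_to_vox, tpl_flat, xw)

        # progressive parameter opening at the coarsest level (translation +
        # rotation, then + zoom, then the full affine) avoids the classic
        # rotation-vs-shear local minima; finer levels refine all 12.
        if first_level:
            stages = [np.arange(6), np.arange(9), np.arange(12)]
            first_level = False
        else:
            stages = [np.arange(12)]

        for free in stages:
            v0 = _params_to_vector(current)

            def fun(q, v0=v0, free=free, cg=full_cost_grad):
                v = v0.copy()
                v[free] = v0[free] + q * _PARAM_SCALE[free]
                c, g = cg(v)
                return c, g[free] * _PARAM_SCALE[free]

            res = optimize.minimize(
                fun,
                np.zeros(free.size),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-10},
            )
            if not np.isfinite(res.fun):
                raise RuntimeError(
                    f"registration diverged at the {level_mm} mm level: {res.message}"
                )
            cost0, _ = fun(np.zeros(free.size))
            if res.fun <= cost0:  # guard: never accept an SSD increase
                v = v0.copy()
                v[free] = v0[free] + res.x * _PARAM_SCALE[free]
                current = _vector_to_params(v)

    if polish:
        # derivative-free polish on the finest level: trilinear resampling
        # makes the cost piecewise-smooth, which can stall quasi-Newton line
        # searches just short of the optimum; the budget is capped because
        # each Powell evaluation resamples the full grid
        v0 = _params_to_vector(current)

        def fun_val(q, v0=v0, cg=full_cost_grad):
            return cg(v0 + q * _PARAM_SCALE)[0]

        res = optimize.minimize(
            fun_val,
            np.zeros(12),
            method="Powell",
            options={"maxiter": 2, "maxfev": 150, "xtol": 1e-4, "ftol": 1e-8},
        )
        if np.isfinite(res.fun) and res.fun <= fun_val(np.zeros(12)):
            current = _vector_to_params(v0 + res.x * _PARAM_SCALE)
    return current


def normalize_subject(
    maps: QuantMaps,
    template: TemplateSpace,
    contrast: ContrastSettings = ContrastSettings(),
    smoothing_fwhm_mm: float = 8.0,
    init: AffineTransform | None = None,
) -> tuple[QuantMaps, AffineTransform]:
    """Normalize a subject's quantitative maps to template space.

    Pipeline: synthesize a T2-weighted source image, smooth source and
    template with the same kernel, estimate the affine by SSD, then apply it
    to R1, R2 and PD (trilinear) and the validity mask (nearest), re-gridding
    to the template grid. Returns the normalized maps and the transform.
    """
    t2w = synthesize(maps, contrast)
    src_s = smooth(t2w, smoothing_fwhm_mm, maps.voxel_sizes)
    tpl_s = smooth(template.data, smoothing_fwhm_mm, template.voxel_sizes)
    transform = estimate_affine(src_s, maps.affine, tpl_s, template.affine, init=init)

    out = {}
    for name in ("r1", "r2", "pd"):
        out[name] = apply_transform(getattr(maps, name), maps.affine, transform, template)
    valid = apply_transform(
        maps.valid.astype(np.uint8), maps.affine, transform, template, interpolation="nearest"
    ).astype(bool)
    valid &= np.isfinite(out["r1"]) & np.isfinite(out["r2"]) & np.isfinite(out["pd"])
    for name in out:
        out[name] = np.where(valid, out[name], np.nan)
    normalized = QuantMaps(
        r1=out["r1"],
        r2=out["r2"],
        pd=out["pd"],
        valid=valid,
        affine=template.affine.copy(),
        pd_calibrated=maps.pd_calibrated,
    )
    return normalized, transform
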