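"""Voxelwise relaxometry: fit R1, R2 and proton density from a
multi-delay, multi-echo saturation-recovery acquisition.

The forward model per voxel is the ideal saturation-recovery, mono-exponential
spin-echo signal

    S(TD, TE) = M0 * (1 - exp(-TD * R1)) * exp(-TE * R2)

with the saturation delay TD and echo time TE in seconds, R1 and R2 in s^-1
and M0 in arbitrary scanner units. Complete spoiling and ideal saturation are
assumed; no B1 or saturation-efficiency correction is applied.

Fitting is nonlinear least squares on (R1, R2) with M0 eliminated analytically
(variable projection): for fixed rates the model is linear in M0, so the
optimizer works on a smooth two-parameter objective. The solver is a
vectorized Levenberg-Marquardt iteration over all voxels simultaneously,
initialized deterministically from a log-linear echo fit (R2) and a two-point
recovery ratio (R1). Unfittable voxels are flagged, never silently zeroed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
import nibabel as nib
import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "AcquisitionSeries",
    "QuantMaps",
    "model_signal",
    "fit_voxel",
    "fit_volume",
    "calibrate_pd",
    "FIT_OK",
    "FIT_INVALID_INPUT",
    "FIT_NO_CONVERGENCE",
]

MS_PER_S = 1000.0

# fit flag codes stored per voxel
FIT_OK = 0
FIT_INVALID_INPUT = 1
FIT_NO_CONVERGENCE = 2

# physiological search bounds for the rates, s^-1
_R1_BOUNDS = (1e-4, 50.0)
_R2_BOUNDS = (1e-4, 500.0)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing of a multi-delay, multi-echo saturation-recovery acquisition.

    All times are entered in milliseconds and converted to seconds once at
    this boundary; rates are in s^-1 everywhere else.
    """

    saturation_delays_ms: tuple[float, ...] = (100.0, 400.0, 1380.0, 2860.0)
    echo_times_ms: tuple[float, ...] = (14.0, 28.0, 42.0, 56.0, 70.0)
    repetition_time_ms: float = 2950.0

    def __post_init__(self) -> None:
        d = np.asarray(self.saturation_delays_ms, dtype=float)
        e = np.asarray(self.echo_times_ms, dtype=float)
        if d.ndim != 1 or d.size < 1 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("saturation delays must be positive and strictly increasing")
        if e.ndim != 1 or e.size < 1 or np.any(e <= 0) or np.any(np.diff(e) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        if self.repetition_time_ms <= 0:
            raise ValueError("repetition time must be positive")
        if np.any(d >= self.repetition_time_ms):
            raise ValueError("all saturation delays must be shorter than the repetition time")
        object.__setattr__(self, "saturation_delays_ms", tuple(float(x) for x in d))
        object.__setattr__(self, "echo_times_ms", tuple(float(x) for x in e))

    @property
    def n_delays(self) -> int:
        return len(self.saturation_delays_ms)

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times_ms)

    @property
    def delays_s(self) -> np.ndarray:
        return np.asarray(self.saturation_delays_ms, dtype=float) / MS_PER_S

    @property
    def echoes_s(self) -> np.ndarray:
        return np.asarray(self.echo_times_ms, dtype=float) / MS_PER_S

    def to_json(self, path: str | Path) -> None:
        payload = {
            "saturation_delays_ms": list(self.saturation_delays_ms),
            "echo_times_ms": list(self.echo_times_ms),
            "repetition_time_ms": self.repetition_time_ms,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionProtocol":
        payload = json.loads(Path(path).read_text())
        return cls(
            saturation_delays_ms=tuple(payload["saturation_delays_ms"]),
            echo_times_ms=tuple(payload["echo_times_ms"]),
            repetition_time_ms=float(payload["repetition_time_ms"]),
        )


@dataclass
class AcquisitionSeries:
    """A 4D acquisition: one image volume per (saturation delay, echo time).

    ``data`` has shape ``(n_delays, n_echoes, nx, ny, nz)``; ``affine`` is the
    voxel-to-world (mm, RAS) matrix shared by all volumes.
    """

    data: np.ndarray
    protocol: AcquisitionProtocol
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 5:
            raise ValueError("series data must be 5D: (delay, echo, x, y, z)")
        if self.data.shape[0] != self.protocol.n_delays or self.data.shape[1] != self.protocol.n_echoes:
            raise ValueError(
                f"series shape {self.data.shape[:2]} does not match protocol "
                f"({self.protocol.n_delays} delays x {self.protocol.n_echoes} echoes)"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def images_per_slice(self) -> int:
        """Number of acquired images per slice (delays x echoes)."""
        return self.protocol.n_delays * self.protocol.n_echoes

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[2:]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def save(self, path: str | Path) -> None:
        """Write as 4D NIfTI (t = delay * n_echoes + echo) plus a JSON sidecar."""
        path = Path(path)
        nd, ne = self.data.shape[:2]
        vol4d = np.moveaxis(self.data.reshape((nd * ne,) + self.shape), 0, -1)
        nib.save(nib.Nifti1Image(vol4d.astype(np.float32), self.affine), str(path))
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
        self.protocol.to_json(str(sidecar) + ".json")

    @classmethod
    def load(cls, path: str | Path, protocol_path: str | Path | None = None) -> "AcquisitionSeries":
        path = Path(path)
        if protocol_path is None:
            protocol_path = str(path.with_suffix("").with_suffix("")) + ".json"
        protocol = AcquisitionProtocol.from_json(protocol_path)
        img = nib.load(str(path))
        vol4d = np.asarray(img.dataobj, dtype=float)
        nd, ne = protocol.n_delays, protocol.n_echoes
        data = np.moveaxis(vol4d, -1, 0).reshape((nd, ne) + vol4d.shape[:3])
        return cls(data=data, protocol=protocol, affine=np.asarray(img.affine))


@dataclass
class QuantMaps:
    """Co-registered quantitative maps sharing one voxel grid.

    R1 and R2 are in s^-1. PD is in raw M0 units after fitting and in percent
    of pure water after :func:`calibrate_pd`. Voxels that could not be fitted
    carry NaN in all maps and ``False`` in ``valid``.
    """

    r1: np.ndarray
    r2: np.ndarray
    pd: np.ndarray
    valid: np.ndarray
    affine: np.ndarray
    fit_quality: np.ndarray | None = None
    fit_flags: np.ndarray | None = None
    pd_calibrated: bool = False

    def __post_init__(self) -> None:
        shapes = {self.r1.shape, self.r2.shape, self.pd.shape, self.valid.shape}
        if len(shapes) != 1:
            raise ValueError("R1, R2, PD and validity volumes must share one shape")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.r1.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def same_grid(self, other: "QuantMaps") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=1e-6)

    def parameter(self, name: str) -> np.ndarray:
        try:
            return {"R1": self.r1, "R2": self.r2, "PD": self.pd}[name]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}; expected R1, R2 or PD") from None

    def save(self, prefix: str | Path, compress: bool = True) -> None:
        """Write ``<prefix>_R1/_R2/_PD/_valid`` NIfTI volumes."""
        prefix = str(prefix)
        ext = ".nii.gz" if compress else ".nii"
        for suffix, vol, dtype in (
            ("_R1", self.r1, np.float32),
            ("_R2", self.r2, np.float32),
            ("_PD", self.pd, np.float32),
            ("_valid", self.valid.astype(np.uint8), np.uint8),
        ):
            nib.save(nib.Nifti1Image(np.asarray(vol, dtype=dtype), self.affine), prefix + suffix + ext)
        if self.fit_quality is not None:
            nib.save(
                nib.Nifti1Image(self.fit_quality.astype(np.float32), self.affine),
                prefix + "_fitq" + ext,
            )

    @classmethod
    def load(cls, prefix: str | Path) -> "QuantMaps":
        prefix = str(prefix)

        def _read(suffix: str):
            for ext in (".nii.gz", ".nii"):
                p = Path(prefix + suffix + ext)
                if p.exists():
                    img = nib.load(str(p))
                    return np.asarray(img.dataobj, dtype=float), np.asarray(img.affine)
            raise FileNotFoundError(f"missing map volume {prefix}{suffix}.nii[.gz]")

        r1, affine = _read("_R1")
        r2, _ = _read("_R2")
        pd, _ = _read("_PD")
        valid, _ = _read("_valid")
        return cls(r1=r1, r2=r2, pd=pd, valid=valid > 0.5, affine=affine)


def model_signal(r1, r2, m0, delay_ms, echo_ms):
    """Saturation-recovery spin-echo signal at one (delay, echo) combination.

    Parameters broadcast; times are milliseconds, rates s^-1. Returns
    ``m0 * (1 - exp(-delay*R1)) * exp(-echo*R2)`` with times in seconds.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    delay = np.asarray(delay_ms, dtype=float) / MS_PER_S
    echo = np.asarray(echo_ms, dtype=float) / MS_PER_S
    for name, arr in (("r1", r1), ("r2", r2), ("m0", m0), ("delay_ms", delay), ("echo_ms", echo)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} must be finite")
    if np.any(r1 < 0) or np.any(r2 < 0):
        raise ValueError("relaxation rates must be non-negative")
    if np.any(delay < 0) or np.any(echo < 0):
        raise ValueError("delay and echo times must be non-negative")
    return m0 * (1.0 - np.exp(-delay * r1)) * np.exp(-echo * r2)


def _signal_basis(r1: np.ndarray, r2: np.ndarray, delays_s: np.ndarray, echoes_s: np.ndarray) -> np.ndarray:
    """Unit-M0 model signals, shape (N, n_delays*n_echoes)."""
    rec = 1.0 - np.exp(-delays_s[None, :] * r1[:, None])        # (N, nd)
    dec = np.exp(-echoes_s[None, :] * r2[:, None])              # (N, ne)
    return (rec[:, :, None] * dec[:, None, :]).reshape(r1.shape[0], -1)


def _init_rates(signals: np.ndarray, delays_s: np.ndarray, echoes_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic starting values: R2 from the log-linear echo decay at the
    longest delay, then R1 from the first/last-delay recovery ratio solved by
    bisection (the ratio is strictly increasing in R1)."""
    tiny = np.finfo(float).tiny
    n = signals.shape[0]

    s_last = np.clip(signals[:, -1, :], tiny, None)             # (N, ne)
    y = np.log(s_last)
    e = echoes_s - echoes_s.mean()
    slope = (y * e[None, :]).sum(axis=1) / (e ** 2).sum()
    r2 = np.clip(-slope, *_R2_BOUNDS)

    # echo-collapsed recovery amplitudes ~ M0 * (1 - exp(-d*R1))
    w = np.exp(-echoes_s[None, :] * r2[:, None])
    denom = np.clip((w ** 2).sum(axis=1), tiny, None)
    amp = (signals * w[:, None, :]).sum(axis=2) / denom[:, None]  # (N, nd)
    d0, dl = delays_s[0], delays_s[-1]
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        ratio = amp[:, 0] / np.clip(amp[:, -1], tiny, None)
    ratio = np.clip(np.nan_to_num(ratio, nan=1.0, posinf=1.0), d0 / dl * (1 + 1e-9), 1.0 - 1e-9)

    lo = np.full(n, _R1_BOUNDS[0])
    hi = np.full(n, _R1_BOUNDS[1])
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        g = (1.0 - np.exp(-d0 * mid)) / (1.0 - np.exp(-dl * mid))
        too_low = g < ratio
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    r1 = np.clip(0.5 * (lo + hi), *_R1_BOUNDS)
    return r1, r2


def _fit_signals(
    signals: np.ndarray,
    delays_s: np.ndarray,
    echoes_s: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Levenberg-Marquardt over voxels.

    ``signals``: (N, n_delays, n_echoes). Returns (r1, r2, m0, residual, flags)
    where residual is the RMS misfit normalized by M0.
    """
    n = signals.shape[0]
    flat = signals.reshape(n, -1)
    k = flat.shape[1]

    finite = np.isfinite(flat).all(axis=1)
    nonzero = np.zeros(n, dtype=bool)
    nonzero[finite] = flat[finite].max(axis=1) > 0
    usable = finite & nonzero

    r1 = np.full(n, np.nan)
    r2 = np.full(n, np.nan)
    m0 = np.full(n, np.nan)
    resid = np.full(n, np.nan)
    flags = np.full(n, FIT_INVALID_INPUT, dtype=np.uint8)
    if not usable.any():
        return r1, r2, m0, resid, flags

    s = flat[usable]
    nu = s.shape[0]
    p1, p2 = _init_rates(signals[usable], delays_s, echoes_s)

    def sse_and_m0(sig: np.ndarray, a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        f = _signal_basis(a, b, delays_s, echoes_s)
        ff = np.einsum("ij,ij->i", f, f)
        sf = np.einsum("ij,ij->i", sig, f)
        amp = np.where(ff > 0, sf / np.where(ff > 0, ff, 1.0), 0.0)
        r = sig - amp[:, None] * f
        return np.einsum("ij,ij->i", r, r), amp, f

    sse, amp, f = sse_and_m0(s, p1, p2)
    lam = np.full(nu, 1e-3)
    converged = np.zeros(nu, dtype=bool)

    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        a, b = p1[active], p2[active]
        amp_a = amp[active]
        s_a = s[active]
        f_a = f[active]

        rec = 1.0 - np.exp(-delays_s[None, :] * a[:, None])
        dec = np.exp(-echoes_s[None, :] * b[:, None])
        drec = delays_s[None, :] * np.exp(-delays_s[None, :] * a[:, None])
        j1 = (amp_a[:, None, None] * (drec[:, :, None] * dec[:, None, :])).reshape(a.size, k)
        j2 = (-amp_a[:, None, None] * (rec[:, :, None] * (echoes_s[None, :] * dec)[:, None, :])).reshape(a.size, k)
        r = s_a - amp_a[:, None] * f_a
        # variable projection (Kaufman): project the Jacobian onto the
        # complement of the M0 direction, since M0 re-optimizes every step
        ff = np.einsum("ij,ij->i", f_a, f_a)
        ffs = np.where(ff > 0, ff, 1.0)
        j1 = j1 - f_a * (np.einsum("ij,ij->i", j1, f_a) / ffs)[:, None]
        j2 = j2 - f_a * (np.einsum("ij,ij->i", j2, f_a) / ffs)[:, None]

        a11 = np.einsum("ij,ij->i", j1, j1)
        a12 = np.einsum("ij,ij->i", j1, j2)
        a22 = np.einsum("ij,ij->i", j2, j2)
        g1 = np.einsum("ij,ij->i", j1, r)
        g2 = np.einsum("ij,ij->i", j2, r)

        l = lam[active]
        d11 = a11 * (1.0 + l)
        d22 = a22 * (1.0 + l)
        det = d11 * d22 - a12 ** 2
        det = np.where(np.abs(det) > 1e-300, det, 1e-300)
        step1 = (d22 * g1 - a12 * g2) / det
        step2 = (d11 * g2 - a12 * g1) / det

        cand1 = np.clip(a + step1, *_R1_BOUNDS)
        cand2 = np.clip(b + step2, *_R2_BOUNDS)
        sse_new, amp_new, f_new = sse_and_m0(s_a, cand1, cand2)

        better = sse_new <= sse[active]
        rel = np.maximum(
            np.abs(cand1 - a) / np.maximum(np.abs(a), 1e-12),
            np.abs(cand2 - b) / np.maximum(np.abs(b), 1e-12),
        )

        sse_drop = sse[active] - sse_new

        idx = np.where(active)[0]
        acc = idx[better]
        rej = idx[~better]
        p1[acc], p2[acc] = cand1[better], cand2[better]
        sse[acc], amp[acc], f[acc] = sse_new[better], amp_new[better], f_new[better]
        lam[acc] = np.maximum(lam[acc] / 3.0, 1e-12)
        lam[rej] = np.minimum(lam[rej] * 10.0, 1e10)
        # converged: tiny accepted step, or the objective is stationary
        stationary = sse_drop[better] <= 1e-12 * (sse_new[better] + 1e-30)
        converged[acc] |= (rel[better] < tol) | stationary
        converged[rej] |= lam[rej] >= 1e10

    r1[usable] = p1
    r2[usable] = p2
    m0[usable] = amp
    with np.errstate(invalid="ignore", divide="ignore"):
        resid[usable] = np.sqrt(sse / k) / np.where(amp > 0, amp, np.nan)
    fl = np.where(converged, FIT_OK, FIT_NO_CONVERGENCE).astype(np.uint8)
    flags[usable] = fl

    bad = usable.copy()
    bad[usable] = amp <= 0
    for arr in (r1, r2, m0, resid):
        arr[bad] = np.nan
    flags[bad] = FIT_INVALID_INPUT
    return r1, r2, m0, resid, flags


def fit_voxel(
    signals: np.ndarray, protocol: AcquisitionProtocol, tol: float = 1e-8, max_iter: int = 200
) -> tuple[float, float, float, float]:
    """Fit one voxel. ``signals`` is a (n_delays, n_echoes) matrix.

    Returns ``(R1, R2, M0, residual)``; all NaN for unusable input (all-zero
    or non-finite), which is a flagged result rather than an exception.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape != (protocol.n_delays, protocol.n_echoes):
        raise ValueError(
            f"signal matrix shape {signals.shape} does not match protocol "
            f"({protocol.n_delays} x {protocol.n_echoes})"
        )
    r1, r2, m0, resid, _ = _fit_signals(
        signals[None], protocol.delays_s, protocol.echoes_s, tol=tol, max_iter=max_iter
    )
    return float(r1[0]), float(r2[0]), float(m0[0]), float(resid[0])


def fit_volume(
    series: AcquisitionSeries,
    mask: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> QuantMaps:
    """Fit every voxel of an acquisition series.

    Voxels outside ``mask`` (if given) are flagged invalid and carry NaN.
    PD is returned in raw M0 units; apply :func:`calibrate_pd` for percent
    of pure water. Deterministic given identical inputs.
    """
    shape = series.shape
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != shape:
            raise ValueError(f"mask shape {mask.shape} does not match series grid {shape}")
        sel = mask.ravel()
    else:
        sel = np.ones(int(np.prod(shape)), dtype=bool)

    nd, ne = series.protocol.n_delays, series.protocol.n_echoes
    sig = series.data.reshape(nd, ne, -1)[:, :, sel]            # (nd, ne, M)
    sig = np.moveaxis(sig, -1, 0)                                # (M, nd, ne)
    r1v, r2v, m0v, residv, flagv = _fit_signals(
        sig, series.protocol.delays_s, series.protocol.echoes_s, tol=tol, max_iter=max_iter
    )

    def _full(vals, fill, dtype=float):
        out = np.full(sel.shape, fill, dtype=dtype)
        out[sel] = vals
        return out.reshape(shape)

    flags = _full(flagv, FIT_INVALID_INPUT, dtype=np.uint8)
    valid = flags != FIT_INVALID_INPUT
    return QuantMaps(
        r1=_full(r1v, np.nan),
        r2=_full(r2v, np.nan),
        pd=_full(m0v, np.nan),
        valid=valid,
        affine=series.affine,
        fit_quality=_full(residv, np.nan),
        fit_flags=flags,
    )


def calibrate_pd(maps: QuantMaps, water_reference_mask: np.ndarray) -> QuantMaps:
    """Rescale PD so the median M0 in a free-water reference region reads 100%.

    The reference region should be free-water-like (ventricular CSF: low R1,
    low R2). R1 and R2 are untouched; applying the calibration twice with the
    same mask is the identity.
    """
    mask = np.asarray(water_reference_mask).astype(bool)
    if mask.shape != maps.shape:
        raise ValueError("reference mask must match the map grid")
    sel = mask & maps.valid & np.isfinite(maps.pd)
    if not sel.any():
        raise ValueError("water reference mask is empty (no valid voxels)")
    ref = float(np.median(maps.pd[sel]))
    if ref <= 0:
        raise ValueError(f"reference median M0 must be positive, got {ref}")
    return replace(maps, pd=maps.pd * (100.0 / ref), pd_calibrated=True)
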