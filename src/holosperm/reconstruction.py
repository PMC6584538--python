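"""Tomographic reconstruction of 3D RI maps from angle-scanned holograms.

Stages: off-axis demodulation (sideband crop + 2D phase unwrapping),
Rytov conversion (complex log of the normalized field), Fourier-diffraction
gridding of each field's spectrum onto its Ewald-sphere cap, and an
iterative Gerchberg–Papoulis non-negativity correction for the missing
cone of axial frequencies left unmeasured by the finite illumination and
detection apertures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.restoration import unwrap_phase

from .core import RITomogram, ValidationError
from .forward import ComplexField, HologramSet, IlluminationPlan, ewald_cap_indices

__all__ = [
    "FrequencySupport",
    "ReconstructionSettings",
    "ReconstructionError",
    "lauer_resolution",
    "demodulate_hologram",
    "demodulate_set",
    "map_to_frequency_space",
    "tomogram_from_spectrum",
    "regularize_missing_cone",
    "reconstruct_tomogram",
]


class ReconstructionError(RuntimeError):
    """Raised when the missing-cone iteration diverges."""


@dataclass
class FrequencySupport:
    """Boolean mask of measured 3D frequency voxels (FFT layout)."""

    filled_mask: np.ndarray
    grid_spacing: tuple[float, float, float]  # cycles/µm per axis (z, y, x)

    @property
    def n_filled(self) -> int:
        return int(np.count_nonzero(self.filled_mask))


@dataclass
class ReconstructionSettings:
    """Missing-cone regularization knobs.

    ``regularization_iterations=0`` reproduces the naive (unregularized)
    inverse transform.  ``convergence_tol`` is the relative RI-contrast
    change between iterations at which the loop stops early.
    """

    regularization_iterations: int = 100
    convergence_tol: float = 1e-4
    enforce_nonnegativity: bool = True

    def validate(self) -> None:
        if self.regularization_iterations < 0:
            raise ValidationError("iterations must be ≥ 0")
        if self.convergence_tol <= 0:
            raise ValidationError("convergence_tol must be > 0")


def lauer_resolution(plan: IlluminationPlan, medium_ri: float = 1.337) -> tuple[float, float]:
    """Lauer-criterion optical resolution (lateral, axial) in nm.

    lateral = λ / (2·(NA_illum + NA_det));
    axial   = λ / ((n_m − √(n_m² − NA_det²)) + (n_m − √(n_m² − NA_illum²))).

    At the default optics (λ = 532 nm, NA 1.2/1.2, n_m = 1.337) this gives
    ≈(111, 356) nm — the quoted instrument-class resolution pair.
    """
    na_i, na_d = plan.na_illumination, plan.na_detection
    if not (0 < na_d < medium_ri) or not (0 <= na_i < medium_ri):
        raise ValidationError("need 0 < NA_det < n_m and 0 ≤ NA_illum < n_m")
    lam = plan.wavelength
    lateral = lam / (2.0 * (na_i + na_d))
    axial_band = (medium_ri - math.sqrt(medium_ri**2 - na_d**2)) + (
        medium_ri - math.sqrt(medium_ri**2 - na_i**2)
    )
    axial = lam / axial_band
    return (lateral * 1e3, axial * 1e3)


def demodulate_hologram(
    hologram: np.ndarray,
    plan: IlluminationPlan,
    pixel_size: float,
    medium_ri: float,
    carrier: tuple[float, float],
    illum_dir: Sequence[float] | None = None,
    out_shape: tuple[int, int] | None = None,
) -> ComplexField:
    """Retrieve the complex field from one off-axis intensity hologram.

    The hologram is mixed down by the reference carrier, the +1 sideband is
    cropped by a circular filter of radius NA_det/λ centred on the
    (known or assumed-normal) illumination frequency, inverse-transformed,
    optionally Fourier-downsampled to ``out_shape``, and the phase is
    2D-unwrapped and offset-aligned to the illumination ramp.

    Raises when the sideband cannot be separated from the reference/DC term.
    """
    holo = np.asarray(hologram, dtype=np.float64)
    if holo.ndim != 2:
        raise ValidationError("hologram must be a 2D intensity image")
    my, mx = holo.shape
    d = np.asarray(illum_dir, dtype=float) if illum_dir is not None else np.array([0.0, 0.0, 1.0])
    f_ill = medium_ri * d[:2] / plan.wavelength  # cycles/µm (fx, fy)
    radius = plan.na_detection / plan.wavelength
    fc = np.asarray(carrier, dtype=float)  # (fy, fx)
    sep = math.hypot(fc[1] - f_ill[0], fc[0] - f_ill[1])
    if sep <= radius:
        raise ValidationError(
            f"carrier/NA conflict: reference at {sep:.2f} cycles/µm from the "
            f"sideband centre, inside the NA_det/λ = {radius:.2f} crop"
        )

    Y, X = np.meshgrid(np.arange(my) * pixel_size, np.arange(mx) * pixel_size, indexing="ij")
    mixed = holo * np.exp(2j * math.pi * (fc[0] * Y + fc[1] * X))
    spec = np.fft.fft2(mixed)
    fx = np.fft.fftfreq(mx, pixel_size)
    fy = np.fft.fftfreq(my, pixel_size)
    FY, FX = np.meshgrid(fy, fx, indexing="ij")
    keep = (FX - f_ill[0]) ** 2 + (FY - f_ill[1]) ** 2 <= radius**2
    u = np.fft.ifft2(np.where(keep, spec, 0.0))

    if out_shape is not None and tuple(out_shape) != (my, mx):
        ny, nx = out_shape
        U = np.fft.fftshift(np.fft.fft2(u))
        y0, x0 = (my - ny) // 2, (mx - nx) // 2
        u = np.fft.ifft2(np.fft.ifftshift(U[y0 : y0 + ny, x0 : x0 + nx])) * (ny * nx) / (my * mx)
        pixel_size = pixel_size * mx / nx

    amp = np.abs(u)
    ph = unwrap_phase(np.angle(u))
    out = ComplexField(
        amplitude=amp,
        phase=ph,
        pixel_size=pixel_size,
        illum_dir=tuple(d),
        wavelength=plan.wavelength,
        medium_ri=medium_ri,
    )
    # align the global 2π offset left free by unwrapping
    resid = np.median(out.phase - out.illumination_ramp())
    out.phase = out.phase - 2 * math.pi * round(resid / (2 * math.pi))
    return out


def demodulate_set(hset: HologramSet, plan: IlluminationPlan,
                   out_shape: tuple[int, int] | None = None) -> list[ComplexField]:
    """Demodulate every frame of a :class:`HologramSet`."""
    if out_shape is None:
        os_ = plan.camera_oversample
        out_shape = (hset.frames.shape[1] // os_, hset.frames.shape[2] // os_)
    return [
        demodulate_hologram(
            frame, plan, hset.pixel_size, hset.medium_ri, hset.carrier,
            illum_dir=d, out_shape=out_shape,
        )
        for frame, d in zip(hset.frames, hset.illum_dirs)
    ]


def _check_unwrapped(psi_imag: np.ndarray) -> None:
    jump = max(
        float(np.abs(np.diff(psi_imag, axis=0)).max(initial=0.0)),
        float(np.abs(np.diff(psi_imag, axis=1)).max(initial=0.0)),
    )
    if jump > 0.95 * 2 * math.pi:
        raise ValidationError(
            f"Rytov phase shows ≈2π jumps (max step {jump:.2f} rad): unwrap "
            "the field phase before frequency mapping"
        )


def map_to_frequency_space(
    fields: Sequence[ComplexField],
    plan: IlluminationPlan,
    grid_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
) -> tuple[np.ndarray, FrequencySupport]:
    """Grid the Rytov spectra of all fields onto the 3D potential spectrum.

    Each field's 2D Rytov-phase spectrum is placed on its Ewald-sphere cap
    (nearest-voxel assignment); frequency voxels hit more than once are
    averaged.  Returns the filled scattering-potential spectrum (FFT
    layout, same normalization as ``np.fft.fftn`` of the potential) and the
    support mask of measured voxels.
    """
    if not fields:
        raise ValidationError("need at least one field")
    nz, ny, nx = grid_shape
    dz, dy, dx = voxel_size
    lam = fields[0].wavelength
    medium_ri = fields[0].medium_ri
    k0 = 2 * math.pi / lam
    km = medium_ri * k0
    dV = dz * dy * dx

    acc = np.zeros(grid_shape, dtype=np.complex128)
    count = np.zeros(grid_shape, dtype=np.int64)
    for f in fields:
        if f.phase.shape != (ny, nx):
            raise ValidationError(
                f"field grid {f.phase.shape} does not match target lateral grid {(ny, nx)}"
            )
        if not math.isclose(f.wavelength, lam, rel_tol=1e-9):
            raise ValidationError("fields must share one wavelength")
        psi = f.rytov_phase()
        _check_unwrapped(psi.imag)
        psi_spec = np.fft.fft2(psi) * (dy * dx)
        k_in = km * np.asarray(f.illum_dir)
        ok, iz, iy, ix, KZ = ewald_cap_indices(
            grid_shape, voxel_size, lam, medium_ri, plan.na_detection, k_in
        )
        vals = psi_spec[ok] * (2.0 * KZ[ok]) / 1j / dV
        np.add.at(acc, (iz, iy, ix), vals)
        np.add.at(count, (iz, iy, ix), 1)

    filled = count > 0
    acc[filled] /= count[filled]
    support = FrequencySupport(
        filled_mask=filled,
        grid_spacing=(1.0 / (nz * dz), 1.0 / (ny * dy), 1.0 / (nx * dx)),
    )
    return acc, support


def tomogram_from_spectrum(
    spectrum: np.ndarray,
    medium_ri: float,
    wavelength: float,
    voxel_size: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    metadata: dict | None = None,
) -> RITomogram:
    """Naive inverse transform: potential spectrum → RI map (no iteration)."""
    k0 = 2 * math.pi / wavelength
    v = np.fft.ifftn(spectrum).real
    n = np.sqrt(np.maximum(medium_ri**2 + v / (k0 * k0), 0.0))
    return RITomogram(n, voxel_size, medium_ri, origin=origin, metadata=metadata or {})


def regularize_missing_cone(
    spectrum: np.ndarray,
    support: FrequencySupport,
    settings: ReconstructionSettings,
    medium_ri: float,
    wavelength: float,
    voxel_size: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> RITomogram:
    """Gerchberg–Papoulis missing-cone correction with a non-negativity prior.

    Alternates a real-space step (RI clamped to ≥ medium, i.e. scattering
    potential ≥ 0) with a frequency-space step that restores the measured
    voxels, so the iteration extrapolates into the missing cone without
    ever overwriting data.  Stops at the iteration cap or when the relative
    RI-contrast change falls below ``convergence_tol``; three consecutive
    growing steps raise :class:`ReconstructionError` with the trace.
    """
    settings.validate()
    meta = {
        "iterations_requested": settings.regularization_iterations,
        "convergence_tol": settings.convergence_tol,
        "lauer_resolution_nm": None,
    }
    if settings.regularization_iterations == 0:
        return tomogram_from_spectrum(
            spectrum, medium_ri, wavelength, voxel_size, origin, metadata=meta | {"iterations_run": 0}
        )

    mask = support.filled_mask
    data = spectrum[mask]
    v = np.fft.ifftn(spectrum).real
    trace: list[float] = []
    grow = 0
    for it in range(settings.regularization_iterations):
        v_prev = v
        if settings.enforce_nonnegativity:
            v = np.clip(v, 0.0, None)
        s = np.fft.fftn(v)
        s[mask] = data
        v = np.fft.ifftn(s).real
        denom = float(np.linalg.norm(v_prev))
        rel = float(np.linalg.norm(v - v_prev)) / max(denom, 1e-30)
        trace.append(rel)
        if len(trace) >= 2 and rel > trace[-2]:
            grow += 1
            if grow >= 3:
                raise ReconstructionError(
                    f"missing-cone iteration diverging; relative-change trace: {trace}"
                )
        else:
            grow = 0
        if rel < settings.convergence_tol:
            break
    k0 = 2 * math.pi / wavelength
    n = np.sqrt(np.maximum(medium_ri**2 + v / (k0 * k0), 0.0))
    return RITomogram(
        n, voxel_size, medium_ri, origin=origin,
        metadata=meta | {"iterations_run": len(trace), "change_trace": trace},
    )


def reconstruct_tomogram(
    hset: HologramSet,
    plan: IlluminationPlan,
    grid_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    settings: ReconstructionSettings | None = None,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> RITomogram:
    """Hologram stack → RI tomogram (demodulate, grid, regularize)."""
    settings = settings or ReconstructionSettings()
    fields = demodulate_set(hset, plan, out_shape=grid_shape[1:])
    spectrum, support = map_to_frequency_space(fields, plan, grid_shape, voxel_size)
    tomo = regularize_missing_cone(
        spectrum, support, settings, hset.medium_ri, hset.wavelength, voxel_size, origin
    )
    tomo.metadata["lauer_resolution_nm"] = lauer_resolution(plan, hset.medium_ri)
    return tomo
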