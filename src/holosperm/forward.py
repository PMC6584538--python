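"""Weak-scattering forward model: angle-scanned fields and off-axis holograms.

Simulates what a holotomography instrument records for a known RI phantom.
For each illumination direction the complex Rytov phase at the detection
plane is synthesized from the Fourier diffraction theorem: the 2D spectrum
of the Rytov phase equals the Ewald-sphere cap of the 3D spectrum of the
scattering potential

    V(r) = k₀² (n(r)² − n_m²),      k₀ = 2π/λ,

shifted by the illumination wavevector and low-pass limited by the
detection NA.  This is the exact forward counterpart of the reconstruction
mapping, valid for weakly scattering samples (max Δn ≲ 0.05).

Off-axis holograms are intensity interferograms of the sample field with a
tilted plane-wave reference; the camera grid is oversampled relative to
the tomogram so the sideband, its twin and the autocorrelation term stay
separable in Fourier space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import RITomogram, ValidationError

__all__ = [
    "IlluminationPlan",
    "ComplexField",
    "HologramSet",
    "illumination_directions",
    "scattered_field",
    "scattered_fields",
    "synthesize_hologram",
    "simulate_holograms",
]

#: RI contrast above which the first-order (Rytov) model degrades
WEAK_SCATTERING_LIMIT = 0.05


@dataclass
class IlluminationPlan:
    """Optical configuration of the simulated instrument.

    Defaults are holotomography-class values: λ = 532 nm and matched
    illumination/detection NA of 1.2 in an aqueous medium — the
    configuration whose Lauer-criterion resolution reproduces the
    instrument's quoted ≈(110, 360) nm lateral/axial pair.
    """

    wavelength: float = 0.532  # µm
    na_illumination: float = 1.2
    na_detection: float = 1.2
    n_angles: int = 30
    angle_pattern: str = "circle"  # or "spiral"
    carrier_frequency: tuple[float, float] | None = None  # cycles/µm (fy, fx)
    # camera pixels per tomogram pixel: 3× keeps the carrier far enough
    # from the autocorrelation halo (|f_c − f_illum| > 2·NA/λ) for clean
    # sideband demodulation at full illumination NA
    camera_oversample: int = 3

    def validate(self, medium_ri: float) -> None:
        if not (0 < self.na_illumination < medium_ri):
            raise ValidationError("na_illumination must satisfy 0 < NA < medium RI")
        if not (0 < self.na_detection < medium_ri):
            raise ValidationError("na_detection must satisfy 0 < NA < medium RI")
        if self.n_angles < 1:
            raise ValidationError("n_angles must be ≥ 1")
        if self.angle_pattern not in ("circle", "spiral"):
            raise ValidationError(f"unknown angle_pattern {self.angle_pattern!r}")
        if self.camera_oversample < 1:
            raise ValidationError("camera_oversample must be ≥ 1")


@dataclass
class ComplexField:
    """Complex optical field at the detection plane.

    ``phase`` is unwrapped and includes the illumination plane-wave ramp
    (for a pure-medium sample the phase *is* the ramp); the sample-induced
    Rytov phase is recovered by subtracting the ramp implied by
    ``illum_dir``.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    pixel_size: float
    illum_dir: tuple[float, float, float]  # unit (dx, dy, dz), dz > 0
    wavelength: float
    medium_ri: float

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        self.phase = np.asarray(self.phase, dtype=np.float64)
        if self.amplitude.shape != self.phase.shape or self.amplitude.ndim != 2:
            raise ValidationError("amplitude and phase must be matching 2D grids")
        if (self.amplitude < 0).any():
            raise ValidationError("amplitude must be non-negative")

    @property
    def field(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)

    def illumination_ramp(self) -> np.ndarray:
        """Phase ramp k_in·r of the illumination plane wave on this grid."""
        k0 = 2 * math.pi / self.wavelength
        kx = self.medium_ri * k0 * self.illum_dir[0]
        ky = self.medium_ri * k0 * self.illum_dir[1]
        ny, nx = self.phase.shape
        Y, X = np.meshgrid(
            np.arange(ny) * self.pixel_size, np.arange(nx) * self.pixel_size, indexing="ij"
        )
        return kx * X + ky * Y

    def rytov_phase(self) -> np.ndarray:
        """Complex Rytov phase ψ = ln(u/u_in) (ramp removed)."""
        with np.errstate(divide="ignore"):
            log_amp = np.log(np.maximum(self.amplitude, 1e-12))
        return log_amp + 1j * (self.phase - self.illumination_ramp())


@dataclass
class HologramSet:
    """Stack of off-axis intensity holograms plus acquisition metadata."""

    frames: np.ndarray  # (n, My, Mx), non-negative intensities
    illum_dirs: np.ndarray  # (n, 3) unit vectors
    pixel_size: float  # camera pixel, µm
    wavelength: float
    medium_ri: float
    carrier: tuple[float, float]  # cycles/µm (fy, fx)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.illum_dirs = np.asarray(self.illum_dirs, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be (n, My, Mx)")
        if len(self.illum_dirs) != len(self.frames):
            raise ValidationError("one illumination direction per frame required")
        if (self.frames < 0).any():
            raise ValidationError("intensities must be non-negative")
        norms = np.linalg.norm(self.illum_dirs, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValidationError("illum_dirs must be unit vectors")


def illumination_directions(plan: IlluminationPlan, medium_ri: float) -> np.ndarray:
    """Unit wavevector directions (dx, dy, dz) of the illumination scan.

    ``circle``: all angles on a cone at the maximum illumination NA,
    equally spaced in azimuth.  ``spiral``: azimuthal sweep with the polar
    angle ramped from near-normal up to the NA limit.
    """
    plan.validate(medium_ri)
    n = plan.n_angles
    sin_max = plan.na_illumination / medium_ri
    phi = 2 * math.pi * np.arange(n) / n
    if plan.angle_pattern == "circle":
        sin_t = np.full(n, sin_max)
    else:  # spiral
        sin_t = sin_max * (np.arange(n) + 1) / n
    cos_t = np.sqrt(1.0 - sin_t**2)
    return np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)


def ewald_cap_indices(
    grid_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    wavelength: float,
    medium_ri: float,
    na_detection: float,
    k_in: np.ndarray,
):
    """Discrete Ewald-sphere cap for one illumination wavevector.

    Maps every detectable lateral frequency (kx, ky) onto the 3D frequency
    voxel nearest to k − k_in with k on the Ewald sphere
    kz = √((n_m k₀)² − kx² − ky²).  Shared by the forward model and the
    tomographic gridding so the two stay exactly consistent.

    Returns ``(ok, iz, iy, ix, kz)``: a (ny, nx) validity mask, 3D FFT
    indices (already wrapped) for the valid entries, and the Ewald kz over
    the full lateral grid.
    """
    nz, ny, nx = grid_shape
    dz, dy, dx = voxel_size
    k0 = 2 * math.pi / wavelength
    km = medium_ri * k0
    dkz = 2 * math.pi / (nz * dz)
    dky = 2 * math.pi / (ny * dy)
    dkx = 2 * math.pi / (nx * dx)
    kxg = 2 * math.pi * np.fft.fftfreq(nx, dx)
    kyg = 2 * math.pi * np.fft.fftfreq(ny, dy)
    KY, KX = np.meshgrid(kyg, kxg, indexing="ij")
    lat2 = KX**2 + KY**2
    det_mask = lat2 <= (k0 * na_detection) ** 2
    KZ = np.sqrt(np.maximum(km * km - lat2, 0.0))
    ix = np.round((KX - k_in[0]) / dkx).astype(np.int64)
    iy = np.round((KY - k_in[1]) / dky).astype(np.int64)
    iz = np.round((KZ - k_in[2]) / dkz).astype(np.int64)
    ok = (
        det_mask
        & (np.abs(ix) <= nx // 2)
        & (np.abs(iy) <= ny // 2)
        & (np.abs(iz) <= nz // 2)
    )
    return ok, iz[ok] % nz, iy[ok] % ny, ix[ok] % nx, KZ


def _potential_spectrum(tomogram: RITomogram, wavelength: float) -> np.ndarray:
    k0 = 2 * math.pi / wavelength
    v = k0 * k0 * (tomogram.values**2 - tomogram.medium_ri**2)
    return np.fft.fftn(v)


def _snap_illum(illum_dir, tomogram: RITomogram, wavelength: float):
    """Snap lateral illumination frequencies onto the FFT grid (avoids
    wrap-around leakage of the plane-wave ramp)."""
    k0 = 2 * math.pi / wavelength
    km = tomogram.medium_ri * k0
    _, dy, dx = tomogram.voxel_size
    _, ny, nx = tomogram.shape
    dkx = 2 * math.pi / (nx * dx)
    dky = 2 * math.pi / (ny * dy)
    kx = np.round(km * illum_dir[0] / dkx) * dkx
    ky = np.round(km * illum_dir[1] / dky) * dky
    kz2 = km * km - kx * kx - ky * ky
    if kz2 <= 0:
        raise ValidationError("illumination direction outside the medium's Ewald sphere")
    kz = math.sqrt(kz2)
    return np.array([kx, ky, kz]), np.array([kx, ky, kz]) / km


def scattered_fields(
    tomogram: RITomogram,
    plan: IlluminationPlan,
    illum_dirs: np.ndarray | None = None,
) -> list[ComplexField]:
    """Total fields at the detection plane for a whole angle scan.

    The 3D potential spectrum is computed once and re-sampled per angle.
    """
    plan.validate(tomogram.medium_ri)
    if illum_dirs is None:
        illum_dirs = illumination_directions(plan, tomogram.medium_ri)
    max_dn = float(tomogram.contrast().max(initial=0.0))
    if max_dn > WEAK_SCATTERING_LIMIT:
        warnings.warn(
            f"max RI contrast {max_dn:.3f} exceeds the weak-scattering bound "
            f"{WEAK_SCATTERING_LIMIT}; the first-order model degrades",
            stacklevel=2,
        )
    dz, dy, dx = tomogram.voxel_size
    if not math.isclose(dy, dx, rel_tol=1e-9):
        raise ValidationError("detection grid requires square lateral voxels")
    nz, ny, nx = tomogram.shape

    f3 = _potential_spectrum(tomogram, plan.wavelength)
    Y, X = np.meshgrid(np.arange(ny) * dy, np.arange(nx) * dx, indexing="ij")
    dV = dz * dy * dx

    out = []
    for d in np.atleast_2d(illum_dirs):
        k_in, d_snap = _snap_illum(d, tomogram, plan.wavelength)
        ok, iz, iy, ix, KZ = ewald_cap_indices(
            tomogram.shape, tomogram.voxel_size, plan.wavelength,
            tomogram.medium_ri, plan.na_detection, k_in,
        )
        psi_spec = np.zeros((ny, nx), dtype=np.complex128)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = 1j / (2.0 * KZ[ok]) * f3[iz, iy, ix] * dV
        psi_spec[ok] = vals
        psi = np.fft.ifft2(psi_spec) / (dy * dx)
        ramp = k_in[0] * X + k_in[1] * Y
        out.append(
            ComplexField(
                amplitude=np.exp(psi.real),
                phase=psi.imag + ramp,
                pixel_size=dx,
                illum_dir=tuple(d_snap),
                wavelength=plan.wavelength,
                medium_ri=tomogram.medium_ri,
            )
        )
    return out


def scattered_field(
    tomogram: RITomogram, illum_dir: Sequence[float], plan: IlluminationPlan
) -> ComplexField:
    """Total field for one illumination direction (see ``scattered_fields``)."""
    return scattered_fields(tomogram, plan, illum_dirs=np.asarray(illum_dir)[None, :])[0]


def _fourier_upsample(u: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return u
    ny, nx = u.shape
    U = np.fft.fftshift(np.fft.fft2(u))
    out = np.zeros((ny * factor, nx * factor), dtype=np.complex128)
    y0 = (ny * factor - ny) // 2
    x0 = (nx * factor - nx) // 2
    out[y0 : y0 + ny, x0 : x0 + nx] = U
    return np.fft.ifft2(np.fft.ifftshift(out)) * factor * factor


def default_carrier(plan: IlluminationPlan, pixel_size: float) -> tuple[float, float]:
    """Diagonal carrier at 1/3 of the camera Nyquist frequency (cycles/µm)."""
    nyq = 1.0 / (2.0 * pixel_size / plan.camera_oversample)
    return (nyq / 3.0, nyq / 3.0)


def snap_carrier(
    carrier: tuple[float, float], shape: tuple[int, int], pixel_size: float
) -> tuple[float, float]:
    """Round a carrier to the camera's discrete frequency grid.

    An off-grid carrier makes the reference delta leak (sinc tails) across
    the whole hologram spectrum, contaminating the demodulated sideband.
    """
    my, mx = shape
    return (
        round(carrier[0] * my * pixel_size) / (my * pixel_size),
        round(carrier[1] * mx * pixel_size) / (mx * pixel_size),
    )


def synthesize_hologram(
    fieldobj: ComplexField,
    plan: IlluminationPlan,
    noise_snr_db: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Off-axis hologram I = |u + R|² with a tilted plane-wave reference.

    The field is Fourier-upsampled onto the camera grid (pixel =
    ``pixel_size / camera_oversample``) so carrier + sideband stay below
    camera Nyquist; violations raise.  Optional additive Gaussian noise at
    the stated SNR (dB, relative to the mean intensity) is deterministic
    for a given seed.
    """
    plan.validate(fieldobj.medium_ri)
    os_ = plan.camera_oversample
    cam_px = fieldobj.pixel_size / os_
    nyq = 1.0 / (2.0 * cam_px)
    fc = plan.carrier_frequency or default_carrier(plan, fieldobj.pixel_size)
    band = (plan.na_detection + plan.na_illumination) / fieldobj.wavelength
    for f in fc:
        if abs(f) + band > nyq:
            raise ValidationError(
                f"carrier {f:.2f} cycles/µm + signal band {band:.2f} exceeds "
                f"camera Nyquist {nyq:.2f}: aliasing"
            )
    u = _fourier_upsample(fieldobj.field, os_)
    my, mx = u.shape
    fc = snap_carrier(fc, (my, mx), cam_px)
    Y, X = np.meshgrid(np.arange(my) * cam_px, np.arange(mx) * cam_px, indexing="ij")
    ref = np.exp(2j * math.pi * (fc[0] * Y + fc[1] * X))
    intensity = np.abs(u + ref) ** 2
    if noise_snr_db is not None:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        sigma = float(intensity.mean()) / (10.0 ** (noise_snr_db / 20.0))
        intensity = np.clip(intensity + gen.normal(0.0, sigma, intensity.shape), 0.0, None)
    return intensity


def simulate_holograms(
    tomogram: RITomogram,
    plan: IlluminationPlan,
    noise_snr_db: float | None = None,
    seed: int | None = None,
) -> HologramSet:
    """Full acquisition: one off-axis hologram per illumination angle."""
    fields = scattered_fields(tomogram, plan)
    rng = np.random.default_rng(seed)
    fc = plan.carrier_frequency or default_carrier(plan, fields[0].pixel_size)
    cam_shape = tuple(s * plan.camera_oversample for s in fields[0].phase.shape)
    fc = snap_carrier(fc, cam_shape, fields[0].pixel_size / plan.camera_oversample)
    plan_fc = IlluminationPlan(**{**plan.__dict__, "carrier_frequency": tuple(fc)})
    frames = np.stack(
        [synthesize_hologram(f, plan_fc, noise_snr_db, rng) for f in fields]
    )
    return HologramSet(
        frames=frames,
        illum_dirs=np.array([f.illum_dir for f in fields]),
        pixel_size=fields[0].pixel_size / plan.camera_oversample,
        wavelength=plan.wavelength,
        medium_ri=tomogram.medium_ri,
        carrier=tuple(fc),
        metadata={"n_angles": plan.n_angles, "noise_snr_db": noise_snr_db, "seed": seed,
                  "tomogram_pixel_size": fields[0].pixel_size},
    )
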