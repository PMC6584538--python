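"""Shared data containers and exceptions.

The central object of the pipeline is the :class:`RITomogram`, a 3D grid of
refractive-index (RI) values on a regular voxel lattice immersed in a medium
of known RI.  Axis order is ``(z, y, x)``; world coordinates are in µm with
the voxel-centre convention (voxel ``(0, 0, 0)`` sits at ``origin``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["ValidationError", "SizingError", "RITomogram"]


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


class SizingError(ValidationError):
    """Raised when a requested grid cannot contain the object plus padding."""


@dataclass
class RITomogram:
    """3D refractive-index map.

    Parameters
    ----------
    values
        RI values on a ``(z, y, x)`` grid.
    voxel_size
        ``(dz, dy, dx)`` spacing in µm.
    medium_ri
        RI of the immersion medium (background).
    origin
        World coordinate (µm) of the centre of voxel ``(0, 0, 0)``.
    metadata
        Free-form provenance (analytic volumes for fixture shapes,
        reconstruction settings, ...).
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    medium_ri: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError("tomogram values must be a 3D array")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel_size entries must be positive")
        if not np.isfinite(self.values).all():
            raise ValidationError("tomogram contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (µm) of voxel centres along each axis."""
        return tuple(
            self.origin[i] + np.arange(self.shape[i]) * self.voxel_size[i]
            for i in range(3)
        )  # type: ignore[return-value]

    def contrast(self) -> np.ndarray:
        """RI elevation above the medium (Δn)."""
        return self.values - self.medium_ri

    def validate(self, eps: float = 1e-3) -> None:
        """Check the physical invariant n ≥ n_medium − eps."""
        low = float(self.values.min())
        if low < self.medium_ri - eps:
            raise ValidationError(
                f"tomogram RI drops to {low:.4f}, below medium "
                f"{self.medium_ri:.4f} − {eps:g}"
            )
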