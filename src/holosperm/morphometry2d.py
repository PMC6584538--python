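"""2D silhouette morphometry from quantitative phase maps.

Measures the four classical sperm parameters — head length, head width,
midpiece length and tail length — from a single-cell phase image.  The
phase map is either measured (hologram demodulation) or projected from a
tomogram: optical phase delay is the path integral of RI contrast,
φ(x, y) = (2π/λ)·∫ Δn dz.

Measurement pipeline: threshold → largest component → 2D skeleton →
smoothed, boundary-extended medial axis → sub-pixel width profile by
perpendicular sampling.  Head extent comes from an ellipse fit to the
width profile; the midpiece/tail boundary is detected as the sharp drop of
the on-axis phase where the dense midpiece core ends (the same physical
criterion the 3D partition uses on RI values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

from ._axis import (
    extend_to_mask_edge,
    fit_head_profile,
    longest_skeleton_path,
    mask_interpolator,
    profile_width,
    smooth_resample,
)
from .core import RITomogram, ValidationError

__all__ = ["PhaseMap", "Morphometry2D", "project_phase", "measure_2d"]


@dataclass
class PhaseMap:
    """2D unwrapped phase image (radians) with square pixels (µm)."""

    phase: np.ndarray
    pixel_size: float
    source: str = "measured"

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64)
        if self.phase.ndim != 2:
            raise ValidationError("phase must be 2D")
        if not np.isfinite(self.phase).all():
            raise ValidationError("phase contains non-finite values")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0")


@dataclass
class Morphometry2D:
    """The four 2D parameters, in µm.  ``midpiece_length`` and
    ``tail_length`` are disjoint segments; their sum is the flagellum."""

    head_length: float
    head_width: float
    midpiece_length: float
    tail_length: float
    details: dict = field(default_factory=dict, repr=False)


def project_phase(tomogram: RITomogram, wavelength: float = 0.532) -> PhaseMap:
    """Project a tomogram to its ideal phase map along z (no diffraction)."""
    dz, dy, dx = tomogram.voxel_size
    if not math.isclose(dy, dx, rel_tol=1e-9):
        raise ValidationError("projected phase maps require square lateral voxels")
    phase = (2.0 * math.pi / wavelength) * tomogram.contrast().sum(axis=0) * dz
    return PhaseMap(phase=phase, pixel_size=dx, source="projected-from-tomogram")


def _threshold(phase: np.ndarray, method) -> float:
    """Foreground threshold.  ``otsu-floor`` caps Otsu's threshold at 5% of
    the phase maximum: a sperm phase image spans a huge dynamic range (thick
    head vs sub-wavelength tail) and plain Otsu can land above the tail
    signal, amputating the flagellum."""
    if isinstance(method, (int, float)):
        return float(method)
    t_otsu = float(filters.threshold_otsu(phase))
    if method == "otsu":
        return t_otsu
    if method == "otsu-floor":
        return min(t_otsu, 0.05 * float(phase.max()))
    raise ValidationError(f"unknown threshold method {method!r}")


def measure_2d(
    phase_map: PhaseMap,
    threshold="otsu-floor",
    head_boundary_frac: float = 0.25,
    default_midpiece_length: float = 13.0,
    include_midpiece_in_tail: bool = False,
) -> Morphometry2D:
    """Measure the four 2D parameters of a single-cell phase image.

    Raises ``ValidationError`` when the frame is empty or contains more
    than one cell-sized object.
    """
    phase = phase_map.phase
    px = phase_map.pixel_size
    thr = _threshold(phase, threshold)
    fg = phase > thr
    if not fg.any():
        raise ValidationError("empty frame: no foreground above threshold")
    # bridge sub-resolution gaps (e.g. a thin neck dipping under threshold);
    # a real instrument's diffraction blur would close these anyway
    fg = morphology.closing(fg, morphology.disk(2))
    lab, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=bool))
    sizes = ndimage.sum_labels(fg, lab, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    if n > 1 and sizes[order[1]] >= max(0.05 * sizes[order[0]], 50):
        raise ValidationError(f"multi-cell frame: {n} objects above threshold")
    mask = lab == (order[0] + 1)

    coords = np.argwhere(mask) * px
    cov = np.cov(coords.T)
    evals, evecs = np.linalg.eigh(cov)
    aspect = math.sqrt(max(evals[-1], 1e-12) / max(evals[0], 1e-12))
    if aspect < 1.3:
        # compact (head-only) object: principal-axis extents
        proj = (coords - coords.mean(axis=0)) @ evecs
        ext = proj.max(axis=0) - proj.min(axis=0) + px
        return Morphometry2D(
            head_length=float(ext[1]),
            head_width=float(ext[0]),
            midpiece_length=0.0,
            tail_length=0.0,
            details={"degenerate": "head-only", "aspect": aspect},
        )

    ds = px / 2.0
    skel = morphology.skeletonize(mask)
    path = longest_skeleton_path(skel) * px
    axis = smooth_resample(path, ds=ds)
    interp = mask_interpolator(mask, (px, px), (0.0, 0.0))
    axis = extend_to_mask_edge(axis, interp, ds=ds)
    axis = smooth_resample(axis, ds=ds, smooth_um=0.02)

    seg = np.linalg.norm(np.diff(axis, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(s[-1])

    tang = np.gradient(axis, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    normals = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    half_span = 0.75 * math.sqrt(evals[0]) * 4 + 2 * px
    w = np.array(
        [
            profile_width(interp, axis[i], normals[i], half_span, px / 4)
            for i in range(len(axis))
        ]
    )

    head_zone = s <= 0.3 * total
    tail_zone = s >= 0.7 * total
    if w[tail_zone].max(initial=0.0) > w[head_zone].max(initial=0.0):
        axis, w, s = axis[::-1], w[::-1], total - s[::-1]
        tang = -tang[::-1]

    fit = fit_head_profile(s, w, frac=head_boundary_frac)
    s1 = min(fit.boundary, total)
    head_length = fit.length
    head_width = fit.width if fit.ok else float(w[s <= s1].max(initial=float(w.max())))

    s2, drop = _core_end_from_phase(phase, px, axis, s, s1, total, default_midpiece_length)
    midpiece_length = max(s2 - s1, 0.0)
    tail_length = total - (s1 if include_midpiece_in_tail else s2)

    return Morphometry2D(
        head_length=head_length,
        head_width=head_width,
        midpiece_length=midpiece_length,
        tail_length=tail_length,
        details={
            "axis": axis,
            "arclength": s,
            "width_profile": w,
            "boundaries": (s1, s2),
            "head_fit_ok": fit.ok,
            "phase_drop": drop,
            "threshold": thr,
            "total_length": total,
        },
    )


def _core_end_from_phase(
    phase: np.ndarray,
    px: float,
    axis: np.ndarray,
    s: np.ndarray,
    s1: float,
    total: float,
    default_midpiece_length: float,
) -> tuple[float, float]:
    """Midpiece/tail boundary: steepest sustained drop of the on-axis phase.

    The midpiece carries the dense core, so its on-axis optical path
    exceeds the tail's; where the core ends the profile steps down.  The
    step is located at the gradient minimum (refined by the centroid of the
    gradient dip) and accepted only if the local drop clearly exceeds the
    tail's own gentle taper; otherwise a fixed default midpiece length is
    used.
    """
    p = ndimage.map_coordinates(phase, (axis / px).T, order=1, mode="nearest")
    sigma = max(0.25 / (s[1] - s[0]), 1.0)
    p_s = ndimage.gaussian_filter1d(p, sigma)
    g = np.gradient(p_s, s)
    lo, hi = s1 + 1.0, total - 2.0
    sel = (s >= lo) & (s <= hi)
    fallback = (min(s1 + default_midpiece_length, total), 0.0)
    if sel.sum() < 5:
        return fallback
    i_candidates = np.nonzero(sel)[0]
    i_min = i_candidates[np.argmin(g[sel])]
    # drop across a ±0.6 µm window vs typical tail slope
    wnd = 0.6
    p_before = np.interp(max(s[i_min] - wnd, 0.0), s, p_s)
    p_after = np.interp(min(s[i_min] + wnd, total), s, p_s)
    drop = float(p_before - p_after)
    tail_sel = s > s[i_min] + 2.0
    typical = float(np.median(np.abs(g[tail_sel]))) if tail_sel.sum() > 5 else 0.0
    if drop < max(4.0 * typical * 2 * wnd, 0.02):
        return fallback
    # refine: centroid of the gradient dip around the minimum
    win = (s >= s[i_min] - 0.8) & (s <= s[i_min] + 0.8)
    gd = np.clip(-g[win], 0.0, None)
    gd = np.where(gd >= 0.5 * gd.max(), gd, 0.0)
    s2 = float(np.sum(s[win] * gd) / np.sum(gd)) if gd.sum() > 0 else float(s[i_min])
    return (min(max(s2, s1), total), drop)
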