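"""Synthetic sperm phantoms and analytic fixture shapes.

A spermatozoon is modelled as three contiguous compartments threaded on a
common medial axis:

* head — triaxial ellipsoid, flattened in z (width ≥ thickness);
* midpiece — cylinder of constant radius carrying a coaxial high-RI core
  (the mitochondria-dense region);
* tail — linearly tapered filament.

Compartments are mutually exclusive and join head → midpiece → tail with
flat cuts perpendicular to the axis, so the rasterized volume of each part
converges to its closed-form value (ellipsoid, cylinder, cone frustum) as
the voxel size shrinks.  The axis may be bent with constant curvature in
the x–y plane; ``curvature=0`` gives a straight cell along +x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields, replace
from typing import Iterable

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .core import RITomogram, SizingError, ValidationError

__all__ = [
    "SpermDesign",
    "BreedPopulationSpec",
    "build_phantom",
    "calibrate_head_axes",
    "scale_to_cell_volume",
    "sample_population",
    "make_analytic_shape",
    "LABEL_BACKGROUND",
    "LABEL_HEAD",
    "LABEL_MIDPIECE",
    "LABEL_TAIL",
]

LABEL_BACKGROUND, LABEL_HEAD, LABEL_MIDPIECE, LABEL_TAIL = 0, 1, 2, 3

#: fields that are physical lengths/radii (µm) and must stay positive
_LENGTH_FIELDS = (
    "head_length",
    "head_width",
    "head_thickness",
    "midpiece_length",
    "midpiece_radius",
    "tail_length",
    "tail_base_radius",
    "tail_tip_radius",
)
_RI_FIELDS = ("head_ri", "midpiece_ri", "midpiece_core_ri", "tail_ri")


@dataclass
class SpermDesign:
    """Geometric and optical parameters of one phantom cell (µm / RI)."""

    head_length: float
    head_width: float
    head_thickness: float
    midpiece_length: float
    midpiece_radius: float
    tail_length: float
    tail_base_radius: float
    tail_tip_radius: float
    head_ri: float
    midpiece_ri: float
    midpiece_core_ri: float
    tail_ri: float
    curvature: float = 0.0  # 1/µm, constant bend of the medial axis
    midpiece_core_radius: float = 0.25

    def validate(self, medium_ri: float | None = None) -> None:
        for name in _LENGTH_FIELDS:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.head_width < self.head_thickness:
            raise ValidationError("head_width must be ≥ head_thickness (flattened head)")
        if self.tail_tip_radius > self.tail_base_radius:
            raise ValidationError("tail_tip_radius must be ≤ tail_base_radius")
        if medium_ri is not None:
            for name in _RI_FIELDS:
                if getattr(self, name) < medium_ri:
                    raise ValidationError(
                        f"{name}={getattr(self, name):.4f} below medium RI {medium_ri:.4f}"
                    )

    @property
    def total_length(self) -> float:
        return self.head_length + self.midpiece_length + self.tail_length

    def analytic_volumes(self) -> dict[str, float]:
        """Closed-form compartment volumes (µm³) of the flat-cut construction."""
        a = self.head_length / 2.0
        b = self.head_width / 2.0
        c = self.head_thickness / 2.0
        v_head = 4.0 / 3.0 * math.pi * a * b * c
        v_mid = math.pi * self.midpiece_radius**2 * self.midpiece_length
        rb, rt = self.tail_base_radius, self.tail_tip_radius
        v_tail = math.pi * self.tail_length * (rb * rb + rb * rt + rt * rt) / 3.0
        return {
            "head": v_head,
            "midpiece": v_mid,
            "tail": v_tail,
            "cell": v_head + v_mid + v_tail,
        }


@dataclass
class BreedPopulationSpec:
    """Per-group truncated-normal distributions over design parameters.

    ``groups`` maps a group label (e.g. ``"HO"``) to ``{field: (mean, sd)}``
    for any subset of :class:`SpermDesign` fields; unlisted fields are taken
    from ``base_design``.  Sampling truncates at mean ± ``truncation_sd``
    standard deviations and at physical bounds (positive lengths, RI not
    below the medium).
    """

    groups: dict[str, dict[str, tuple[float, float]]]
    n_per_group: int
    seed: int = 0
    base_design: SpermDesign | None = None
    truncation_sd: float = 4.0
    medium_ri: float = 1.337

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be ≥ 2")
        for label, params in self.groups.items():
            for name, (mean, sd) in params.items():
                if sd < 0:
                    raise ValidationError(f"{label}.{name}: SD must be ≥ 0")


def calibrate_head_axes(
    target_volume: float, length_to_width: float, width_to_thickness: float
) -> tuple[float, float, float]:
    """Ellipsoid semi-axes (a, b, c) in µm with prescribed volume and ratios.

    Solves 4/3·π·a·b·c = ``target_volume`` with a/b = ``length_to_width``
    and b/c = ``width_to_thickness`` exactly.
    """
    if target_volume <= 0:
        raise ValidationError("target_volume must be > 0")
    if length_to_width < 1 or width_to_thickness < 1:
        raise ValidationError("aspect ratios must be ≥ 1")
    b = (3.0 * target_volume * width_to_thickness / (4.0 * math.pi * length_to_width)) ** (1.0 / 3.0)
    a = length_to_width * b
    c = b / width_to_thickness
    return a, b, c


def scale_to_cell_volume(design: SpermDesign, target_volume: float) -> SpermDesign:
    """Scale midpiece/tail radii so the analytic whole-cell volume hits a target.

    The head is left untouched; the midpiece and tail cross-sections are
    scaled by a common factor.  Used to pin a phantom to a printed
    whole-cell volume while keeping the 2D silhouette lengths.
    """
    v = design.analytic_volumes()
    rest = target_volume - v["head"]
    if rest <= 0:
        raise ValidationError("target_volume must exceed the head volume")
    s = math.sqrt(rest / (v["midpiece"] + v["tail"]))
    return replace(
        design,
        midpiece_radius=design.midpiece_radius * s,
        tail_base_radius=design.tail_base_radius * s,
        tail_tip_radius=design.tail_tip_radius * s,
        midpiece_core_radius=design.midpiece_core_radius * s,
    )


def _axis_points(design: SpermDesign, ds: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample the medial axis.  Returns (arclengths, xy positions)."""
    L = design.total_length
    n = max(int(math.ceil(L / ds)) + 1, 2)
    s = np.linspace(0.0, L, n)
    k = design.curvature
    if abs(k) < 1e-12:
        xy = np.stack([s, np.zeros_like(s)], axis=1)
    else:
        r = 1.0 / k
        xy = np.stack([r * np.sin(k * s), r * (1.0 - np.cos(k * s))], axis=1)
    return s, xy


def build_phantom(
    design: SpermDesign,
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1),
    medium_ri: float = 1.337,
    pad: float = 1.0,
    shape: tuple[int, int, int] | None = None,
    return_labels: bool = False,
):
    """Rasterize a :class:`SpermDesign` into an :class:`RITomogram`.

    Voxels inside each compartment carry the compartment RI (the midpiece
    additionally carries a coaxial core at ``midpiece_core_ri``); everything
    else is ``medium_ri``.  With ``return_labels=True`` the ground-truth
    compartment label grid (0/1/2/3) is returned alongside the tomogram.

    Raises
    ------
    SizingError
        If an explicit ``shape`` cannot contain the cell plus ``pad``.
    ValidationError
        For non-physical designs (e.g. compartment RI below the medium).
    """
    design.validate(medium_ri=medium_ri)
    dz, dy, dx = (float(v) for v in voxel_size)
    ds = min(dz, dy, dx) / 2.0
    s, xy = _axis_points(design, ds)

    r_max = max(
        design.head_length / 2,
        design.head_width / 2,
        design.head_thickness / 2,
        design.midpiece_radius,
        design.tail_base_radius,
    )
    x_lo, y_lo = xy.min(axis=0) - r_max - pad
    x_hi, y_hi = xy.max(axis=0) + r_max + pad
    z_half = max(design.head_thickness / 2, design.midpiece_radius, design.tail_base_radius) + pad

    need = (
        int(math.ceil(2 * z_half / dz)) + 1,
        int(math.ceil((y_hi - y_lo) / dy)) + 1,
        int(math.ceil((x_hi - x_lo) / dx)) + 1,
    )
    if shape is None:
        shape = need
    elif any(shape[i] < need[i] for i in range(3)):
        raise SizingError(f"grid {shape} too small; cell plus pad needs at least {need}")
    origin = (-(shape[0] - 1) / 2.0 * dz, float(y_lo), float(x_lo))

    zc = origin[0] + np.arange(shape[0]) * dz
    yc = origin[1] + np.arange(shape[1]) * dy
    xc = origin[2] + np.arange(shape[2]) * dx

    labels = np.zeros(shape, dtype=np.uint8)
    values = np.full(shape, medium_ri, dtype=np.float64)
    core = np.zeros(shape, dtype=bool)

    L1 = design.head_length
    L2e = L1 + design.midpiece_length

    # --- tube compartments (midpiece + tail) via nearest axis sample ------
    tube_r_max = max(design.midpiece_radius, design.tail_base_radius)
    tree = cKDTree(xy)
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")
    pts_xy = np.stack([X.ravel(), Y.ravel()], axis=1)
    # prune by z first: tube lives near z=0
    near_z = np.abs(Z.ravel()) <= tube_r_max + max(dz, dy, dx)
    idx_near = np.nonzero(near_z)[0]
    if idx_near.size:
        d_xy, j = tree.query(pts_xy[idx_near], workers=-1)
        s_near = s[j]
        d3 = np.hypot(d_xy, Z.ravel()[idx_near])
        in_mid = (s_near >= L1) & (s_near <= L2e) & (d3 <= design.midpiece_radius)
        frac = np.clip((s_near - L2e) / max(design.tail_length, 1e-12), 0.0, 1.0)
        r_tail = design.tail_base_radius + frac * (design.tail_tip_radius - design.tail_base_radius)
        in_tail = (s_near > L2e) & (d3 <= r_tail)
        in_core = in_mid & (d3 <= design.midpiece_core_radius)
        # sub-voxel axial rod through the head keeps the tapering ellipsoid
        # tip connected to the midpiece (volume impact ≪ one voxel layer)
        in_rod = (s_near >= 0.5 * L1) & (s_near <= L1) & (d3 <= 0.9 * max(dz, dy, dx))

        flat = labels.ravel()
        flat[idx_near[in_tail]] = LABEL_TAIL
        flat[idx_near[in_mid]] = LABEL_MIDPIECE
        flat[idx_near[in_rod]] = LABEL_HEAD
        labels = flat.reshape(shape)
        cflat = core.ravel()
        cflat[idx_near[in_core]] = True
        core = cflat.reshape(shape)

    # --- head ellipsoid, oriented along the local tangent -----------------
    a, b, c = design.head_length / 2, design.head_width / 2, design.head_thickness / 2
    s_c = design.head_length / 2
    k = design.curvature
    if abs(k) < 1e-12:
        centre = np.array([s_c, 0.0])
        theta = 0.0
    else:
        r = 1.0 / k
        centre = np.array([r * np.sin(k * s_c), r * (1.0 - np.cos(k * s_c))])
        theta = k * s_c
    ct, st = math.cos(theta), math.sin(theta)
    U = ct * (X - centre[0]) + st * (Y - centre[1])
    V = -st * (X - centre[0]) + ct * (Y - centre[1])
    in_head = (U / a) ** 2 + (V / b) ** 2 + (Z / c) ** 2 <= 1.0
    labels[in_head] = LABEL_HEAD
    core &= labels == LABEL_MIDPIECE

    values[labels == LABEL_TAIL] = design.tail_ri
    values[labels == LABEL_MIDPIECE] = design.midpiece_ri
    values[core] = design.midpiece_core_ri
    values[labels == LABEL_HEAD] = design.head_ri

    tomo = RITomogram(
        values,
        (dz, dy, dx),
        medium_ri,
        origin=origin,
        metadata={"design": {f.name: getattr(design, f.name) for f in dc_fields(design)}},
    )
    if return_labels:
        return tomo, labels
    return tomo


_PHYS_LOWER = 1e-3  # µm floor for sampled lengths/radii


def sample_population(spec: BreedPopulationSpec) -> dict[str, list[SpermDesign]]:
    """Draw ``n_per_group`` designs per group from truncated normals.

    Deterministic for a fixed ``spec.seed``; each (group, field) pair gets
    its own seeded stream so adding a field does not reshuffle the others.
    """
    spec.validate()
    base = spec.base_design
    if base is None:
        from .presets import default_design

        base = default_design()
    out: dict[str, list[SpermDesign]] = {}
    for g_i, (label, params) in enumerate(sorted(spec.groups.items())):
        draws: dict[str, np.ndarray] = {}
        for f_i, name in enumerate(sorted(params)):
            mean, sd = params[name]
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed, g_i, f_i]))
            if sd == 0:
                draws[name] = np.full(spec.n_per_group, mean)
                continue
            lo = mean - spec.truncation_sd * sd
            hi = mean + spec.truncation_sd * sd
            if name in _LENGTH_FIELDS:
                lo = max(lo, _PHYS_LOWER)
            if name in _RI_FIELDS:
                lo = max(lo, spec.medium_ri)
            draws[name] = stats.truncnorm.rvs(
                (lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd,
                size=spec.n_per_group, random_state=rng,
            )
        designs = []
        for i in range(spec.n_per_group):
            d = replace(base, **{k: float(v[i]) for k, v in draws.items()})
            if d.head_thickness > d.head_width:
                d = replace(d, head_thickness=d.head_width)
            d.validate()
            designs.append(d)
        out[label] = designs
    return out


def make_analytic_shape(
    kind: str,
    params: dict[str, float | Iterable[float]],
    ri: float = 1.35,
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1),
    medium_ri: float = 1.337,
    pad: float = 1.0,
) -> RITomogram:
    """Voxelize a simple shape with its analytic volume/area as metadata.

    ``kind`` is one of ``sphere`` (radius), ``ellipsoid`` (semi_axes, z/y/x
    order), ``cube`` (edge), ``cylinder`` (radius, length; axis along x).
    The analytic ellipsoid area uses the Thomsen approximation (exact for
    the sphere).
    """
    dz, dy, dx = (float(v) for v in voxel_size)
    if kind == "sphere":
        r = float(params["radius"])
        half = (r + pad, r + pad, r + pad)
        vol = 4.0 / 3.0 * math.pi * r**3
        area = 4.0 * math.pi * r**2
    elif kind == "ellipsoid":
        sa = tuple(float(v) for v in params["semi_axes"])
        half = tuple(v + pad for v in sa)
        vol = 4.0 / 3.0 * math.pi * sa[0] * sa[1] * sa[2]
        p = 1.6075
        ap, bp, cp = (v**p for v in sa)
        area = 4.0 * math.pi * ((ap * bp + ap * cp + bp * cp) / 3.0) ** (1.0 / p)
    elif kind == "cube":
        e = float(params["edge"])
        half = (e / 2 + pad,) * 3
        vol, area = e**3, 6.0 * e**2
    elif kind == "cylinder":
        r, length = float(params["radius"]), float(params["length"])
        half = (r + pad, r + pad, length / 2 + pad)
        vol = math.pi * r**2 * length
        area = 2.0 * math.pi * r * (r + length)
    else:
        raise ValidationError(f"unknown shape kind: {kind!r}")
    if any(v <= pad for v in half):
        raise ValidationError("shape dimensions must be positive")

    # voxel centres sit half a step off the shape's symmetry planes so that
    # grid-aligned boundaries (cube faces) fall between centres, not on them
    shape = tuple(2 * int(math.ceil(half[i] / (dz, dy, dx)[i])) for i in range(3))
    origin = tuple((-shape[i] / 2.0 + 0.5) * (dz, dy, dx)[i] for i in range(3))
    zc = origin[0] + np.arange(shape[0]) * dz
    yc = origin[1] + np.arange(shape[1]) * dy
    xc = origin[2] + np.arange(shape[2]) * dx
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")

    if kind == "sphere":
        mask = Z**2 + Y**2 + X**2 <= r**2
    elif kind == "ellipsoid":
        mask = (Z / sa[0]) ** 2 + (Y / sa[1]) ** 2 + (X / sa[2]) ** 2 <= 1.0
    elif kind == "cube":
        mask = (np.abs(Z) <= e / 2) & (np.abs(Y) <= e / 2) & (np.abs(X) <= e / 2)
    else:
        mask = (Z**2 + Y**2 <= r**2) & (np.abs(X) <= length / 2)

    values = np.full(shape, medium_ri)
    values[mask] = ri
    return RITomogram(
        values,
        (dz, dy, dx),
        medium_ri,
        origin=origin,
        metadata={"kind": kind, "analytic_volume": vol, "analytic_area": area},
    )
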