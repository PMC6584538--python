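"""Medial-axis utilities shared by the 2D and 3D morphometry modules.

The cell axis is recovered from a topological skeleton of the segmented
cell: skeleton voxels form a graph (full diagonal connectivity, Euclidean
edge weights), the axis is the longest geodesic path through that graph,
smoothed by a spline and extended along its end tangents until it leaves
the mask.  A width profile along the axis then drives compartment
boundaries; the head is located by fitting an ellipse to the profile,
which (unlike a bare width threshold) recovers the full head extent of an
ellipsoidal head without the ~1.5% truncation bias of the threshold
crossing alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, ndimage, sparse
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "longest_skeleton_path",
    "smooth_resample",
    "extend_to_mask_edge",
    "mask_interpolator",
    "profile_width",
    "HeadProfileFit",
    "fit_head_profile",
]


def longest_skeleton_path(skeleton: np.ndarray) -> np.ndarray:
    """Ordered voxel coordinates of the longest geodesic in a skeleton.

    Works for 2D and 3D boolean skeletons.  Uses the standard double
    shortest-path sweep: the farthest node from an arbitrary start, then
    the farthest node from that — the path between them is the skeleton's
    diameter.
    """
    coords = np.argwhere(skeleton)
    n = len(coords)
    if n == 0:
        raise ValueError("empty skeleton")
    if n == 1:
        return coords
    index = -np.ones(skeleton.shape, dtype=np.int64)
    index[tuple(coords.T)] = np.arange(n)

    ndim = skeleton.ndim
    offsets = np.array(
        [o for o in np.ndindex(*(3,) * ndim)], dtype=np.int64
    ) - 1
    offsets = offsets[np.any(offsets != 0, axis=1)]

    rows, cols, w = [], [], []
    for off in offsets:
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < np.array(skeleton.shape)), axis=1)
        j = index[tuple(nb[ok].T)]
        hit = j >= 0
        rows.append(np.arange(n)[ok][hit])
        cols.append(j[hit])
        w.append(np.full(hit.sum(), float(np.linalg.norm(off))))
    g = sparse.csr_matrix(
        (np.concatenate(w), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )

    d0 = dijkstra(g, indices=0)
    d0[~np.isfinite(d0)] = -1
    e1 = int(np.argmax(d0))
    d1, pred = dijkstra(g, indices=e1, return_predecessors=True)
    d1[~np.isfinite(d1)] = -1
    e2 = int(np.argmax(d1))
    path = [e2]
    while path[-1] != e1:
        p = pred[path[-1]]
        if p < 0:
            break
        path.append(int(p))
    return coords[path[::-1]]


def smooth_resample(points_um: np.ndarray, ds: float, smooth_um: float = 0.15) -> np.ndarray:
    """Fit a smoothing spline through ordered axis points and resample at
    uniform arclength ``ds`` (µm).  ``smooth_um`` is the per-point RMS
    smoothing allowance — raw skeleton chains otherwise overestimate
    arclength through lattice stair-stepping."""
    pts = np.asarray(points_um, dtype=float)
    # collapse consecutive duplicates
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
    pts = pts[keep]
    if len(pts) < 2:
        return pts
    k = min(3, len(pts) - 1)
    tck, _ = interpolate.splprep(pts.T, s=len(pts) * smooth_um**2, k=k)
    u = np.linspace(0, 1, max(4 * len(pts), 64))
    dense = np.stack(interpolate.splev(u, tck), axis=1)
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total < ds:
        return dense[[0, -1]]
    s_new = np.arange(0.0, total + ds / 2, ds)
    out = np.stack([np.interp(s_new, arc, dense[:, i]) for i in range(dense.shape[1])], axis=1)
    return out


def mask_interpolator(mask: np.ndarray, voxel_size, origin):
    """Return f(points_um) -> linearly interpolated mask occupancy in [0, 1]."""
    m = mask.astype(np.float32)
    vs = np.asarray(voxel_size, dtype=float)
    org = np.asarray(origin, dtype=float)

    def f(pts_um: np.ndarray) -> np.ndarray:
        idx = (np.atleast_2d(pts_um) - org) / vs
        return ndimage.map_coordinates(m, idx.T, order=1, mode="constant", cval=0.0)

    return f


def extend_to_mask_edge(axis_um: np.ndarray, interp, ds: float, max_extend: float = 10.0) -> np.ndarray:
    """Prolong both axis ends along their tangents until occupancy < 0.5.

    Skeletons stop well inside blunt ends (the medial axis of an ellipse
    ends at its vertex curvature centres), so the measured axis must be
    pushed out to the actual cell boundary, with the final point placed
    sub-voxel by linear interpolation of the occupancy crossing.
    """
    out = axis_um
    for end in (0, 1):
        pts = out[::-1] if end == 0 else out
        tang = pts[-1] - pts[-min(5, len(pts) - 1) - 1]
        norm = np.linalg.norm(tang)
        if norm < 1e-9:
            continue
        tang = tang / norm
        n_steps = int(max_extend / ds)
        probe = pts[-1] + tang * ds * np.arange(1, n_steps + 1)[:, None]
        occ = interp(probe)
        below = np.nonzero(occ < 0.5)[0]
        if below.size == 0:
            continue
        stop = below[0]
        # sub-step edge position between last inside and first outside probe
        prev_occ = occ[stop - 1] if stop > 0 else interp(pts[-1][None])[0]
        frac = (prev_occ - 0.5) / max(prev_occ - occ[stop], 1e-9)
        edge = pts[-1] + tang * ds * (stop + frac)
        ext = probe[:stop]
        seg = np.vstack([ext, edge]) if len(ext) else edge[None]
        out = np.vstack([seg[::-1], out]) if end == 0 else np.vstack([out, seg])
    return out


def profile_width(interp, point: np.ndarray, direction: np.ndarray, half_span: float, step: float) -> float:
    """Full occupancy width along a line through ``point``.

    Samples the mask interpolator along ±``half_span`` and returns the
    distance between the outermost 0.5-crossings, linearly interpolated to
    sub-voxel precision.  Works in 2D and 3D.
    """
    t = np.arange(-half_span, half_span + step / 2, step)
    pts = point[None, :] + t[:, None] * direction[None, :]
    v = interp(pts)
    above = v >= 0.5
    if not above.any():
        return 0.0
    i0, i1 = np.nonzero(above)[0][[0, -1]]
    lo = t[i0]
    if i0 > 0 and v[i0] > v[i0 - 1]:
        lo = t[i0] - (v[i0] - 0.5) / (v[i0] - v[i0 - 1]) * step
    hi = t[i1]
    if i1 < len(t) - 1 and v[i1] > v[i1 + 1]:
        hi = t[i1] + (v[i1] - 0.5) / (v[i1] - v[i1 + 1]) * step
    return float(hi - lo)


@dataclass
class HeadProfileFit:
    """Ellipse model of the head's axial width profile.

    w(s)² = W²·(1 − ((s − c)/a)²): ``length`` = 2a, ``width`` = W,
    ``boundary`` = c + a (arclength where the head ends).
    """

    length: float
    width: float
    centre: float
    boundary: float
    ok: bool


def fit_head_profile(s: np.ndarray, w: np.ndarray, frac: float = 0.25) -> HeadProfileFit:
    """Locate the head on a width profile ordered head-first.

    The head/midpiece boundary is seeded by the first arclength where the
    width falls below ``frac`` × the maximum head width; the reported head
    length/width come from a least-squares ellipse fit to the profile up to
    that crossing.  Falls back to the raw threshold crossing when the fit
    degenerates (e.g. non-elliptical heads).
    """
    s = np.asarray(s, dtype=float)
    w = np.asarray(w, dtype=float)
    w_max = float(w.max())
    i_max = int(np.argmax(w))
    thresh = frac * w_max

    cross = None
    for i in range(i_max, len(s)):
        if w[i] < thresh:
            # sub-sample crossing
            f = (w[i - 1] - thresh) / max(w[i - 1] - w[i], 1e-12)
            cross = s[i - 1] + f * (s[i] - s[i - 1])
            break
    if cross is None:
        cross = float(s[-1])

    sel = (s <= cross) & (w >= 0.35 * w_max)
    fit_ok = False
    length = cross
    width = w_max
    centre = cross / 2.0
    if sel.sum() >= 5:
        C2, C1, C0 = np.polyfit(s[sel], w[sel] ** 2, 2)
        if C2 < 0:
            c = -C1 / (2 * C2)
            W2 = C0 + C2 * c * c + C1 * c  # value of the quadratic at its apex
            a2 = -W2 / C2
            if W2 > 0 and a2 > 0:
                a = float(np.sqrt(a2))
                bnd = c + a
                if 0.5 * cross <= bnd <= 1.6 * cross:
                    length, width, centre = 2 * a, float(np.sqrt(W2)), float(c)
                    cross = bnd
                    fit_ok = True
    return HeadProfileFit(length=length, width=width, centre=centre, boundary=float(cross), ok=fit_ok)
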