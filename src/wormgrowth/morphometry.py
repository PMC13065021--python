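"""Midline extraction, straightening, volumetry and fluorescence measures.

A segmented worm is straightened along its midline and its volume inferred
assuming rotational symmetry: each straightened cross-section is treated as
a circle whose diameter is the measured body width at that position, so

    V = Σ_i π · (w_i / 2)² · Δs · pixel_size³

with Δs = 1 px arc-length steps.  Fluorescence is quantified as the
background-subtracted sum over the mask (total F) and per-pixel
concentration C = F / area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.interpolate import splev, splprep
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize

__all__ = [
    "Midline",
    "StraightenedWorm",
    "FluorMeasure",
    "StraighteningError",
    "extract_midline",
    "straighten",
    "estimate_volume",
    "estimate_background",
    "measure_fluorescence",
    "quantify_roi",
]


class StraighteningError(RuntimeError):
    """Raised when a mask has no usable elongated midline (e.g. a coil)."""


@dataclass
class Midline:
    """Ordered sub-pixel midline points with cumulative arc length (px)."""

    points: np.ndarray  # (N, 2) float (row, col)
    arc_length: np.ndarray  # (N,) cumulative, starts at 0

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])


@dataclass
class StraightenedWorm:
    """Worm resampled into a straightened frame.

    Rows are cross-sections along arc length; ``width`` is the body width
    per row in px (sub-pixel, from integrating the interpolated mask along
    the normal); ``mask_rows`` is the thresholded straightened mask.
    """

    image: np.ndarray  # (N, 2*halfwidth+1) sampled intensities
    mask_rows: np.ndarray  # same shape, bool
    width: np.ndarray  # (N,) px
    length: float  # px
    frame_index: int = -1
    truncated_rows: int = 0  # rows whose normal exited the image


@dataclass
class FluorMeasure:
    """Background-subtracted fluorescence of one frame."""

    total: float  # F, a.u.
    area: int  # px
    concentration: float  # C = F / A
    background: float
    negative_total: bool = False  # background likely overestimated


# ---------------------------------------------------------------------------
# midline
# ---------------------------------------------------------------------------

_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(skel: np.ndarray):
    """Sparse weighted adjacency over skeleton pixels (8-connectivity)."""
    coords = np.argwhere(skel)
    index = -np.ones(skel.shape, dtype=int)
    index[tuple(coords.T)] = np.arange(len(coords))
    rows, cols, w = [], [], []
    for dy, dx in _NEIGH:
        shifted = np.zeros_like(skel)
        ys = slice(max(dy, 0), skel.shape[0] + min(dy, 0))
        xs = slice(max(dx, 0), skel.shape[1] + min(dx, 0))
        ys2 = slice(max(-dy, 0), skel.shape[0] + min(-dy, 0))
        xs2 = slice(max(-dx, 0), skel.shape[1] + min(-dx, 0))
        shifted[ys, xs] = skel[ys2, xs2]
        both = skel & shifted
        src = index[both]
        dst = index[tuple((np.argwhere(both) - (dy, dx)).T)]
        rows.append(src)
        cols.append(dst)
        w.append(np.full(src.size, np.hypot(dy, dx)))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    w = np.concatenate(w)
    adj = sparse.csr_matrix((w, (rows, cols)), shape=(len(coords),) * 2)
    return coords, adj


def _longest_geodesic(coords: np.ndarray, adj: sparse.csr_matrix) -> np.ndarray:
    """Pixel path between the two most distant skeleton endpoints."""
    deg = np.asarray((adj > 0).sum(axis=1)).ravel()
    endpoints = np.flatnonzero(deg == 1)
    if endpoints.size < 2:
        # cycle or blob skeleton: fall back to the two most distant nodes
        # from an arbitrary start (double sweep)
        d0 = dijkstra(adj, indices=0)
        a = int(np.nanargmax(np.where(np.isinf(d0), np.nan, d0)))
        endpoints = np.array([a])
        da, pred = dijkstra(adj, indices=a, return_predecessors=True)
        b = int(np.nanargmax(np.where(np.isinf(da), np.nan, da)))
        return _walk_back(coords, pred, a, b)
    dist, preds = dijkstra(adj, indices=endpoints, return_predecessors=True)
    sub = dist[:, endpoints]
    sub[np.isinf(sub)] = -1.0
    i, j = np.unravel_index(np.argmax(sub), sub.shape)
    return _walk_back(coords, preds[i], endpoints[i], endpoints[j])


def _walk_back(coords, pred, start, end):
    path = [end]
    while path[-1] != start:
        nxt = pred[path[-1]]
        if nxt < 0:
            break
        path.append(int(nxt))
    return coords[np.array(path[::-1])]


def _mask_interp(mask: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(
        mask.astype(float), pts.T, order=1, mode="constant", cval=0.0
    )


def _extend_to_boundary(path: np.ndarray, mask: np.ndarray, k: int = 5) -> np.ndarray:
    """Extend both path ends to the mask boundary along the local tangent."""
    def extension(end, inner):
        d = end - inner
        n = np.linalg.norm(d)
        if n == 0:
            return np.empty((0, 2))
        d = d / n
        pts = []
        p = end.astype(float)
        for _ in range(200):
            p = p + 0.5 * d
            if (
                not (0 <= p[0] <= mask.shape[0] - 1 and 0 <= p[1] <= mask.shape[1] - 1)
                or _mask_interp(mask, p[None, :])[0] <= 0.5
            ):
                break
            pts.append(p.copy())
        return np.array(pts) if pts else np.empty((0, 2))

    k = min(k, len(path) - 1)
    head = extension(path[0].astype(float), path[k].astype(float))
    tail = extension(path[-1].astype(float), path[-1 - k].astype(float))
    parts = [head[::-1], path.astype(float), tail]
    return np.concatenate([p for p in parts if len(p)], axis=0)


def _trim_end_hooks(
    path: np.ndarray, width: float, max_angle_deg: float = 30.0
) -> np.ndarray:
    """Drop skeleton end segments that hook off the body axis.

    Blunt (flat-cut) mask ends give the classic rectangle-skeleton
    Y-branches: the geodesic path bends ~45° toward a corner over the last
    half body width.  Ends whose direction deviates from the adjacent
    segment by more than ``max_angle_deg`` are removed; smoothly curved
    worm tips turn far less over that distance and are left alone.
    """
    m = max(int(np.ceil(width / 2.0)), 3)
    if len(path) < 3 * m:
        return path

    def hooked(end_seg, inner_seg):
        d1 = end_seg[-1] - end_seg[0]
        d2 = inner_seg[-1] - inner_seg[0]
        n1, n2 = np.linalg.norm(d1), np.linalg.norm(d2)
        if n1 == 0 or n2 == 0:
            return False
        cosang = np.clip(d1 @ d2 / (n1 * n2), -1.0, 1.0)
        return np.degrees(np.arccos(cosang)) > max_angle_deg

    if hooked(path[:m][::-1], path[m: 2 * m][::-1]):
        path = path[m:]
    if hooked(path[-m:], path[-2 * m: -m]):
        path = path[:-m]
    return path


def _spline_resample(path: np.ndarray, smooth_per_pt: float = 0.5):
    """Smoothing-spline fit of a pixel path, resampled at 1-px arc steps."""
    with np.errstate(all="ignore"):
        tck, _ = splprep(path.T, s=smooth_per_pt * len(path), k=min(3, len(path) - 1))
    dense = np.stack(splev(np.linspace(0, 1, 8 * len(path)), tck), axis=1)
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    n = max(int(round(s[-1])) + 1, 2)
    s_new = np.linspace(0.0, s[-1], n)
    pts = np.stack(
        [np.interp(s_new, s, dense[:, 0]), np.interp(s_new, s, dense[:, 1])], axis=1
    )
    return pts, s_new


def _recenter(pts: np.ndarray, mask: np.ndarray, halfwidth: float) -> np.ndarray:
    """Move each midline point to the midpoint of its perpendicular chord.

    Only the contiguous run of mask samples around the current point is
    used, so chords never jump to body parts lying beyond a curved tip.
    """
    tang = np.gradient(pts, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    offs = np.arange(-halfwidth, halfwidth + 0.126, 0.25)
    ci = int(np.argmin(np.abs(offs)))
    out = pts.copy()
    for i in range(len(pts)):
        vals = _mask_interp(mask, pts[i][None, :] + offs[:, None] * normal[i][None, :]) > 0.5
        if not vals[ci]:
            continue
        lo = ci
        while lo > 0 and vals[lo - 1]:
            lo -= 1
        hi = ci
        while hi < offs.size - 1 and vals[hi + 1]:
            hi += 1
        out[i] = pts[i] + 0.5 * (offs[lo] + offs[hi]) * normal[i]
    return out


def extract_midline(mask: np.ndarray, min_elongation: float = 2.0) -> Midline:
    """Midline of a single-component worm mask.

    Skeletonizes the mask, takes the longest geodesic path between
    skeleton endpoints, extends both ends to the mask boundary along the
    local tangent, smooths with a spline and resamples at 1-px arc-length
    steps.

    Raises :class:`StraighteningError` for masks without a dominant
    elongated axis (path shorter than ``min_elongation`` × body width), as
    for coiled worms or compact blobs.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise StraighteningError("empty mask")
    n_comp = ndimage.label(mask, structure=np.ones((3, 3)))[1]
    if n_comp != 1:
        raise StraighteningError(f"mask has {n_comp} components")
    skel = skeletonize(mask)
    if skel.sum() < 2:
        raise StraighteningError("degenerate skeleton")
    coords, adj = _skeleton_graph(skel)
    path = _longest_geodesic(coords, adj)
    if len(path) < 4:
        raise StraighteningError("skeleton path too short")
    width = 2.0 * ndimage.distance_transform_edt(mask).max()
    path = _trim_end_hooks(path, width)
    path = _extend_to_boundary(path, mask)
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    if seg.sum() < min_elongation * width:
        raise StraighteningError(
            f"no elongated axis: path {seg.sum():.1f} px vs width {width:.1f} px"
        )
    pts, s_new = _spline_resample(path)
    # one chord-recentering pass pulls the smoothed path back onto the
    # body axis where the spline cut corners of strongly bent postures
    pts = _recenter(pts, mask, halfwidth=max(width / 2.0 + 2.0, 4.0))
    pts, s_new = _spline_resample(pts)
    inside = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] <= mask.shape[0] - 1)
        & (pts[:, 1] >= 0)
        & (pts[:, 1] <= mask.shape[1] - 1)
    )
    if not inside.all():  # smoothing may push blunt-cut ends off-frame
        first, last = np.argmax(inside), len(inside) - np.argmax(inside[::-1]) - 1
        pts = pts[first: last + 1]
        s_new = s_new[first: last + 1] - s_new[first]
    return Midline(points=pts, arc_length=s_new)


# ---------------------------------------------------------------------------
# straightening
# ---------------------------------------------------------------------------

def straighten(
    image: np.ndarray,
    mask: np.ndarray,
    midline: Midline,
    halfwidth: int | None = None,
    frame_index: int = -1,
    substep: float = 0.25,
) -> StraightenedWorm:
    """Resample the worm into a straightened frame along midline normals.

    For each arc-length row, intensity and mask are sampled at 1-px steps
    along the normal.  The width is measured with sub-pixel precision by
    integrating the bilinearly interpolated mask along the same normal at
    ``substep`` spacing, which removes most of the ±1 px quantization a
    hard sample count would carry into the squared-width volume integral.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    pts = midline.points
    if halfwidth is None:
        halfwidth = int(np.ceil(1.5 * ndimage.distance_transform_edt(mask).max())) + 3

    tang = np.gradient(pts, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)

    offsets = np.arange(-halfwidth, halfwidth + 1, dtype=float)
    coords = pts[:, None, :] + offsets[None, :, None] * normal[:, None, :]
    flat = coords.reshape(-1, 2).T
    img_rows = ndimage.map_coordinates(image, flat, order=1, mode="constant", cval=0.0)
    msk_rows = ndimage.map_coordinates(mask.astype(float), flat, order=1, mode="constant", cval=0.0)
    img_rows = img_rows.reshape(len(pts), offsets.size)
    msk_rows = msk_rows.reshape(len(pts), offsets.size) > 0.5

    fine = np.arange(-halfwidth, halfwidth + substep / 2, substep)
    fco = pts[:, None, :] + fine[None, :, None] * normal[:, None, :]
    fmask = ndimage.map_coordinates(
        mask.astype(float), fco.reshape(-1, 2).T, order=1, mode="constant", cval=0.0
    ).reshape(len(pts), fine.size)
    width = fmask.sum(axis=1) * substep

    in_bounds = (
        (coords[..., 0] >= 0)
        & (coords[..., 0] <= image.shape[0] - 1)
        & (coords[..., 1] >= 0)
        & (coords[..., 1] <= image.shape[1] - 1)
    )
    truncated = int(np.sum(~in_bounds.all(axis=1)))

    return StraightenedWorm(
        image=img_rows,
        mask_rows=msk_rows,
        width=width,
        length=midline.length,
        frame_index=frame_index,
        truncated_rows=truncated,
    )


def estimate_volume(straightened: StraightenedWorm, pixel_size_um: float = 1.0) -> float:
    """Rotational-symmetry volume V = Σ π (w_i/2)² Δs · pixel_size³ (µm³)."""
    w = np.asarray(straightened.width, dtype=float)
    if w.size == 0:
        return float("nan")
    ds = np.gradient(np.arange(w.size, dtype=float))  # 1 px rows
    return float(np.sum(np.pi * (w / 2.0) ** 2 * ds) * pixel_size_um**3)


# ---------------------------------------------------------------------------
# fluorescence
# ---------------------------------------------------------------------------

def estimate_background(image: np.ndarray, mask: np.ndarray, dilate_px: int = 10) -> float:
    """Median intensity outside the mask dilated by ``dilate_px``."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if dilate_px > 0:
        dilated = ndimage.binary_dilation(mask, ndimage.generate_binary_structure(2, 2), iterations=dilate_px)
    else:
        dilated = mask
    outside = ~dilated
    if not outside.any():
        raise ValueError("mask (after dilation) covers the whole frame")
    return float(np.median(image[outside]))


def measure_fluorescence(image: np.ndarray, mask: np.ndarray, background: float) -> FluorMeasure:
    """Total background-subtracted fluorescence and per-pixel concentration."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        return FluorMeasure(float("nan"), 0, float("nan"), background)
    total = float(np.sum(image[mask] - background))
    return FluorMeasure(
        total=total,
        area=area,
        concentration=total / area,
        background=float(background),
        negative_total=total < 0,
    )


def quantify_roi(
    image: np.ndarray,
    roi_mask: np.ndarray,
    exclusion_mask: np.ndarray | None = None,
    background: float = 0.0,
) -> float:
    """Per-pixel background-subtracted intensity of an ROI.

    Excluded pixels (e.g. manually marked nuclei) are removed from the ROI
    before summing; returns NaN for an empty effective ROI.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if exclusion_mask is not None:
        roi = roi & ~np.asarray(exclusion_mask, dtype=bool)
    n = int(roi.sum())
    if n == 0:
        return float("nan")
    return float(np.sum(np.asarray(image, dtype=float)[roi] - background) / n)
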