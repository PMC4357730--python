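"""Height-map processing: flattening, backbone tracing, complex detection
and particle volume measurement.

This is the automated counterpart of measuring AFM topographs by hand:
scan lines are flattened with low-order polynomial background fits, DNA
fragments are traced as ordered backbone polylines via skeletonisation,
protein-DNA complexes are picked as local height maxima riding on a traced
backbone, and particle volumes are integrated above a local background.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy import ndimage
from skimage.morphology import skeletonize

from .errors import InvalidParameterError, UnmeasurableComplexError
from .geometry import ComplexRecord, PolylineTrace, arc_coordinates, \
    position_fraction, resample_polyline
from .render import HeightMap

#: complexes farther than this from any backbone are not assigned, nm
DEFAULT_CAPTURE_DISTANCE = 5.0
#: integration mask radius for particle volumes, nm (~protein footprint)
DEFAULT_MASK_RADIUS = 10.0
#: minimum absolute rise of the detection threshold above background, nm
_THRESHOLD_FLOOR = 0.1


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def background_threshold(heights: np.ndarray) -> float:
    """Robust foreground threshold: median + max(3 * 1.4826 * MAD, floor)."""
    med = float(np.median(heights))
    return med + max(3.0 * 1.4826 * _mad(heights), _THRESHOLD_FLOOR)


def flatten(image: HeightMap, order: int = 3) -> HeightMap:
    """Per-scanline polynomial background subtraction (order 0-3).

    Each row is fit twice: a first fit over all pixels, then a refit
    restricted to background pixels (residuals below a robust threshold)
    so DNA and protein features do not drag the background estimate.
    """
    if order not in (0, 1, 2, 3):
        raise InvalidParameterError("flatten order must be 0..3")
    h = image.heights.copy()
    x = np.arange(h.shape[1], dtype=float)
    for r in range(h.shape[0]):
        row = h[r]
        coef = np.polyfit(x, row, order)
        resid = row - np.polyval(coef, x)
        cut = np.median(resid) + max(3.0 * 1.4826 * _mad(resid), 1e-12)
        mask = resid <= cut
        if mask.sum() > order + 1:
            coef = np.polyfit(x[mask], row[mask], order)
        h[r] = row - np.polyval(coef, x)
    # anchor the global background at zero
    h -= np.median(h[h <= background_threshold(h)])
    return HeightMap(h, image.pixel_size)


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pix = set(zip(rows.tolist(), cols.tolist()))
    for r, c in pix:
        g.add_node((r, c))
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) == (0, 0):
                    continue
                q = (r + dr, c + dc)
                if q in pix:
                    g.add_edge((r, c), q, weight=float(np.hypot(dr, dc)))
    return g


def _longest_endpoint_path(g: nx.Graph) -> list[tuple[int, int]] | None:
    """Backbone = geodesically farthest endpoint pair (prunes side branches)."""
    endpoints = [n for n in g if g.degree(n) == 1]
    if not endpoints:
        return None
    # double sweep: farthest node from an arbitrary endpoint, then farthest
    # endpoint from that one — exact on trees, which pruned skeletons are
    start = endpoints[0]
    dist = nx.single_source_dijkstra_path_length(g, start)
    a = max((n for n in endpoints), key=lambda n: (dist.get(n, -1), -n[0], -n[1]))
    dist_a, paths_a = nx.single_source_dijkstra(g, a)
    b = max((n for n in endpoints), key=lambda n: (dist_a.get(n, -1), -n[0], -n[1]))
    return paths_a[b]


def _smooth_path(path_nm: np.ndarray, window: int = 3) -> np.ndarray:
    """Moving-average smoothing removes pixel-quantisation zigzag, which
    otherwise inflates contour lengths by several percent."""
    if len(path_nm) <= window:
        return path_nm
    kernel = np.ones(window) / window
    pad = window // 2
    out = np.empty_like(path_nm)
    for d in range(2):
        col = np.pad(path_nm[:, d], pad, mode="edge")
        out[:, d] = np.convolve(col, kernel, mode="valid")
    # keep the true endpoints so fragment length is not shortened
    out[0], out[-1] = path_nm[0], path_nm[-1]
    return out


def trace_backbones(
    image: HeightMap,
    threshold: float | None = None,
    min_size_px: int = 12,
) -> list[PolylineTrace]:
    """Trace DNA fragments on a flattened height map as ordered polylines.

    Threshold -> binary mask -> skeleton -> walk between the geodesically
    farthest endpoint pair (side branches pruned) -> smoothed polyline per
    fragment.  Fragments touching the image margin are flagged
    ``excluded``; cyclic skeletons (no endpoints) are flagged
    ``unresolvable``.  No fragments found returns an empty list.
    """
    h = image.heights
    thr = background_threshold(h) if threshold is None else threshold
    mask = h > thr
    labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3), int))
    if n_lab:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_size_px)
        mask &= ~np.isin(labels, small[small > 0])
        labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3), int))
    traces: list[PolylineTrace] = []
    px = image.pixel_size
    for lab in range(1, n_lab + 1):
        comp = labels == lab
        touches_margin = bool(
            comp[0].any() or comp[-1].any() or comp[:, 0].any() or comp[:, -1].any())
        skel = skeletonize(comp)
        if skel.sum() < 2:
            continue
        g = _skeleton_graph(skel)
        path = _longest_endpoint_path(g)
        fid = len(traces)
        if path is None:  # cyclic skeleton
            rows, cols = np.nonzero(skel)
            pts = np.column_stack([cols, rows]).astype(float) * px
            traces.append(PolylineTrace(fid, pts, excluded=touches_margin,
                                        unresolvable=True))
            continue
        pts = np.array([[c * px, r * px] for r, c in path], float)
        pts = _smooth_path(pts)
        traces.append(PolylineTrace(fid, pts, excluded=touches_margin))
    return traces


def detect_complexes(
    image: HeightMap,
    traces: list[PolylineTrace],
    ridge_height: float | None = None,
    margin: float = 0.3,
    capture_distance: float = DEFAULT_CAPTURE_DISTANCE,
    min_separation_nm: float = 6.0,
) -> list[ComplexRecord]:
    """Locate protein-DNA complexes as height maxima on traced backbones.

    Local maxima exceeding the DNA ridge height by ``margin`` nm and lying
    within ``capture_distance`` nm of a backbone polyline become complex
    records anchored at the nearest arc position.  The ridge height
    defaults to the median image height sampled along the traces.
    """
    h = image.heights
    px = image.pixel_size
    if not traces:
        return []
    dense = {}
    for t in traces:
        pts = resample_polyline(t.points, px / 2.0)
        arc = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        dense[t.fragment_id] = (pts, arc, t)
    if ridge_height is None:
        samples = []
        for pts, _, _ in dense.values():
            rr = np.clip((pts[:, 1] / px).round().astype(int), 0, h.shape[0] - 1)
            cc = np.clip((pts[:, 0] / px).round().astype(int), 0, h.shape[1] - 1)
            samples.append(h[rr, cc])
        ridge_height = float(np.median(np.concatenate(samples)))

    thr = ridge_height + margin
    min_dist_px = max(int(round(min_separation_nm / px)), 1)
    footprint = np.ones((2 * min_dist_px + 1,) * 2, bool)
    local_max = (h == ndimage.maximum_filter(h, footprint=footprint)) & (h > thr)
    peaks = np.argwhere(local_max)

    records: list[ComplexRecord] = []
    for r, c in peaks:
        x, y = c * px, r * px
        best = None
        for fid, (pts, arc, t) in dense.items():
            d = np.hypot(pts[:, 0] - x, pts[:, 1] - y)
            i = int(np.argmin(d))
            if best is None or d[i] < best[0]:
                best = (float(d[i]), fid, float(arc[i]), t)
        dist, fid, s, t = best
        if dist > capture_distance:
            continue
        rec = ComplexRecord(fragment_id=fid, s_nm=s, excluded=t.excluded)
        try:
            rec.position_fraction = position_fraction(t, s)
        except Exception:
            rec.excluded = True
        records.append(rec)
    return records


def measure_volume(
    image: HeightMap,
    x_nm: float,
    y_nm: float,
    mask_radius: float = DEFAULT_MASK_RADIUS,
    annulus_width: float = 6.0,
) -> float:
    """Integrated particle volume (nm^3) above a local background.

    Sums (height - background) * pixel area over a disc of
    ``mask_radius``; the background is the median height in an annulus
    immediately outside the disc.  A mask clipped by the image margin
    raises :class:`UnmeasurableComplexError` (the complex is excluded).
    """
    h = image.heights
    px = image.pixel_size
    r_out = mask_radius + annulus_width
    r0 = y_nm / px
    c0 = x_nm / px
    r_out_px = r_out / px
    if (r0 - r_out_px < -0.5 or c0 - r_out_px < -0.5
            or r0 + r_out_px > h.shape[0] - 0.5
            or c0 + r_out_px > h.shape[1] - 0.5):
        raise UnmeasurableComplexError(
            "volume mask clipped by the image margin")
    rr, cc = np.mgrid[0:h.shape[0], 0:h.shape[1]]
    d = np.hypot(rr - r0, cc - c0) * px
    mask = d <= mask_radius
    annulus = (d > mask_radius) & (d <= r_out)
    background = float(np.median(h[annulus]))
    return float(((h[mask] - background) * px * px).sum())
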