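"""Render synthetic AFM height maps from simulated fragments.

DNA appears as a ridge with Gaussian cross-section (~0.5 nm tall, sigma
~2 nm, matching dried dsDNA on mica); a bound protein is a rotationally
symmetric Gaussian bump whose integrated volume equals the sampled AFM
volume.  Heights compose by maximum (a tip cannot report two stacked
surfaces), the image is broadened by grayscale dilation with a spherical
tip, and additive pixel noise is applied last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import PlacementError
from .geometry import PolylineTrace, arc_coordinates, resample_polyline


@dataclass
class HeightMap:
    """Raster of surface heights (nm) on a square-pixel grid."""

    heights: np.ndarray  # (rows, cols), nm
    pixel_size: float  # nm

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class RenderParams:
    """Raster geometry of the synthetic AFM surface (all nm)."""

    pixel_size: float = 2.0  # matches ~2 nm pixel resolution of the scans
    dna_height: float = 0.5
    dna_sigma: float = 2.0
    protein_sigma: float = 2.5
    tip_radius: float = 2.0
    noise_sd: float = 0.05
    clearance: float = 20.0  # min spacing between placed fragments
    max_retries: int = 200


def _stamp_gaussian_max(img: np.ndarray, row: float, col: float,
                        amplitude: float, sigma_px: float) -> None:
    """Compose a Gaussian bump into the image by pixel-wise maximum."""
    r_ext = int(np.ceil(4 * sigma_px))
    r0 = max(int(np.floor(row)) - r_ext, 0)
    r1 = min(int(np.ceil(row)) + r_ext + 1, img.shape[0])
    c0 = max(int(np.floor(col)) - r_ext, 0)
    c1 = min(int(np.ceil(col)) + r_ext + 1, img.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d2 = (rr - row) ** 2 + (cc - col) ** 2
    patch = amplitude * np.exp(-d2 / (2.0 * sigma_px ** 2))
    np.maximum(img[r0:r1, c0:c1], patch, out=img[r0:r1, c0:c1])


def _spherical_tip(radius_nm: float, pixel_size: float) -> np.ndarray:
    """Structuring function for grayscale dilation by a spherical tip apex."""
    r_px = max(int(np.ceil(radius_nm / pixel_size)), 1)
    ax = np.arange(-r_px, r_px + 1) * pixel_size
    d2 = ax[:, None] ** 2 + ax[None, :] ** 2
    h = np.where(d2 <= radius_nm ** 2,
                 np.sqrt(np.maximum(radius_nm ** 2 - d2, 0.0)) - radius_nm,
                 -np.inf)
    return h


def render_fragments(
    traces: list[PolylineTrace],
    complexes: list[tuple[int, float, float]] | None = None,
    params: RenderParams | None = None,
    rng: np.random.Generator | int | None = None,
    place: bool = True,
    image_shape: tuple[int, int] | None = None,
) -> tuple[HeightMap, dict[int, np.ndarray]]:
    """Render fragments (and their bound proteins) onto one height map.

    ``complexes`` lists (fragment_id, arc_position_nm, volume_nm3); the
    protein bump amplitude is chosen so its analytic integral equals the
    requested volume.  With ``place=True`` each fragment is randomly
    translated/rotated onto the canvas with a clearance between bounding
    boxes; exceeding the retry budget raises :class:`PlacementError`.

    Returns the height map and the placed (nm) coordinates per fragment,
    which serve as rendering ground truth for the tracer.
    """
    p = params or RenderParams()
    rng = np.random.default_rng(rng)
    complexes = complexes or []
    px = p.pixel_size

    placed: dict[int, np.ndarray] = {}
    if place:
        spans = []
        for t in traces:
            pts = t.points - t.points.mean(axis=0)
            spans.append(np.linalg.norm(pts, axis=1).max())
        if image_shape is None:
            # canvas sized so the expected packing stays sparse
            area = sum((2 * s + 2 * p.clearance) ** 2 for s in spans) * 3.0
            side_nm = max(np.sqrt(area), 4 * (max(spans) + p.clearance))
            n_px = int(np.ceil(side_nm / px))
            image_shape = (n_px, n_px)
        boxes: list[tuple[float, float, float]] = []  # (x, y, radius)
        for t, span in zip(traces, spans):
            pts = t.points - t.points.mean(axis=0)
            ok = False
            for _ in range(p.max_retries):
                ang = rng.uniform(0, 2 * np.pi)
                c, s = np.cos(ang), np.sin(ang)
                rot = pts @ np.array([[c, -s], [s, c]]).T
                lim_x = image_shape[1] * px
                lim_y = image_shape[0] * px
                margin = span + p.clearance
                if lim_x <= 2 * margin or lim_y <= 2 * margin:
                    break
                cx = rng.uniform(margin, lim_x - margin)
                cy = rng.uniform(margin, lim_y - margin)
                if all(np.hypot(cx - bx, cy - by) > span + br + p.clearance
                       for bx, by, br in boxes):
                    placed[t.fragment_id] = rot + [cx, cy]
                    boxes.append((cx, cy, span))
                    ok = True
                    break
            if not ok:
                raise PlacementError(
                    f"could not place fragment {t.fragment_id}",
                    fragment_index=t.fragment_id)
    else:
        for t in traces:
            placed[t.fragment_id] = t.points.copy()
        if image_shape is None:
            allpts = np.vstack(list(placed.values()))
            pad = 12 * p.dna_sigma
            shift = allpts.min(axis=0) - pad
            for fid in placed:
                placed[fid] = placed[fid] - shift
            allpts = np.vstack(list(placed.values()))
            image_shape = (int(np.ceil((allpts[:, 1].max() + pad) / px)),
                           int(np.ceil((allpts[:, 0].max() + pad) / px)))

    img = np.zeros(image_shape, dtype=float)
    sigma_px = p.dna_sigma / px
    for fid, pts in placed.items():
        dense = resample_polyline(pts, px / 2.0)
        for x, y in dense:
            _stamp_gaussian_max(img, y / px, x / px, p.dna_height, sigma_px)

    prot_sigma_px = p.protein_sigma / px
    for fid, s_nm, volume in complexes:
        if fid not in placed:
            continue
        pts = placed[fid]
        arc = arc_coordinates(PolylineTrace(fid, pts))
        x = np.interp(s_nm, arc, pts[:, 0])
        y = np.interp(s_nm, arc, pts[:, 1])
        # Gaussian bump integral = H * 2 pi sigma^2
        amplitude = max(volume, 0.0) / (2.0 * np.pi * p.protein_sigma ** 2)
        _stamp_gaussian_max(img, y / px, x / px, amplitude, prot_sigma_px)

    if p.tip_radius > 0:
        tip = _spherical_tip(p.tip_radius, px)
        img = ndimage.grey_dilation(img, structure=tip, mode="nearest")
    if p.noise_sd > 0:
        img = img + rng.normal(0.0, p.noise_sd, size=img.shape)
    return HeightMap(img, px), placed
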