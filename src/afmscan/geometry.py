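"""Per-complex geometric measurements on traced DNA backbones.

A traced DNA fragment is an ordered 2-D polyline in nanometres.  The
measurements here mirror what is done manually on AFM topographs: contour
length along the backbone, fractional binding position (distance to the
closer fragment end over full length), DNA bend angle at a bound or probed
site, and conversion of measured AFM particle volumes to approximate
molecular weight through the empirical calibration ``MW = (V + 5.9) / 1.2``.

The bend angle beta is defined as the deviation of the backbone from a
straight line: a tangent line is fit to each DNA arm flanking the site
(skipping an exclusion zone that covers the protein footprint) and

    beta = 180 - alpha

where alpha is the angle enclosed by the two arm lines at the site, so a
straight backbone gives beta = 0 and a hairpin gives beta -> 180.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InvalidInputError,
    InvalidParameterError,
    InvalidTraceError,
    UnmeasurableComplexError,
)

#: default half-size of the region around a bound protein that is excluded
#: from tangent fitting, nm (protein footprint ~10 nm across)
DEFAULT_EXCLUSION_RADIUS = 5.0
#: default arc length of backbone used to fit each arm tangent, nm
DEFAULT_ARM_WINDOW = 10.0


@dataclass
class PolylineTrace:
    """Ordered 2-D backbone points (nm) for one DNA fragment."""

    fragment_id: int
    points: np.ndarray  # (n, 2) float array, nm
    excluded: bool = False  # e.g. touches the image margin
    unresolvable: bool = False  # e.g. cyclic skeleton

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InvalidTraceError("trace points must be an (n, 2) array")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        return contour_length(self)


@dataclass
class ComplexRecord:
    """One protein-DNA complex located on a traced fragment."""

    fragment_id: int
    s_nm: float  # arc position along the backbone
    position_fraction: float = np.nan  # % of length, in [0, 50]
    bend_angle_deg: float = np.nan  # beta, in [0, 180]
    volume_nm3: float = np.nan
    mw_kda: float = np.nan
    end_bound: bool = False
    neighbor_excluded: bool = False
    specific: bool = False
    excluded: bool = False
    experiment: int = 0


def records_to_frame(records: Sequence[ComplexRecord]) -> pd.DataFrame:
    """Tabulate complex records (one row per complex)."""
    cols = [
        "fragment_id", "s_nm", "position_fraction", "bend_angle_deg",
        "volume_nm3", "mw_kda", "end_bound", "neighbor_excluded",
        "specific", "excluded", "experiment",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records],
                        columns=cols)


def contour_length(trace: PolylineTrace | np.ndarray) -> float:
    """Contour length of a backbone polyline: sum of segment lengths, nm."""
    pts = trace.points if isinstance(trace, PolylineTrace) else np.asarray(trace, float)
    if len(pts) < 2:
        raise InvalidTraceError("contour length needs at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def arc_coordinates(trace: PolylineTrace) -> np.ndarray:
    """Cumulative arc length at each polyline vertex, starting at 0."""
    seg = np.linalg.norm(np.diff(trace.points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def position_fraction(trace: PolylineTrace, s: float) -> float:
    """Binding position as % of fragment length, folded to the closer end.

    Returns ``100 * min(s, L - s) / L`` in [0, 50].
    """
    L = contour_length(trace)
    if not (0.0 <= s <= L * (1 + 1e-9)):
        raise InvalidParameterError(
            f"arc position s={s} outside [0, {L}] for fragment "
            f"{trace.fragment_id}")
    s = min(s, L)
    return 100.0 * min(s, L - s) / L


def resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing (endpoint kept)."""
    pts = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(int(np.ceil(total / spacing)), 1)
    s_new = np.linspace(0.0, total, n + 1)
    x = np.interp(s_new, arc, pts[:, 0])
    y = np.interp(s_new, arc, pts[:, 1])
    return np.column_stack([x, y])


def _fit_arm_direction(pts: np.ndarray, vertex: np.ndarray) -> np.ndarray:
    """Total-least-squares line through arm points, oriented away from vertex."""
    centered = pts - pts.mean(axis=0)
    # first right-singular vector = TLS direction
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    # orient from the point nearest the vertex toward the farthest one
    dist = np.linalg.norm(pts - vertex, axis=1)
    away = pts[np.argmax(dist)] - pts[np.argmin(dist)]
    if np.dot(d, away) < 0:
        d = -d
    return d / np.linalg.norm(d)


def bend_angle(
    trace: PolylineTrace,
    s: float,
    exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS,
    arm_window: float = DEFAULT_ARM_WINDOW,
) -> float:
    """DNA bend angle beta (deg) at arc position ``s``.

    A straight line is fit (total least squares) to each backbone arm over
    ``arm_window`` nm of contour starting ``exclusion_radius`` nm away from
    ``s`` on either side; beta = 180 - alpha where alpha is the angle the
    two arm lines enclose at the site.

    Raises
    ------
    UnmeasurableComplexError
        if either arm has less than ``exclusion_radius + arm_window / 2``
        of contour available.
    """
    if exclusion_radius < 0 or arm_window <= 0:
        raise InvalidParameterError("exclusion_radius >= 0 and arm_window > 0 required")
    L = contour_length(trace)
    min_reach = exclusion_radius + arm_window / 2.0
    if s < min_reach or L - s < min_reach:
        raise UnmeasurableComplexError(
            f"arms too short at s={s:.1f} on fragment {trace.fragment_id} "
            f"(need {min_reach:.1f} nm each side of contour {L:.1f} nm)")

    # dense resampling so short windows always contain enough support points
    spacing = min(arm_window / 10.0, 1.0)
    pts = resample_polyline(trace.points, spacing)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    # nearest resampled point to the site; ties broken toward lower arc position
    vertex = pts[int(np.argmin(np.abs(arc - s)))]

    left = (arc >= s - exclusion_radius - arm_window) & (arc <= s - exclusion_radius)
    right = (arc >= s + exclusion_radius) & (arc <= s + exclusion_radius + arm_window)
    if left.sum() < 2 or right.sum() < 2:
        raise UnmeasurableComplexError(
            f"insufficient arm support at s={s:.1f} on fragment {trace.fragment_id}")

    u = _fit_arm_direction(pts[left], vertex)
    v = _fit_arm_direction(pts[right], vertex)
    alpha = np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0)))
    beta = 180.0 - alpha
    return float(np.clip(beta, 0.0, 180.0))


def volume_to_mw(volume_nm3: float) -> float:
    """Convert an AFM particle volume (nm^3) to molecular weight (kDa).

    Uses the empirical linear calibration MW = (V + 5.9) / 1.2 obtained from
    reference proteins of known molecular weight.
    """
    v = np.asarray(volume_nm3, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InvalidParameterError("volume must be finite")
    out = (v + 5.9) / 1.2
    return float(out) if out.ndim == 0 else out


def fit_length_distribution(lengths: Sequence[float]) -> tuple[float, float]:
    """Gaussian fit (MLE) to a set of measured contour lengths -> (center, sd)."""
    lengths = np.asarray(lengths, float)
    if lengths.size < 2:
        raise InvalidInputError("need at least 2 lengths to fit a distribution")
    center, sd = stats.norm.fit(lengths)
    return float(center), float(sd)


def flag_filters(
    records: Sequence[ComplexRecord],
    traces: Sequence[PolylineTrace],
    length_fit: tuple[float, float] | None = None,
    end_zone_pct: float = 5.0,
    neighbor_min_nm: float = 50.0,
) -> list[ComplexRecord]:
    """Apply the standard inclusion filters to a set of complexes.

    * complexes on fragments whose contour length lies outside
      ``center +/- 2 sd`` of a Gaussian fit to the fragment-length
      distribution are dropped (``length_fit`` may be supplied, e.g.
      (165, 24) nm, or is computed from the trace set);
    * ``end_bound`` is set where the fractional position is below
      ``end_zone_pct`` (DNA-end binders, excluded from specificity fits);
    * ``neighbor_excluded`` is set where another complex sits within
      ``neighbor_min_nm`` of arc length on the same fragment (bend angles
      of crowded complexes are constrained and not used).
    """
    lengths = {t.fragment_id: contour_length(t) for t in traces}
    if length_fit is None:
        length_fit = fit_length_distribution(list(lengths.values()))
    center, sd = length_fit
    lo, hi = center - 2 * sd, center + 2 * sd

    out: list[ComplexRecord] = []
    by_fragment: dict[tuple[int, int], list[ComplexRecord]] = {}
    for r in records:
        L = lengths.get(r.fragment_id)
        if L is None or not (lo <= L <= hi):
            continue
        r = replace(r, end_bound=bool(r.position_fraction < end_zone_pct))
        out.append(r)
        by_fragment.setdefault((r.experiment, r.fragment_id), []).append(r)

    for group in by_fragment.values():
        if len(group) < 2:
            continue
        for a in group:
            if any(b is not a and abs(b.s_nm - a.s_nm) < neighbor_min_nm
                   for b in group):
                a.neighbor_excluded = True
    return out


def intrinsic_bend_scan(
    trace: PolylineTrace,
    interval: float = 50.0,
    mask_radius: float = 10.0,
    arm_window: float = DEFAULT_ARM_WINDOW,
    site_fraction: float | None = None,
) -> list[tuple[float, float]]:
    """Measure intrinsic DNA bending along a protein-free fragment.

    Emulates moving a protein-sized mask along the backbone: the bend angle
    is evaluated with the mask radius as the tangent exclusion zone either
    at regular ``interval`` nm positions (scan mode) or at the single site
    position ``site_fraction * L`` (site mode, e.g. 0.46 for a lesion at
    46% of fragment length).  Positions whose arms would leave the fragment
    are skipped.
    """
    L = contour_length(trace)
    margin = mask_radius + arm_window
    if site_fraction is not None:
        positions = [site_fraction * L]
    else:
        positions = list(np.arange(interval, L, interval))
    out = []
    for s in positions:
        if s < margin or L - s < margin:
            continue
        try:
            beta = bend_angle(trace, s, exclusion_radius=mask_radius,
                              arm_window=arm_window)
        except UnmeasurableComplexError:
            continue
        out.append((float(s), beta))
    return out
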