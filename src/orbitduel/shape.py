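"""Shape analytics for closed perceived paths.

Quantifies the observable signatures of a predicted percept: radial
lobe count (ellipse = 2, triangle = 3, five-point star = 5), principal-
axis aspect ratio and orientation, self-intersection count (the corner
loops of inducer-pursuit percepts), and whether the sides between lobes
bulge outward (convex), inward (concave) or run straight.

All metrics expect a closed path sampled uniformly over exactly one
repeat period with the endpoint excluded (half-open sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import find_peaks

from .kinematics import Trajectory

__all__ = [
    "ShapeMetrics",
    "lobe_count",
    "aspect_ratio",
    "self_intersections",
    "side_class",
    "analyze_shape",
]

#: Radial prominence (fraction of mean radius) below which a local
#: maximum is floating-point ripple, not a lobe.
LOBE_PROMINENCE_FRAC = 0.01
#: |chord deviation| below this fraction of mean radius counts as straight.
STRAIGHT_FRAC = 0.005


@dataclass(frozen=True)
class ShapeMetrics:
    """Summary descriptors of one closed path."""

    lobe_count: int
    aspect_ratio: float
    major_axis_deg: float
    n_self_intersections: int
    side_class: str
    mean_radius: float

    def to_dict(self) -> dict:
        return asdict(self)


def _points(path) -> np.ndarray:
    if isinstance(path, Trajectory):
        return np.asarray(path.xy, dtype=float)
    pts = np.asarray(path, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("path must be a Trajectory or an (n, 2) array")
    return pts


def _check_closed(pts: np.ndarray) -> None:
    """A half-open periodic sampling closes onto itself: the gap between
    the last and first samples must be comparable to the sample spacing."""
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    gap = np.linalg.norm(pts[0] - pts[-1])
    if steps.size and gap > 5.0 * max(np.median(steps), 1e-30):
        raise ValueError("path is not closed (not sampled over one full period)")


def _radii(pts: np.ndarray) -> tuple[np.ndarray, float]:
    r = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    return r, float(r.mean())


def _lobe_peaks(pts: np.ndarray, prominence_frac: float) -> np.ndarray:
    """Indices of cyclic local maxima of centroid distance."""
    r, mean_r = _radii(pts)
    if mean_r == 0:
        return np.array([], dtype=int)
    n = r.size
    tiled = np.concatenate([r, r, r])
    peaks, _ = find_peaks(tiled, prominence=prominence_frac * mean_r)
    mid = peaks[(peaks >= n) & (peaks < 2 * n)] - n
    return np.sort(mid)


def lobe_count(path, prominence_frac: float = LOBE_PROMINENCE_FRAC) -> int:
    """Number of radial lobes of a closed path.

    A lobe is a strict cyclic local maximum of the distance to the
    centroid with prominence at least ``prominence_frac`` of the mean
    radius; a constant-radius path (circle) has none.
    """
    pts = _points(path)
    if pts.shape[0] < 8:
        raise ValueError("need at least 8 samples to count lobes")
    _check_closed(pts)
    return int(_lobe_peaks(pts, prominence_frac).size)


def aspect_ratio(path, collinear_tol: float = 1e-12) -> tuple[float, float]:
    """Principal-axis aspect ratio and major-axis orientation of a path.

    Uses the second central moments of the samples (uniform-in-time
    sampling of an axis-aligned ellipse ``(A sin wt, B cos wt)`` yields
    exactly A/B).  Returns ``(sqrt(l_major / l_minor), angle_deg)`` with
    the angle in [0, 180) from horizontal; a circle reports (1, 0) by
    convention and a collinear path reports ``inf`` with the line's
    orientation.
    """
    pts = _points(path)
    centered = pts - pts.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise ValueError("degenerate path: all samples coincide")
    cov = centered.T @ centered / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    l_minor, l_major = float(evals[0]), float(evals[1])
    v = evecs[:, 1]
    angle = float(np.degrees(np.arctan2(v[1], v[0]))) % 180.0
    if l_minor <= collinear_tol * l_major:
        return float("inf"), angle
    ar = float(np.sqrt(l_major / l_minor))
    if abs(ar - 1.0) < 1e-9:
        return 1.0, 0.0
    return ar, angle


def _segment_crossings(pts: np.ndarray) -> np.ndarray:
    """Proper (transversal) crossing points between non-adjacent segments
    of the closed polyline through ``pts``.  O(n^2), blocked over rows to
    bound memory."""
    n = pts.shape[0]
    p1 = pts
    p2 = np.roll(pts, -1, axis=0)
    d = p2 - p1
    out = []
    for i in range(n - 2):
        # segments j > i + 1, excluding the wrap-adjacent pair (0, n-1)
        j0 = i + 2
        j1 = n if i > 0 else n - 1
        if j0 >= j1:
            continue
        a1, da = p1[i], d[i]
        b1 = p1[j0:j1]
        db = d[j0:j1]
        denom = da[0] * db[:, 1] - da[1] * db[:, 0]
        r = b1 - a1
        t_num = r[:, 0] * db[:, 1] - r[:, 1] * db[:, 0]
        u_num = r[:, 0] * da[1] - r[:, 1] * da[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = t_num / denom
            u = u_num / denom
        ok = (denom != 0) & (t > 0) & (t < 1) & (u > 0) & (u < 1)
        if np.any(ok):
            out.append(a1 + t[ok, None] * da)
    if not out:
        return np.empty((0, 2))
    return np.vstack(out)


def self_intersections(path, dedup_tol_frac: float = 1e-9) -> int:
    """Count transversal self-crossings of a closed sampled path.

    Crossings of distinct segment pairs that land on the same geometric
    point (within ``dedup_tol_frac`` of the mean radius) are counted
    once.  Collinear retracing (a degenerate segment-shaped path) does
    not count: only proper crossings do.
    """
    pts = _points(path)
    _check_closed(pts)
    crossings = _segment_crossings(pts)
    if crossings.shape[0] == 0:
        return 0
    _, mean_r = _radii(pts)
    tol = dedup_tol_frac * max(mean_r, 1e-30)
    kept: list[np.ndarray] = []
    for c in crossings:
        if not any(np.linalg.norm(c - k) <= tol for k in kept):
            kept.append(c)
    return len(kept)


def side_class(path, lobes: int | None = None,
               straight_frac: float = STRAIGHT_FRAC,
               prominence_frac: float = LOBE_PROMINENCE_FRAC) -> str:
    """Classify the sides between consecutive lobes of a closed path.

    The path is split at its lobe maxima; each side's midpoint is
    compared with the chord joining the side's endpoints.  Deviation
    away from the centroid means the side bulges outward (convex),
    toward it concave, and |deviation| below ``straight_frac`` of the
    mean radius counts as straight.  Sides that disagree give "mixed".
    Requires at least 3 lobes (an ellipse has no sides to classify).
    """
    pts = _points(path)
    _check_closed(pts)
    peaks = _lobe_peaks(pts, prominence_frac)
    if lobes is not None and lobes != peaks.size:
        raise ValueError(f"stated lobe count {lobes} != detected {peaks.size}")
    if peaks.size < 3:
        raise ValueError(f"side classification needs >= 3 lobes, found {peaks.size}")
    n = pts.shape[0]
    centroid = pts.mean(axis=0)
    _, mean_r = _radii(pts)
    classes = []
    for a, b in zip(peaks, np.roll(peaks, -1)):
        length = (b - a) % n
        mid = pts[(a + length // 2) % n]
        pa, pb = pts[a], pts[b % n]
        chord = pb - pa
        norm = np.linalg.norm(chord)
        if norm == 0:
            continue
        nhat = np.array([-chord[1], chord[0]]) / norm
        # orient the normal away from the centroid
        if nhat @ ((pa + pb) / 2 - centroid) < 0:
            nhat = -nhat
        dev = float((mid - pa) @ nhat)
        if abs(dev) < straight_frac * mean_r:
            classes.append("straight")
        elif dev > 0:
            classes.append("convex")
        else:
            classes.append("concave")
    uniq = set(classes)
    return classes[0] if len(uniq) == 1 else "mixed"


def analyze_shape(path) -> ShapeMetrics:
    """Compute the full descriptor set for one closed path."""
    pts = _points(path)
    lobes = lobe_count(pts)
    ar, angle = aspect_ratio(pts)
    n_x = self_intersections(pts)
    if lobes >= 3:
        sc = side_class(pts)
    elif ar == 1.0:
        sc = "convex"  # circle: every arc bulges outward
    else:
        sc = "convex" if np.isfinite(ar) else "straight"
    _, mean_r = _radii(pts)
    return ShapeMetrics(lobe_count=lobes, aspect_ratio=ar, major_axis_deg=angle,
                        n_self_intersections=n_x, side_class=sc, mean_radius=mean_r)
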