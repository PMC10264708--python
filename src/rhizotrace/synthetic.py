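"""Parametric monocot root-system generator with analytic ground truth.

Stands in for undeposited rhizobox time-lapses: a grain point, a primary
root and several seminal roots, each with an emergence time (hours after
sowing), a constant elongation rate, an initial heading (degrees from the
downward vertical, positive toward image right), a constant curvature and
seeded per-step heading wobble. Roots are traced as polylines in 0.5 px
arc-length steps — the full trajectory to ``max_length_mm`` is generated
once per seed, and the state at time t is an exact-arc-length prefix, so
growth is consistent across frames and every trait has a closed-form or
directly computable ground-truth value.

Rasterization sweeps a disk of radius ``stroke_width/2`` along each
polyline (a pixel is foreground iff its center lies within that distance
of the centerline), giving round caps; ground-truth hull/bounding-box
helpers based on the buffered centerline account for the half-stroke
inflation of mask-derived traits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import LineString, MultiLineString
from shapely.ops import unary_union

from .mask_io import BinaryRootMask, FrameEntry, SeriesManifest

__all__ = [
    "RootSpec",
    "RootSystemSpec",
    "GroundTruth",
    "grow",
    "rasterize",
    "render_series",
    "gp_like",
    "bcc93_like",
    "buffered_hull_area",
    "buffered_bbox_width",
]

STEP_PX = 0.5  # arc-length tracing step


@dataclass(frozen=True)
class RootSpec:
    """One root: geometry and growth schedule.

    ``parent`` is None for roots emerging at the grain, else
    ``(parent_index, branch_position_mm, branch_angle_deg)``; a branch
    takes its parent's local heading plus the branch angle.
    """

    heading_deg: float
    emergence_has: float
    growth_rate_mm_h: float
    max_length_mm: float
    curvature_deg_per_mm: float = 0.0
    wobble_sd_deg: float = 0.0
    parent: Optional[tuple[int, float, float]] = None

    def __post_init__(self) -> None:
        if self.emergence_has < 0:
            raise ValueError("emergence must be >= 0 HAS")
        if self.growth_rate_mm_h <= 0:
            raise ValueError("growth rate must be > 0")
        if self.max_length_mm <= 0:
            raise ValueError("max length must be > 0")

    def length_at(self, t_has: float) -> float:
        """Arc length grown by time t: rate × max(0, t − emergence), capped."""
        return min(max(0.0, t_has - self.emergence_has)
                   * self.growth_rate_mm_h, self.max_length_mm)


@dataclass(frozen=True)
class RootSystemSpec:
    grain: tuple[float, float]  # (x, y) px
    roots: tuple[RootSpec, ...]  # first = primary, then seminals
    stroke_width_px: float = 3.0
    height: int = 260
    width: int = 360
    scale_mm_per_px: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        gx, gy = self.grain
        if not (0 <= gx < self.width and 0 <= gy < self.height):
            raise ValueError("grain must lie inside the image")
        if self.stroke_width_px < 1:
            raise ValueError("stroke width must be >= 1 px")
        for i, r in enumerate(self.roots):
            if r.parent is not None:
                pi, pos, _ = r.parent
                if not (0 <= pi < i):
                    raise ValueError("parent index must precede the child")
                par = self.roots[pi]
                if pos > par.max_length_mm:
                    raise ValueError("branch position beyond parent length")
                reach = par.emergence_has + pos / par.growth_rate_mm_h
                if r.emergence_has < reach - 1e-9:
                    raise ValueError(
                        "child emerges before parent reaches branch point"
                    )


@dataclass
class GroundTruth:
    """Analytic state of a system at one time point (px and mm units)."""

    t_has: float
    polylines: list[np.ndarray]  # per root, (N, 2) float (x, y) px; N=0 if unemerged
    lengths_mm: list[float]
    tips_px: list[Optional[tuple[float, float]]]
    total_length_mm: float
    srga_deg: Optional[float]
    hull_area_mm2: float  # hull of centerline vertices
    bbox_width_mm: float  # centerline-vertex extent
    emergence_times: list[float]
    clipped: bool


def _trace_full(spec: RootSystemSpec) -> list[np.ndarray]:
    """Full trajectory of every root to max length (deterministic per seed).

    Returns per-root (N, 2) arrays of (x, y) px at STEP_PX arc spacing,
    starting at the root's origin.
    """
    step_mm = STEP_PX * spec.scale_mm_per_px
    polys: list[np.ndarray] = []
    headings: list[np.ndarray] = []
    for i, root in enumerate(spec.roots):
        rng = np.random.default_rng([spec.rng_seed, i])
        if root.parent is None:
            origin = np.array(spec.grain, dtype=float)
            h0 = root.heading_deg
        else:
            pi, pos_mm, branch_deg = root.parent
            idx = min(int(round(pos_mm / step_mm)), len(polys[pi]) - 1)
            origin = polys[pi][idx].copy()
            h0 = headings[pi][idx] + branch_deg
        n_steps = int(math.ceil(root.max_length_mm / step_mm))
        pts = np.empty((n_steps + 1, 2))
        hdg = np.empty(n_steps + 1)
        pts[0] = origin
        hdg[0] = h0
        h = h0
        p = origin.copy()
        for s in range(1, n_steps + 1):
            h += root.curvature_deg_per_mm * step_mm
            if root.wobble_sd_deg > 0:
                h += rng.normal(0.0, root.wobble_sd_deg)
            rad = math.radians(h)
            p = p + STEP_PX * np.array([math.sin(rad), math.cos(rad)])
            pts[s] = p
            hdg[s] = h
        polys.append(pts)
        headings.append(hdg)
    return polys


def grow(spec: RootSystemSpec, t_has: float) -> list[np.ndarray]:
    """Centerline polylines of every root at time t (empty before emergence).

    The prefix of the full seeded trajectory with the exact arc length
    ``rate × (t − emergence)`` capped at the maximum length; the last point
    is interpolated so the polyline's arc length is exact.
    """
    if t_has < 0:
        raise ValueError("t must be >= 0 HAS")
    full = _trace_full(spec)
    step_mm = STEP_PX * spec.scale_mm_per_px
    out = []
    for root, pts in zip(spec.roots, full):
        length = root.length_at(t_has)
        if length <= 0:
            out.append(np.empty((0, 2)))
            continue
        n_full = int(length / step_mm)
        frac = length / step_mm - n_full
        n_full = min(n_full, len(pts) - 1)
        poly = pts[: n_full + 1].copy()
        if frac > 1e-9 and n_full + 1 < len(pts):
            extra = pts[n_full] + frac * (pts[n_full + 1] - pts[n_full])
            poly = np.vstack([poly, extra])
        out.append(poly)
    return out


def ground_truth(spec: RootSystemSpec, t_has: float) -> GroundTruth:
    """Analytic trait values at time t, computed from the polylines."""
    polys = grow(spec, t_has)
    lengths = [r.length_at(t_has) for r in spec.roots]
    tips = [tuple(p[-1]) if len(p) else None for p in polys]
    gx, gy = spec.grain

    # SRGA between the first two seminal roots (grain→tip vectors); in a
    # system without a distinct primary the first two roots are used.
    sem = (1, 2) if len(spec.roots) >= 3 else (0, 1)
    srga_val: Optional[float] = None
    if len(spec.roots) > max(sem):
        t1, t2 = tips[sem[0]], tips[sem[1]]
        if t1 is not None and t2 is not None:
            a = np.array([t1[0] - gx, t1[1] - gy])
            b = np.array([t2[0] - gx, t2[1] - gy])
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if na > 0 and nb > 0:
                cos = float(np.clip(a @ b / (na * nb), -1, 1))
                srga_val = math.degrees(math.acos(cos))

    verts = np.vstack([p for p in polys if len(p)]) if any(
        len(p) for p in polys) else np.empty((0, 2))
    hull_mm2 = 0.0
    bbox_mm = 0.0
    if len(verts) >= 3:
        try:
            hull_mm2 = ConvexHull(verts).volume * spec.scale_mm_per_px ** 2
        except QhullError:
            hull_mm2 = 0.0
    if len(verts):
        bbox_mm = float(verts[:, 0].max() - verts[:, 0].min()) \
            * spec.scale_mm_per_px

    clipped = bool(len(verts)) and bool(
        (verts[:, 0] < 0).any() or (verts[:, 1] < 0).any()
        or (verts[:, 0] > spec.width - 1).any()
        or (verts[:, 1] > spec.height - 1).any()
    )
    return GroundTruth(
        t_has=t_has,
        polylines=polys,
        lengths_mm=lengths,
        tips_px=tips,
        total_length_mm=float(sum(lengths)),
        srga_deg=srga_val,
        hull_area_mm2=float(hull_mm2),
        bbox_width_mm=bbox_mm,
        emergence_times=[r.emergence_has for r in spec.roots],
        clipped=clipped,
    )


def rasterize(
    polylines: Sequence[np.ndarray],
    stroke_width: float,
    size: tuple[int, int],
    scale: float = 1.0,
) -> BinaryRootMask:
    """Union of disks of radius stroke/2 swept along the centerlines.

    A pixel is foreground iff its center lies within ``stroke_width / 2``
    of any polyline segment. Content outside the image is clipped.
    """
    if stroke_width < 1:
        raise ValueError("stroke width must be >= 1 px")
    H, W = size
    grid = np.zeros((H, W), dtype=bool)
    r = stroke_width / 2.0
    pad = int(math.ceil(r)) + 1
    for poly in polylines:
        if len(poly) == 0:
            continue
        if len(poly) == 1:
            segs = [(poly[0], poly[0])]
        else:
            segs = list(zip(poly[:-1], poly[1:]))
        for a, b in segs:
            x0 = max(int(math.floor(min(a[0], b[0]))) - pad, 0)
            x1 = min(int(math.ceil(max(a[0], b[0]))) + pad, W - 1)
            y0 = max(int(math.floor(min(a[1], b[1]))) - pad, 0)
            y1 = min(int(math.ceil(max(a[1], b[1]))) + pad, H - 1)
            if x1 < x0 or y1 < y0:
                continue
            yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
            dx, dy = b[0] - a[0], b[1] - a[1]
            l2 = dx * dx + dy * dy
            if l2 == 0:
                d2 = (xx - a[0]) ** 2 + (yy - a[1]) ** 2
            else:
                t = ((xx - a[0]) * dx + (yy - a[1]) * dy) / l2
                t = np.clip(t, 0.0, 1.0)
                d2 = (xx - (a[0] + t * dx)) ** 2 + (yy - (a[1] + t * dy)) ** 2
            grid[y0:y1 + 1, x0:x1 + 1] |= d2 <= r * r
    return BinaryRootMask(grid, scale=scale)


def render_mask(spec: RootSystemSpec, t_has: float) -> BinaryRootMask:
    """Rasterized system state at time t."""
    return rasterize(grow(spec, t_has), spec.stroke_width_px,
                     (spec.height, spec.width), spec.scale_mm_per_px)


def render_series(
    spec: RootSystemSpec,
    out_dir: Union[str, Path],
    interval_min: float = 40.0,
    duration_h: float = 2.0,
    start_has: float = 0.0,
) -> tuple[SeriesManifest, list[GroundTruth]]:
    """Write a frame sequence (PNG, root=255) plus ground truth to disk.

    Frames are captured at ``start_has, start_has + interval, …`` up to and
    including ``start_has + duration``. Output is deterministic for a given
    spec (byte-identical PNGs for equal seeds). Returns the manifest and
    the per-frame ground truth; both are also persisted (``manifest.csv``,
    ``ground_truth.json``, ``spec.json``).
    """
    if duration_h <= 0:
        raise ValueError("duration must be > 0")
    if interval_min <= 0:
        raise ValueError("interval must be > 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = int(round(duration_h * 60.0 / interval_min))
    entries = []
    truths = []
    for i in range(n + 1):
        t = start_has + i * interval_min / 60.0
        mask = render_mask(spec, t)
        img = (mask.grid.astype(np.uint8)) * 255
        path = out_dir / f"frame_{i:04d}.png"
        iio.imwrite(path, img)
        entries.append(FrameEntry(path, i, t))
        truths.append(ground_truth(spec, t))
    manifest = SeriesManifest(tuple(entries), capture_interval_min=interval_min)
    pd.DataFrame(
        [{"path": str(e.path), "frame_id": e.frame_id,
          "timestamp_has": e.timestamp} for e in entries]
    ).to_csv(out_dir / "manifest.csv", index=False)
    (out_dir / "ground_truth.json").write_text(json.dumps([
        {
            "frame_id": i,
            "t_has": gt.t_has,
            "lengths_mm": gt.lengths_mm,
            "total_length_mm": gt.total_length_mm,
            "tips_px": [list(t) if t else None for t in gt.tips_px],
            "srga_deg": gt.srga_deg,
            "hull_area_mm2": gt.hull_area_mm2,
            "bbox_width_mm": gt.bbox_width_mm,
            "emergence_times": gt.emergence_times,
            "clipped": gt.clipped,
        }
        for i, gt in enumerate(truths)
    ], indent=1))
    (out_dir / "spec.json").write_text(json.dumps(spec_to_json(spec), indent=1))
    return manifest, truths


def spec_to_json(spec: RootSystemSpec) -> dict:
    return {
        "grain": list(spec.grain),
        "stroke_width_px": spec.stroke_width_px,
        "height": spec.height,
        "width": spec.width,
        "scale_mm_per_px": spec.scale_mm_per_px,
        "rng_seed": spec.rng_seed,
        "roots": [
            {
                "heading_deg": r.heading_deg,
                "emergence_has": r.emergence_has,
                "growth_rate_mm_h": r.growth_rate_mm_h,
                "max_length_mm": r.max_length_mm,
                "curvature_deg_per_mm": r.curvature_deg_per_mm,
                "wobble_sd_deg": r.wobble_sd_deg,
                "parent": list(r.parent) if r.parent else None,
            }
            for r in spec.roots
        ],
    }


def spec_from_json(data: dict) -> RootSystemSpec:
    roots = tuple(
        RootSpec(
            heading_deg=r["heading_deg"],
            emergence_has=r["emergence_has"],
            growth_rate_mm_h=r["growth_rate_mm_h"],
            max_length_mm=r["max_length_mm"],
            curvature_deg_per_mm=r.get("curvature_deg_per_mm", 0.0),
            wobble_sd_deg=r.get("wobble_sd_deg", 0.0),
            parent=tuple(r["parent"]) if r.get("parent") else None,
        )
        for r in data["roots"]
    )
    return RootSystemSpec(
        grain=tuple(data["grain"]),
        roots=roots,
        stroke_width_px=data.get("stroke_width_px", 3.0),
        height=data.get("height", 260),
        width=data.get("width", 360),
        scale_mm_per_px=data.get("scale_mm_per_px", 0.2),
        rng_seed=data.get("rng_seed", 0),
    )


# ---------------------------------------------------------------------------
# Stroke-inflation helpers for ground-truth comparison
# ---------------------------------------------------------------------------


def _buffered(polylines: Sequence[np.ndarray], radius_px: float):
    lines = [LineString(p) for p in polylines if len(p) >= 2]
    pts = [p for p in polylines if len(p) == 1]
    geoms = lines + [LineString([p[0], p[0] + 1e-6]) for p in pts]
    if not geoms:
        return None
    return unary_union(MultiLineString(lines) if len(lines) > 1
                       else geoms[0] if len(geoms) == 1 else
                       unary_union(geoms)).buffer(radius_px)


def buffered_hull_area(polylines: Sequence[np.ndarray],
                       radius_px: float) -> float:
    """Convex-hull area (px²) of the centerlines dilated by ``radius_px``.

    With radius = stroke/2 this is the continuous-geometry expectation of
    the mask hull; pixel-center sampling lands between the radii
    ``(stroke − √2)/2`` and ``stroke/2`` depending on orientation.
    """
    buf = _buffered(polylines, radius_px)
    return 0.0 if buf is None else float(buf.convex_hull.area)


def buffered_bbox_width(polylines: Sequence[np.ndarray],
                        radius_px: float) -> float:
    """Horizontal extent (px) of the centerlines dilated by ``radius_px``."""
    buf = _buffered(polylines, radius_px)
    if buf is None:
        return 0.0
    minx, _, maxx, _ = buf.bounds
    return float(maxx - minx)


# ---------------------------------------------------------------------------
# Genotype-like presets
# ---------------------------------------------------------------------------


def _preset(
    seminal_half_angle: float,
    seed: int,
    heading_noise_sd_deg: float = 0.0,
    wobble_sd_deg: float = 0.3,
) -> RootSystemSpec:
    """The first two seminal roots at ±half-angle from the vertical.

    The scene is deliberately minimal — the two roots whose inter-heading
    defines the SRGA, the first doubling as the longest (primary-like)
    axis. ``heading_noise_sd_deg`` adds seeded Gaussian noise to each
    root's initial heading, emulating between-plant variation; the ground
    truth tracks the noisy headings exactly.
    """
    rng = np.random.default_rng([seed, 9173])

    def noisy(h: float) -> float:
        if heading_noise_sd_deg <= 0:
            return h
        return h + float(rng.normal(0.0, heading_noise_sd_deg))

    roots = (
        RootSpec(heading_deg=noisy(-seminal_half_angle), emergence_has=64.0,
                 growth_rate_mm_h=2.0, max_length_mm=32.0,
                 wobble_sd_deg=wobble_sd_deg),
        RootSpec(heading_deg=noisy(+seminal_half_angle), emergence_has=70.0,
                 growth_rate_mm_h=2.0, max_length_mm=30.0,
                 wobble_sd_deg=wobble_sd_deg),
    )
    return RootSystemSpec(grain=(180.0, 28.0), roots=roots, rng_seed=seed)


def gp_like(seed: int = 0, heading_noise_sd_deg: float = 0.0) -> RootSystemSpec:
    """Broad-angled genotype stand-in: seminal inter-heading 109.3°."""
    return _preset(109.3 / 2.0, seed, heading_noise_sd_deg)


def bcc93_like(seed: int = 0,
               heading_noise_sd_deg: float = 0.0) -> RootSystemSpec:
    """Narrow-angled genotype stand-in: seminal inter-heading 62.7°."""
    return _preset(62.7 / 2.0, seed, heading_noise_sd_deg)
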