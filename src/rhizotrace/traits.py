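"""Per-frame root-system-architecture traits.

Everything is measured from a cleaned binary mask, its skeleton graph and a
grain landmark: projected root area, total and longest (seed-anchored) root
length, primary-root orientation by orthogonal regression of the primary
path's skeleton pixels, convex-hull area and bounding-box width of the
foreground, the root growth angle RGA (grain→farthest-tip line against the
horizontal through the grain) and the seminal root growth angle SRGA (angle
at the grain between the first two seminal root tips).

The *primary root* is operationalised as the maximum-length simple path
from the graph node nearest the grain to any endpoint, found by exhaustive
depth-first enumeration — root graphs are small. Lengths use subpixel
centerline refinement when :func:`refine_graph` has been applied (as
:func:`extract_traits` does); otherwise the raw geodesic chain metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from ._centerline import refined_chain_geometry
from .config import RunConfig
from .mask_io import BinaryRootMask, clean_mask
from .skelgraph import SkeletonGraph, build_graph, prune_spurs
from .skeletonize import skeletonize

__all__ = [
    "Landmarks",
    "TraitRecord",
    "PrimaryRoot",
    "root_area",
    "total_root_length",
    "longest_root",
    "primary_root_angle",
    "convex_hull_area",
    "bounding_box_width",
    "seminal_tips",
    "rga",
    "srga",
    "refine_graph",
    "extract_traits",
    "render_overlay",
    "TRAIT_COLUMNS",
]

XY = tuple[float, float]

TRAIT_COLUMNS = (
    "frame_id", "timestamp_has", "root_area", "total_root_length",
    "longest_root_length", "primary_root_angle", "convex_hull_area",
    "bounding_box_width", "rga", "srga", "n_endpoints", "n_junctions",
)


@dataclass(frozen=True)
class Landmarks:
    """Grain position and optional manual overrides.

    ``seed_exclusion_radius_px`` of None defers to the run config; manual
    tips, when given, bypass automatic seminal-tip identification.
    """

    grain: XY
    seed_exclusion_radius_px: Optional[float] = None
    manual_tips: Optional[tuple[XY, ...]] = None


@dataclass(frozen=True)
class TraitRecord:
    """One frame's trait vector; angle traits are None when undefined."""

    frame_id: int
    timestamp_has: float
    root_area: float
    total_root_length: float
    longest_root_length: float
    primary_root_angle: Optional[float]
    convex_hull_area: float
    bounding_box_width: float
    rga: Optional[float]
    srga: Optional[float]
    n_endpoints: int
    n_junctions: int

    def __post_init__(self) -> None:
        if self.longest_root_length > self.total_root_length + 1e-6:
            raise ValueError("longest root cannot exceed total length")
        for name in ("root_area", "total_root_length", "longest_root_length",
                     "convex_hull_area", "bounding_box_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PrimaryRoot:
    nodes: tuple[int, ...]
    edges: tuple[tuple[int, int, int], ...]
    length_mm: float
    pixels: tuple[tuple[int, int], ...]


# ---------------------------------------------------------------------------
# Mask-level traits
# ---------------------------------------------------------------------------


def root_area(mask: BinaryRootMask) -> float:
    """Foreground pixel count × scale² (mm²)."""
    return float(mask.grid.sum()) * mask.scale ** 2


def _foreground_points(mask: BinaryRootMask) -> np.ndarray:
    ys, xs = np.nonzero(mask.grid)
    if len(ys) == 0:
        raise ValueError("mask has no foreground")
    return np.stack([xs, ys], axis=1).astype(float)


def convex_hull_area(mask: BinaryRootMask) -> float:
    """Area of the convex hull of foreground pixel centers, in mm².

    Singleton and collinear point sets have a degenerate hull: area 0.
    """
    pts = _foreground_points(mask)
    if len(pts) < 3:
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0  # collinear
    return float(hull.volume) * mask.scale ** 2


def bounding_box_width(mask: BinaryRootMask) -> float:
    """Inclusive horizontal pixel extent × scale (mm)."""
    pts = _foreground_points(mask)
    return float(pts[:, 0].max() - pts[:, 0].min() + 1) * mask.scale


# ---------------------------------------------------------------------------
# Graph-level traits
# ---------------------------------------------------------------------------


def _edge_weight(d: dict) -> float:
    return d.get("length_refined_mm", d["length_mm"])


def total_root_length(graph: SkeletonGraph) -> float:
    """Sum of all edge lengths in mm (refined lengths when available)."""
    return float(sum(_edge_weight(d)
                     for *_, d in graph.multi.edges(data=True)))


def _start_node(graph: SkeletonGraph, landmarks: Landmarks) -> int:
    gx, gy = landmarks.grain
    best = None
    for n, d in graph.multi.nodes(data=True):
        x, y = d["position"]
        key = (math.hypot(x - gx, y - gy), y, x, n)
        if best is None or key < best[0]:
            best = (key, n)
    if best is None:
        raise ValueError("no root material")
    return best[1]


def _anchored(graph: SkeletonGraph, landmarks: Landmarks
              ) -> tuple[SkeletonGraph, int]:
    """Graph plus the start node for seed-anchored paths.

    The start is the skeleton location nearest the grain. When that is a
    mid-chain pixel rather than an existing node — as happens when two
    roots diverging from the grain thin into one V-shaped chain — the edge
    is split there and a degree-2 ``anchor`` node inserted, so paths and
    tip partitions genuinely start at the seed. Refined edge lengths are
    prorated over the split by raw chain length.
    """
    gx, gy = landmarks.grain
    if graph.n_nodes == 0:
        raise ValueError("no root material")
    start = _start_node(graph, landmarks)
    sx, sy = graph.multi.nodes[start]["position"]
    best_node_d = math.hypot(sx - gx, sy - gy)

    best = None  # (dist, y, x, u, v, k, idx)
    for u, v, k, d in graph.multi.edges(keys=True, data=True):
        chain = d["chain"]
        for idx in range(1, len(chain) - 1):
            x, y = chain[idx]
            dist = math.hypot(x - gx, y - gy)
            cand = (dist, y, x, u, v, k, idx)
            if best is None or cand < best:
                best = cand
    if best is None or best[0] >= best_node_d - 1e-9:
        return graph, start

    dist, y, x, u, v, k, idx = best
    G = graph.multi.copy()
    d = G.edges[u, v, k]
    chain = list(d["chain"])
    if chain[0] not in set(G.nodes[u]["pixels"]):
        u, v = v, u  # orient chain from u to v
    aid = max(G.nodes) + 1
    G.add_node(aid, position=(x, y), kind="anchor", pixels=((x, y),))
    raw_total = d["length_mm"]
    c1, c2 = chain[: idx + 1], chain[idx:]
    from .skelgraph import chain_length

    l1 = chain_length(c1, graph.scale)
    l2 = chain_length(c2, graph.scale)
    attrs1 = {"chain": tuple(c1), "length_mm": l1}
    attrs2 = {"chain": tuple(c2), "length_mm": l2}
    if "length_refined_mm" in d and raw_total > 0:
        ref = d["length_refined_mm"]
        attrs1["length_refined_mm"] = ref * l1 / raw_total
        attrs2["length_refined_mm"] = ref * l2 / raw_total
    G.remove_edge(u, v, k)
    G.add_edge(u, aid, **attrs1)
    G.add_edge(aid, v, **attrs2)
    return SkeletonGraph(G, scale=graph.scale, shape=graph.shape), aid


def _oriented_chain(graph: SkeletonGraph, u: int, v: int, k: int
                    ) -> list[tuple[int, int]]:
    """Edge chain ordered from node u to node v."""
    d = graph.multi.edges[u, v, k]
    chain = list(d["chain"])
    if chain[0] in set(graph.multi.nodes[u]["pixels"]):
        return chain
    return chain[::-1]


def _enumerate_paths(graph: SkeletonGraph, start: int):
    """Yield (terminal_node, length, edge_path) for every simple path from
    ``start``; a self-loop may be appended as a terminating move."""
    G = graph.multi
    out: list[tuple[int, float, tuple]] = []

    def rec(node: int, visited: set, length: float, epath: tuple) -> None:
        if node != start or epath:
            out.append((node, length, epath))
        for nbr, keydict in sorted(G.adj[node].items()):
            if nbr == node:
                for k, d in sorted(keydict.items()):
                    if (node, node, k) not in epath:
                        out.append((node, length + _edge_weight(d),
                                    epath + ((node, node, k),)))
                continue
            if nbr in visited:
                continue
            for k, d in sorted(keydict.items()):
                rec(nbr, visited | {nbr}, length + _edge_weight(d),
                    epath + ((node, nbr, k),))

    rec(start, {start}, 0.0, ())
    return out


def _node_sort_key(graph: SkeletonGraph, n: int) -> tuple:
    x, y = graph.multi.nodes[n]["position"]
    return (y, x, n)


def longest_root(graph: SkeletonGraph, landmarks: Landmarks
                 ) -> PrimaryRoot:
    """Maximum-length simple path from the node nearest the grain to an
    endpoint; this path is designated the primary root.

    In a graph without endpoint nodes (a pure cycle) the longest simple
    path to any node — including one closing self-loop — is returned.
    Ties break toward the lexicographically smallest terminal (y, x).
    """
    if graph.n_nodes == 0:
        raise ValueError("no root material")
    graph, start = _anchored(graph, landmarks)
    kinds = {n: d["kind"] for n, d in graph.multi.nodes(data=True)}
    has_endpoints = any(k == "endpoint" for k in kinds.values())

    all_paths = _enumerate_paths(graph, start)
    best: Optional[tuple[float, tuple, int, tuple]] = None
    for endpoint_only in ((True, False) if has_endpoints else (False,)):
        for terminal, length, epath in all_paths:
            if endpoint_only and kinds[terminal] != "endpoint":
                continue
            key = (-length, _node_sort_key(graph, terminal))
            if best is None or (key[0], key[1]) < (best[0], best[1]):
                best = (key[0], key[1], terminal, epath)
        if best is not None:
            break
    if best is None:  # isolated single node
        pos = graph.multi.nodes[start]["position"]
        return PrimaryRoot((start,), (), 0.0, (pos,))

    _, _, terminal, epath = best
    length = -best[0]
    nodes = (start,) + tuple(v for _, v, _ in epath)
    pixels: list[tuple[int, int]] = []
    for u, v, k in epath:
        chain = _oriented_chain(graph, u, v, k)
        if pixels and pixels[-1] == chain[0]:
            chain = chain[1:]
        pixels.extend(chain)
    if not pixels:
        pixels = [graph.multi.nodes[start]["position"]]
    return PrimaryRoot(nodes, tuple(epath), float(length), tuple(pixels))


def primary_root_angle(path_pixels: Sequence[tuple[float, float]]) -> float:
    """Orientation of the principal axis of the path's pixels.

    Orthogonal regression: the dominant eigenvector of the 2×2 coordinate
    covariance, reported as the angle to the horizontal image axis in
    (0, 180] degrees (y increases downward; a vertical root reads 90°).
    """
    pts = np.asarray(path_pixels, dtype=float)
    if len(pts) < 2 or np.allclose(pts, pts[0]):
        raise ValueError("need at least 2 distinct pixels")
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    vx, vy = evecs[:, int(np.argmax(evals))]
    ang = math.degrees(math.atan2(vy, vx)) % 180.0
    return 180.0 if ang == 0.0 else ang


def seminal_tips(graph: SkeletonGraph, landmarks: Landmarks, k: int = 2
                 ) -> list[XY]:
    """Positions of the ``k`` major root tips, longest root first.

    Manual tips, when provided, are returned verbatim. Otherwise endpoint
    nodes are grouped by the first edge their best (longest) seed-anchored
    path takes out of the start node — one group per root emerging from the
    grain region — and the k groups of greatest path length each contribute
    their endpoint farthest from the grain. Subpixel-refined tip positions
    are used when available. Ties break by (y, x).
    """
    if landmarks.manual_tips is not None:
        return list(landmarks.manual_tips)
    if k < 1:
        raise ValueError("k must be >= 1")
    graph, start = _anchored(graph, landmarks)
    G = graph.multi
    candidates = [n for n, d in G.nodes(data=True)
                  if d["kind"] == "endpoint" and n != start]
    if len(candidates) < k:
        raise ValueError(
            f"fewer than {k} endpoints available ({len(candidates)})"
        )

    best_path: dict[int, tuple[float, tuple]] = {}
    for terminal, length, epath in _enumerate_paths(graph, start):
        if terminal not in set(candidates) or not epath:
            continue
        cur = best_path.get(terminal)
        if cur is None or length > cur[0] + 1e-12:
            best_path[terminal] = (length, epath)

    groups = _tip_groups(graph, start, sorted(best_path), 0)

    gx, gy = landmarks.grain

    def tip_position(n: int) -> XY:
        d = G.nodes[n]
        if "tip_position" in d:
            return d["tip_position"]
        return (float(d["position"][0]), float(d["position"][1]))

    ranked = []
    for members in groups:
        glen = max(best_path[m][0] for m in members)
        far = max(members, key=lambda m: (
            math.hypot(tip_position(m)[0] - gx, tip_position(m)[1] - gy),
            [-c for c in _node_sort_key(graph, m)],
        ))
        ranked.append((-glen, _node_sort_key(graph, far), far))
    ranked.sort()
    return [tip_position(r[2]) for r in ranked[:k]]


def _tip_groups(graph: SkeletonGraph, start: int, targets: list[int],
                depth: int) -> list[list[int]]:
    """Partition target endpoints into one group per root.

    Targets are grouped by the first edge of their best path out of
    ``start``; a group whose members share that edge is re-partitioned
    from the far end of it, so roots that merge near the grain (even
    through a loop pinched between crossing strokes) still separate at
    their true divergence node.
    """
    if not targets:
        return []
    best: dict[int, tuple[float, tuple]] = {}
    tset = set(targets)
    for terminal, length, epath in _enumerate_paths(graph, start):
        if terminal not in tset or not epath:
            continue
        cur = best.get(terminal)
        if cur is None or length > cur[0] + 1e-12:
            best[terminal] = (length, epath)
    by_first: dict[tuple, list[int]] = {}
    for node in sorted(best):
        u, v, kk = best[node][1][0]
        by_first.setdefault((min(u, v), max(u, v), kk), []).append(node)
    out: list[list[int]] = []
    for (u, v, kk), members in sorted(by_first.items()):
        w = v if u == start else u
        if len(members) == 1 or w == start or depth >= graph.n_edges:
            out.append(members)
        else:
            out.extend(_tip_groups(graph, w, members, depth + 1))
    return out


def rga(landmarks: Landmarks, tips: Sequence[XY]) -> float:
    """Root growth angle: grain→farthest-tip line vs the horizontal, [0, 90]°."""
    if not tips:
        raise ValueError("need at least one tip")
    gx, gy = landmarks.grain
    tip = max(tips, key=lambda t: (math.hypot(t[0] - gx, t[1] - gy),
                                   -t[1], -t[0]))
    dx, dy = tip[0] - gx, tip[1] - gy
    if math.hypot(dx, dy) == 0:
        raise ValueError("tip coincides with grain")
    return math.degrees(math.atan2(abs(dy), abs(dx)))


def srga(landmarks: Landmarks, tip1: XY, tip2: XY) -> float:
    """Seminal root growth angle: angle at the grain between two tips, [0, 180]°."""
    gx, gy = landmarks.grain
    a = np.array([tip1[0] - gx, tip1[1] - gy])
    b = np.array([tip2[0] - gx, tip2[1] - gy])
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("tip coincides with grain")
    cos = float(np.clip(a @ b / (na * nb), -1.0, 1.0))
    return math.degrees(math.acos(cos))


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------


def render_overlay(
    mask: BinaryRootMask,
    graph: Optional[SkeletonGraph] = None,
    primary: Optional[PrimaryRoot] = None,
    path=None,
):
    """QC overlay: mask (gray), skeleton (green), primary path (red),
    convex hull outline (blue). Returns an H×W×3 uint8 array; writes a PNG
    when ``path`` is given."""
    H, W = mask.shape
    img = np.zeros((H, W, 3), dtype=np.uint8)
    img[mask.grid] = (90, 90, 90)
    if graph is not None:
        for e in graph.edges():
            for x, y in e.chain:
                img[y, x] = (60, 200, 60)
    if primary is not None:
        for x, y in primary.pixels:
            xi, yi = int(round(x)), int(round(y))
            if 0 <= yi < H and 0 <= xi < W:
                img[yi, xi] = (230, 60, 60)
    if mask.grid.any():
        pts = _foreground_points(mask)
        if len(pts) >= 3:
            try:
                hull = ConvexHull(pts)
                verts = pts[hull.vertices].astype(int)
                from skimage.draw import line as _line

                for a, b in zip(verts, np.roll(verts, -1, axis=0)):
                    rr, cc = _line(a[1], a[0], b[1], b[0])
                    img[rr, cc] = (80, 120, 230)
            except QhullError:
                pass
    if path is not None:
        import imageio.v3 as iio

        iio.imwrite(path, img)
    return img


def refine_graph(graph: SkeletonGraph, mask: BinaryRootMask) -> SkeletonGraph:
    """Attach subpixel-refined lengths and tip positions to a graph.

    Sets ``length_refined_mm`` on every edge and ``tip_position`` on every
    endpoint node; subsequent length traits then use the refined metric.
    """
    G = graph.multi
    for u, v, k, d in G.edges(keys=True, data=True):
        chain = _oriented_chain(graph, u, v, k)
        owner0 = u if chain == list(d["chain"]) else v
        owner1 = v if owner0 == u else u
        tip0 = G.nodes[owner0]["kind"] == "endpoint"
        tip1 = G.nodes[owner1]["kind"] == "endpoint"
        length_px, t0, t1 = refined_chain_geometry(mask.grid, chain,
                                                   tip0, tip1)
        d["length_refined_mm"] = length_px * graph.scale
        if t0 is not None:
            G.nodes[owner0]["tip_position"] = t0
        if t1 is not None:
            G.nodes[owner1]["tip_position"] = t1
    return graph


def _exclude_seed(mask: BinaryRootMask, landmarks: Landmarks,
                  radius_px: float) -> BinaryRootMask:
    if radius_px <= 0:
        return mask
    H, W = mask.shape
    gx, gy = landmarks.grain
    yy, xx = np.mgrid[0:H, 0:W]
    keep = (xx - gx) ** 2 + (yy - gy) ** 2 > radius_px ** 2
    return BinaryRootMask(mask.grid & keep, scale=mask.scale)


def _empty_record(frame_id: int, timestamp: float) -> TraitRecord:
    return TraitRecord(frame_id, timestamp, 0.0, 0.0, 0.0, None, 0.0, 0.0,
                       None, None, 0, 0)


def extract_traits(
    mask: BinaryRootMask,
    landmarks: Landmarks,
    config: Optional[RunConfig] = None,
    frame_id: int = 0,
    timestamp_has: float = 0.0,
) -> TraitRecord:
    """Run the full per-frame pipeline: clean → skeletonize → graph →
    prune → refine → traits.

    The seed-exclusion disk around the grain is removed before any trait is
    measured, so the grain body never counts as root. A frame with no
    remaining root material yields an all-zero record with angle traits
    absent; trait-level failures (e.g. too few endpoints for SRGA) are
    recorded as absent values rather than raised.
    """
    cfg = config or RunConfig()
    H, W = mask.shape
    gx, gy = landmarks.grain
    if not (0 <= gx < W and 0 <= gy < H):
        raise ValueError(f"grain ({gx},{gy}) outside image {W}x{H}")
    radius = (landmarks.seed_exclusion_radius_px
              if landmarks.seed_exclusion_radius_px is not None
              else cfg.seed_exclusion_radius_px)
    m = _exclude_seed(mask, landmarks, radius)
    m = clean_mask(m, cfg.min_object_px, cfg.fill_holes_max_px)
    if not m.grid.any():
        return _empty_record(frame_id, timestamp_has)

    skel = skeletonize(m)
    graph = build_graph(skel)
    graph = prune_spurs(graph, cfg.spur_min_mm)
    graph = refine_graph(graph, m)

    area = root_area(m)
    total = total_root_length(graph)
    hull = convex_hull_area(m)
    bbox = bounding_box_width(m)
    kinds = graph.node_kinds()

    angle: Optional[float] = None
    rga_deg: Optional[float] = None
    srga_deg: Optional[float] = None
    longest = 0.0
    try:
        primary = longest_root(graph, landmarks)
        longest = min(primary.length_mm, total)
        if len(primary.pixels) >= 2:
            angle = primary_root_angle(primary.pixels)
    except ValueError:
        pass
    try:
        if landmarks.manual_tips is not None:
            tips = list(landmarks.manual_tips)
        else:
            tips = []
            for k in (2, 1):
                try:
                    tips = seminal_tips(graph, landmarks, k=k)
                    break
                except ValueError:
                    continue
        if tips:
            rga_deg = rga(landmarks, tips)
        if len(tips) >= 2:
            srga_deg = srga(landmarks, tips[0], tips[1])
    except ValueError:
        pass

    return TraitRecord(
        frame_id=frame_id,
        timestamp_has=timestamp_has,
        root_area=area,
        total_root_length=total,
        longest_root_length=longest,
        primary_root_angle=angle,
        convex_hull_area=hull,
        bounding_box_width=bbox,
        rga=rga_deg,
        srga=srga_deg,
        n_endpoints=kinds["endpoint"],
        n_junctions=kinds["junction"],
    )
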