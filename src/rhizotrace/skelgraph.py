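"""Skeleton → undirected multigraph of endpoints/junctions and pixel chains.

This is the network-graph construction step of the phenotyping pipeline,
implemented directly on the pixel grid. Node pixels are skeleton pixels of
8-neighbour degree 1 (endpoints), degree ≥ 3 (junctions) or degree 0
(isolated); 8-connected clumps of junction pixels — which parallel thinning
produces at crossings — are merged into a single junction node at the
clump's integer-rounded centroid. Every remaining (degree-2) pixel belongs
to exactly one maximal chain; each chain becomes one edge whose geodesic
length is ``scale × (axial steps + √2 · diagonal steps)``. A connected
component consisting only of degree-2 pixels is a pure cycle: its
lexicographically smallest (y, x) pixel is promoted to a ``cycle_anchor``
node carrying one self-loop edge. Parallel edges and self-loops are kept;
the union of edge chains and node pixels reconstructs the skeleton exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import networkx as nx
import numpy as np
from scipy import ndimage as ndi

from .mask_io import STRUCT8
from .skeletonize import NEIGHBOR_OFFSETS, Skeleton

__all__ = [
    "SkelNode",
    "SkelEdge",
    "SkeletonGraph",
    "classify_pixels",
    "build_graph",
    "prune_spurs",
    "chain_length",
]

SQRT2 = math.sqrt(2.0)

Pixel = tuple[int, int]  # (x, y)


@dataclass(frozen=True)
class SkelNode:
    id: int
    position: Pixel
    kind: str  # endpoint | junction | isolated | cycle_anchor
    pixels: tuple[Pixel, ...] = ()  # all skeleton pixels owned by the node


@dataclass(frozen=True)
class SkelEdge:
    u: int
    v: int
    key: int
    chain: tuple[Pixel, ...]
    length_mm: float


@dataclass
class SkeletonGraph:
    """Multigraph wrapper; ``multi`` is a networkx.MultiGraph.

    Node attributes: ``position`` (x, y), ``kind``, ``pixels``.
    Edge attributes: ``chain`` (tuple of (x, y) from u to v), ``length_mm``,
    and optionally ``length_refined_mm`` once subpixel refinement has run.
    """

    multi: nx.MultiGraph
    scale: float
    shape: tuple[int, int]  # (H, W) of the source skeleton grid

    def nodes(self) -> list[SkelNode]:
        return [
            SkelNode(n, d["position"], d["kind"], tuple(d["pixels"]))
            for n, d in sorted(self.multi.nodes(data=True))
        ]

    def edges(self) -> list[SkelEdge]:
        return [
            SkelEdge(u, v, k, tuple(d["chain"]), d["length_mm"])
            for u, v, k, d in self.multi.edges(keys=True, data=True)
        ]

    @property
    def n_nodes(self) -> int:
        return self.multi.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.multi.number_of_edges()

    def total_length_mm(self) -> float:
        return float(
            sum(d["length_mm"] for *_, d in self.multi.edges(data=True))
        )

    def node_kinds(self) -> dict[str, int]:
        out = {"endpoint": 0, "junction": 0, "isolated": 0, "cycle_anchor": 0}
        for _, d in self.multi.nodes(data=True):
            out[d["kind"]] += 1
        return out

    def to_skeleton(self) -> Skeleton:
        grid = np.zeros(self.shape, dtype=bool)
        for _, d in self.multi.nodes(data=True):
            for x, y in d["pixels"]:
                grid[y, x] = True
        for *_, d in self.multi.edges(data=True):
            for x, y in d["chain"]:
                grid[y, x] = True
        return Skeleton(grid, scale=self.scale)

    def to_json(self) -> dict:
        return {
            "scale_mm_per_px": self.scale,
            "shape": list(self.shape),
            "nodes": [
                {"id": n, "x": d["position"][0], "y": d["position"][1],
                 "kind": d["kind"]}
                for n, d in sorted(self.multi.nodes(data=True))
            ],
            "edges": [
                {"u": u, "v": v, "length_mm": d["length_mm"],
                 "chain": [list(p) for p in d["chain"]]}
                for u, v, k, d in self.multi.edges(keys=True, data=True)
            ],
        }

    def save_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))


def chain_length(chain: Iterable[Pixel], scale: float = 1.0) -> float:
    """Geodesic length of an 8-connected pixel chain in mm.

    Axial steps cost 1, diagonal steps √2; a single pixel has length 0.
    """
    pts = list(chain)
    total = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        dx, dy = abs(x1 - x0), abs(y1 - y0)
        if max(dx, dy) != 1:
            raise ValueError(
                f"chain pixels ({x0},{y0}) and ({x1},{y1}) are not 8-neighbours"
            )
        total += SQRT2 if dx + dy == 2 else 1.0
    return total * scale


def _degree_grid(grid: np.ndarray) -> np.ndarray:
    return ndi.convolve(grid.astype(np.int8), STRUCT8, mode="constant") - grid


def classify_pixels(skeleton: Skeleton) -> dict[Pixel, int]:
    """Map each skeleton pixel (x, y) to its 8-neighbour skeleton degree."""
    deg = _degree_grid(skeleton.grid)
    ys, xs = np.nonzero(skeleton.grid)
    return {(int(x), int(y)): int(deg[y, x]) for y, x in zip(ys, xs)}


def _neighbors(grid: np.ndarray, y: int, x: int) -> list[tuple[int, int]]:
    H, W = grid.shape
    out = []
    for dy, dx in NEIGHBOR_OFFSETS:
        yy, xx = y + dy, x + dx
        if 0 <= yy < H and 0 <= xx < W and grid[yy, xx]:
            out.append((yy, xx))
    return out


def build_graph(skeleton: Skeleton) -> SkeletonGraph:
    """Construct the endpoint/junction multigraph of a thin skeleton."""
    grid = skeleton.grid
    deg = _degree_grid(grid)
    G = nx.MultiGraph()

    # --- nodes ------------------------------------------------------------
    node_of_pixel: dict[tuple[int, int], int] = {}  # (y, x) -> node id
    records: list[tuple[tuple[int, int], str, list[tuple[int, int]]]] = []

    junc = grid & (deg >= 3)
    if junc.any():
        lab, n_clusters = ndi.label(junc, structure=STRUCT8)
        for ci in range(1, n_clusters + 1):
            ys, xs = np.nonzero(lab == ci)
            pix = sorted(zip(ys.tolist(), xs.tolist()))
            records.append((pix[0], "junction", pix))
    for kind, sel in (("endpoint", grid & (deg == 1)),
                      ("isolated", grid & (deg == 0))):
        ys, xs = np.nonzero(sel)
        for y, x in zip(ys.tolist(), xs.tolist()):
            records.append(((y, x), kind, [(y, x)]))

    records.sort(key=lambda r: r[0])  # deterministic ids by seed pixel (y, x)
    for nid, (seed, kind, pix) in enumerate(records):
        if kind == "junction":
            cy = int(round(float(np.mean([p[0] for p in pix]))))
            cx = int(round(float(np.mean([p[1] for p in pix]))))
            pos = (cx, cy)
        else:
            pos = (seed[1], seed[0])
        G.add_node(nid, position=pos, kind=kind,
                   pixels=tuple((x, y) for y, x in pix))
        for p in pix:
            node_of_pixel[p] = nid

    # --- chains between node pixels ----------------------------------------
    visited: set[tuple[int, int]] = set()  # consumed degree-2 pixels
    stub_seen: set[frozenset] = set()  # direct node-node adjacencies

    def add_edge(chain_yx: list[tuple[int, int]]) -> None:
        u = node_of_pixel[chain_yx[0]]
        v = node_of_pixel[chain_yx[-1]]
        chain = tuple((x, y) for y, x in chain_yx)
        G.add_edge(u, v, chain=chain,
                   length_mm=chain_length(chain, skeleton.scale))

    for p in sorted(node_of_pixel):
        y, x = p
        for q in _neighbors(grid, y, x):
            if q in node_of_pixel:
                if node_of_pixel[q] == node_of_pixel[p]:
                    continue  # internal junction-cluster adjacency
                key = frozenset((p, q))
                if key in stub_seen:
                    continue
                stub_seen.add(key)
                add_edge([p, q])
            elif q not in visited:
                chain = [p, q]
                visited.add(q)
                prev, cur = p, q
                while True:
                    nxt = [r for r in _neighbors(grid, *cur) if r != prev]
                    assert len(nxt) == 1, "degree-2 chain pixel expected"
                    nxt = nxt[0]
                    chain.append(nxt)
                    if nxt in node_of_pixel:
                        break
                    visited.add(nxt)
                    prev, cur = cur, nxt
                add_edge(chain)

    # --- pure cycles: all-degree-2 components -------------------------------
    leftover = grid & (deg == 2)
    for y, x in zip(*np.nonzero(leftover)):
        p = (int(y), int(x))
        if p in visited or p in node_of_pixel:
            continue
        # walk the ring from its lexicographically smallest pixel
        ring = {p}
        frontier = [p]
        while frontier:
            cur = frontier.pop()
            for r in _neighbors(grid, *cur):
                if r not in ring and r not in node_of_pixel:
                    ring.add(r)
                    frontier.append(r)
        anchor = min(ring)
        nid = G.number_of_nodes()
        G.add_node(nid, position=(anchor[1], anchor[0]), kind="cycle_anchor",
                   pixels=((anchor[1], anchor[0]),))
        node_of_pixel[anchor] = nid
        chain = [anchor]
        nbrs = _neighbors(grid, *anchor)
        prev, cur = anchor, nbrs[0]
        chain.append(cur)
        visited.add(cur)
        while cur != anchor:
            nxt = [r for r in _neighbors(grid, *cur) if r != prev]
            nxt = nxt[0]
            chain.append(nxt)
            if nxt != anchor:
                visited.add(nxt)
            prev, cur = cur, nxt
        add_edge(chain)
        visited.update(ring - {anchor})

    return SkeletonGraph(G, scale=skeleton.scale, shape=grid.shape)


def _component_edge_count(G: nx.MultiGraph, node: int) -> int:
    comp = nx.node_connected_component(G, node)
    return sum(1 for u, v, k in G.edges(keys=True) if u in comp)


def prune_spurs(graph: SkeletonGraph, min_len_mm: float) -> SkeletonGraph:
    """Iteratively delete terminal edges shorter than ``min_len_mm``.

    A spur is an edge incident to an endpoint node. The shortest spur is
    removed from the skeleton grid and the graph is rebuilt, which merges
    the two surviving chains of any junction reduced to degree 2; this
    repeats until no spur below the threshold remains. An edge that is the
    only edge of its component is never removed (a component is never
    emptied).
    """
    if min_len_mm <= 0:
        return graph
    g = graph
    while True:
        G = g.multi
        cands = []
        for u, v, k, d in G.edges(keys=True, data=True):
            if d["length_mm"] >= min_len_mm:
                continue
            ends = [n for n in (u, v) if G.nodes[n]["kind"] == "endpoint"]
            if not ends:
                continue
            if _component_edge_count(G, u) <= 1:
                continue
            tip = ends[0]
            cands.append((d["length_mm"], u, v, k, tip))
        if not cands:
            return g
        cands.sort(key=lambda c: (c[0], c[1], c[2], c[3]))
        _, u, v, k, tip = cands[0]
        chain = G.edges[u, v, k]["chain"]
        grid = g.to_skeleton().grid.copy()
        # keep the junction-side terminal pixel; drop the rest of the chain
        tip_pos = G.nodes[tip]["position"]
        pts = list(chain) if chain[0] == tip_pos else list(chain[::-1])
        for x, y in pts[:-1]:
            grid[y, x] = False
        # re-thin: junction clumps left behind by the removed chain reduce
        # to clean 1-px chains before the graph is rebuilt
        from .mask_io import BinaryRootMask
        from .skeletonize import skeletonize as _thin

        g = build_graph(_thin(BinaryRootMask(grid, scale=g.scale)))
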