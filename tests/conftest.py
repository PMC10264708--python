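"""Shared fixtures and independent oracles.

The oracles re-derive expected values by routes that share no code with the
implementation: maximal-chain statistics by component counting and
adjacent-pair summation, convex hulls by the all-pairs half-plane test,
longest paths via networkx simple-path enumeration.
"""

from __future__ import annotations

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from scipy import ndimage as ndi

from rhizotrace.mask_io import BinaryRootMask

SQRT2 = math.sqrt(2.0)
OFFS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
S8 = np.ones((3, 3), dtype=int)


def random_blob_mask(rng: np.random.Generator, side: int = 64,
                     density: float = 0.45) -> BinaryRootMask:
    grid = rng.random((side, side)) < density
    grid = ndi.binary_closing(grid)
    return BinaryRootMask(grid)


def count_components8(grid: np.ndarray) -> int:
    return ndi.label(grid, structure=S8)[1]


def count_holes4(grid: np.ndarray) -> int:
    padded = np.pad(~grid, 1, constant_values=True)
    return ndi.label(padded)[1] - 1  # 4-connectivity; outer background is one


# ---------------------------------------------------------------------------
# Chain-statistics oracle (node kinds, edge count, total geodesic length)
# ---------------------------------------------------------------------------


def chain_stats_oracle(grid: np.ndarray) -> dict:
    """Graph statistics of a thin skeleton without walking any chain.

    Node pixels are those of degree != 2; junction clumps merge by flood
    fill; every 8-connected component of degree-2 pixels is exactly one
    chain (one edge), plus one edge per direct adjacency between pixels of
    different nodes, plus one per pure cycle. Total geodesic length is the
    sum over 8-adjacent pixel pairs not internal to a junction clump.
    """
    pts = {(int(y), int(x)) for y, x in zip(*np.nonzero(grid))}
    deg = {p: sum(((p[0] + dy, p[1] + dx) in pts) for dy, dx in OFFS8)
           for p in pts}

    junction_px = {p for p in pts if deg[p] >= 3}
    seen: set = set()
    n_junctions = 0
    for p in sorted(junction_px):
        if p in seen:
            continue
        n_junctions += 1
        stack = [p]
        seen.add(p)
        while stack:
            cur = stack.pop()
            for dy, dx in OFFS8:
                q = (cur[0] + dy, cur[1] + dx)
                if q in junction_px and q not in seen:
                    seen.add(q)
                    stack.append(q)

    node_px = {p for p in pts if deg[p] != 2}

    # chain components among degree-2 pixels
    deg2 = {p for p in pts if deg[p] == 2}
    comp_of: dict = {}
    comps: list[set] = []
    for p in sorted(deg2):
        if p in comp_of:
            continue
        comp = {p}
        stack = [p]
        comp_of[p] = len(comps)
        while stack:
            cur = stack.pop()
            for dy, dx in OFFS8:
                q = (cur[0] + dy, cur[1] + dx)
                if q in deg2 and q not in comp:
                    comp_of[q] = len(comps)
                    comp.add(q)
                    stack.append(q)
        comps.append(comp)

    n_pure_cycles = 0
    n_chain_edges = 0
    for comp in comps:
        touches_node = any(
            (p[0] + dy, p[1] + dx) in node_px
            for p in comp for dy, dx in OFFS8
        )
        if touches_node:
            n_chain_edges += 1
        else:
            n_pure_cycles += 1

    # direct adjacencies between different node pixels (junction-internal
    # pairs belong to one merged node and are not edges)
    def cluster_id(p):
        return ("j", _junction_cluster_id(p, junction_px)) \
            if p in junction_px else ("s", p)

    def _junction_cluster_id(p, jset):
        # flood to the lexicographically smallest pixel of p's clump
        comp = {p}
        stack = [p]
        while stack:
            cur = stack.pop()
            for dy, dx in OFFS8:
                q = (cur[0] + dy, cur[1] + dx)
                if q in jset and q not in comp:
                    comp.add(q)
                    stack.append(q)
        return min(comp)

    n_direct = 0
    for p in node_px:
        for dy, dx in OFFS8:
            q = (p[0] + dy, p[1] + dx)
            if q in node_px and p < q and cluster_id(p) != cluster_id(q):
                n_direct += 1

    total = 0.0
    for p in pts:
        for dy, dx in OFFS8:
            q = (p[0] + dy, p[1] + dx)
            if q in pts and p < q:
                if p in junction_px and q in junction_px:
                    continue
                total += SQRT2 if dy and dx else 1.0

    return {
        "endpoint": sum(1 for p in pts if deg[p] == 1),
        "junction": n_junctions,
        "isolated": sum(1 for p in pts if deg[p] == 0),
        "cycle_anchor": n_pure_cycles,
        "n_edges": n_chain_edges + n_direct + n_pure_cycles,
        "total_length": total,
    }


# ---------------------------------------------------------------------------
# Convex-hull oracle: all-pairs half-plane test + shoelace
# ---------------------------------------------------------------------------


def hull_area_oracle(points: np.ndarray) -> float:
    pts = [tuple(map(float, p)) for p in points]
    pts = sorted(set(pts))
    if len(pts) < 3:
        return 0.0
    hull_pts = []
    for a, b in combinations(pts, 2):
        pos = neg = 0
        for c in pts:
            cross = ((b[0] - a[0]) * (c[1] - a[1])
                     - (b[1] - a[1]) * (c[0] - a[0]))
            if cross > 1e-12:
                pos += 1
            elif cross < -1e-12:
                neg += 1
        if pos == 0 or neg == 0:  # supporting line
            hull_pts.extend([a, b])
    hull_pts = sorted(set(hull_pts))
    if len(hull_pts) < 3:
        return 0.0
    cx = sum(p[0] for p in hull_pts) / len(hull_pts)
    cy = sum(p[1] for p in hull_pts) / len(hull_pts)
    ordered = sorted(hull_pts, key=lambda p: math.atan2(p[1] - cy, p[0] - cx))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(ordered, ordered[1:] + ordered[:1]):
        area += x0 * y1 - x1 * y0
    return abs(area) / 2.0


# ---------------------------------------------------------------------------
# Longest seed-anchored path oracle via networkx enumeration
# ---------------------------------------------------------------------------


def longest_path_oracle(G: nx.MultiGraph, start: int,
                        weight: str = "length_mm") -> float:
    """Max-length simple path from start to an endpoint-kind node, with a
    self-loop allowed as a final move; enumerated with networkx."""
    comp = nx.node_connected_component(G, start)
    kinds = {n: d["kind"] for n, d in G.nodes(data=True)}
    targets = [n for n in comp if kinds[n] == "endpoint"]
    if not targets:
        targets = sorted(comp)
    loops = {}
    for u, v, k, d in G.edges(keys=True, data=True):
        if u == v:
            loops[u] = max(loops.get(u, 0.0), d[weight])

    best = 0.0
    found = False
    for t in targets:
        if t == start:
            if start in loops:
                best = max(best, loops[start])
                found = True
            continue
        for epath in nx.all_simple_edge_paths(G, start, t):
            length = sum(G.edges[e][weight] for e in epath)
            length += loops.get(t, 0.0)
            best = max(best, length)
            found = True
    if not found and start in loops:
        best = loops[start]
    return best


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
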