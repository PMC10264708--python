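"""Built-in consistency checks for the `selftest` CLI command.

Each check re-derives an expected value by an independent route — a
brute-force chain enumerator for the graph, analytic ground truth for the
generator — and compares at a stated tolerance. A hidden perturbation hook
lets the CLI demonstrate that a broken length metric is caught.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .mask_io import STRUCT8, BinaryRootMask
from .skelgraph import build_graph
from .skeletonize import NEIGHBOR_OFFSETS, skeletonize
from .synthetic import RootSpec, RootSystemSpec, ground_truth, render_mask
from .traits import Landmarks, extract_traits
from .config import RunConfig

SQRT2 = math.sqrt(2.0)


@dataclass
class Report:
    lines: list[str] = field(default_factory=list)
    ok: bool = True

    def check(self, name: str, passed: bool, detail: str) -> None:
        status = "PASS" if passed else "FAIL"
        self.lines.append(f"{status}  {name}: {detail}")
        self.ok = self.ok and passed


def _random_mask(rng: np.random.Generator, side: int = 48) -> BinaryRootMask:
    grid = rng.random((side, side)) < 0.45
    grid = ndi.binary_closing(grid)
    return BinaryRootMask(grid)


def _brute_total_length(grid: np.ndarray) -> float:
    """Total geodesic length by direct pixel-pair counting.

    Every 8-adjacent skeleton pixel pair contributes one step except pairs
    internal to a junction cluster (both degrees ≥ 3), mirroring how chains
    terminate at node pixels.
    """
    pts = {(int(y), int(x)) for y, x in zip(*np.nonzero(grid))}
    deg = {}
    for y, x in pts:
        deg[(y, x)] = sum(((y + dy, x + dx) in pts)
                          for dy, dx in NEIGHBOR_OFFSETS)
    total = 0.0
    for y, x in pts:
        for dy, dx in NEIGHBOR_OFFSETS:
            q = (y + dy, x + dx)
            if q in pts and (y, x) < q:
                if deg[(y, x)] >= 3 and deg[q] >= 3:
                    continue
                total += SQRT2 if dy and dx else 1.0
    return total


def run(length_perturbation: float = 1.0) -> Report:
    rep = Report()
    rng = np.random.default_rng(20260926)

    # 1. skeleton topology preservation
    bad = 0
    for _ in range(15):
        m = _random_mask(rng)
        s = skeletonize(m)
        n_m = ndi.label(m.grid, structure=STRUCT8)[1]
        n_s = ndi.label(s.grid, structure=STRUCT8)[1]
        if not (s.grid <= m.grid).all() or n_m != n_s:
            bad += 1
        if not (skeletonize(s.as_mask()).grid == s.grid).all():
            bad += 1
    rep.check("skeleton topology (subset/components/idempotence, 15 masks)",
              bad == 0, f"{bad} violations (tolerance 0)")

    # 2. graph total length vs brute-force pixel-pair enumeration
    worst = 0.0
    for _ in range(20):
        s = skeletonize(_random_mask(rng, side=40))
        g = build_graph(s)
        impl = g.total_length_mm() * length_perturbation
        ref = _brute_total_length(s.grid)
        worst = max(worst, abs(impl - ref))
    rep.check("graph geodesic length vs brute-force enumeration (20 skeletons)",
              worst < 1e-6, f"max |Δ| = {worst:.2e} px (tolerance 1e-6)")

    # 3. straight-root length recovery within 5%
    worst_pct = 0.0
    for i, (heading, length) in enumerate([(0.0, 25.0), (35.0, 18.0),
                                           (-60.0, 22.0)]):
        spec = RootSystemSpec(
            grain=(120.0, 20.0),
            roots=(RootSpec(heading_deg=heading, emergence_has=0.0,
                            growth_rate_mm_h=1.0, max_length_mm=length),),
            height=200, width=240, scale_mm_per_px=0.2, rng_seed=i,
        )
        t = length  # 1 mm/h: fully grown at t = length hours
        mask = render_mask(spec, t)
        rec = extract_traits(
            mask, Landmarks(grain=spec.grain, seed_exclusion_radius_px=0.0),
            RunConfig(scale_mm_per_px=spec.scale_mm_per_px),
        )
        gt = ground_truth(spec, t)
        err = abs(rec.total_root_length - gt.total_length_mm) \
            / gt.total_length_mm * 100
        worst_pct = max(worst_pct, err)
    rep.check("straight-root total-length recovery (3 cases)",
              worst_pct <= 5.0, f"max error {worst_pct:.2f}% (tolerance 5%)")
    return rep
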