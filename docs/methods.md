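# Methods

## Pipeline model

A rhizobox time-lapse is modelled as an ordered sequence of frames with
timestamps in hours after sowing (HAS). When only frame indices are
available, timestamps are `start_has + index × interval/60`; the default
capture interval is 4 minutes, and analysis typically runs on every 10th
frame (a 40-minute cadence). Coordinates are 0-based pixels, x rightward,
y downward; physical calibration is one isotropic mm-per-pixel factor
(default 1.0, i.e. pixel units — rhizobox setups rarely publish a
calibration, so none is assumed).

Per frame the pipeline is:

1. **Binarization.** Three rules: fixed threshold on a named channel,
   per-channel colour box (for manually traced overlays in a saturated
   colour), or automatic Otsu threshold (between-class-variance maximum)
   on grayscale. Foreground is the root system.
2. **Cleanup.** 8-connected components below `min_object_px` are removed,
   then 4-connected background holes below `fill_holes_max_px` filled.
   Removal precedes filling so a speck inside a hole joins that hole
   before filling is decided; this order makes the operation idempotent.
   A disk of `seed_exclusion_radius_px` (default 10 px) around the grain
   landmark is excluded so the grain body never counts as root.
3. **Thinning.** scikit-image's two-subiteration parallel thinning
   (Zhang's method) followed by a sequential simple-point reduction:
   raster-order deletion of every pixel whose 8-neighbour foreground is
   one 8-component and whose 4-adjacent background is one 4-component
   (precomputed for all 256 neighbourhood configurations), skipping
   endpoints and isolated pixels, until the set is irreducible.
   Irreducibility is what makes thinning idempotent — plain parallel
   thinning is not a fixed point of itself near degree-3 clumps. The
   result preserves 8-component and 4-hole counts exactly; foreground
   connectivity is 8, background 4, the border is background.
4. **Graph construction.** Skeleton pixels of degree 1/≥3/0 become
   endpoint/junction/isolated node pixels; 8-connected clumps of junction
   pixels merge into one node at their rounded centroid (thinning
   produces such clumps at crossings). Maximal degree-2 chains become
   edges with the geodesic pixel metric (1 axial, √2 diagonal) × scale;
   parallel edges and self-loops are kept; an all-degree-2 component is a
   pure cycle anchored at its lexicographically smallest (y, x) pixel.
   The union of edge chains and node pixels reconstructs the skeleton
   exactly, which the tests assert.
5. **Spur pruning.** Terminal edges shorter than `spur_min_px` (default
   5 px, enough to remove 1–3 px thinning barbs at a 3 px stroke without
   touching lateral roots) are removed shortest-first; after each removal
   the pixel set is re-thinned and the graph rebuilt, which dissolves
   junctions reduced to degree 2 and guarantees the pruned graph equals
   the graph of the pruned skeleton. An edge that is the only edge of its
   component is never removed.
6. **Traits** (see README for definitions). Trait-level lengths and tip
   positions use the subpixel refinement below; graph-level edge lengths
   remain the raw geodesic metric, which is what the spur threshold, the
   exported graph JSON and the enumeration oracles use.

## Subpixel centerline refinement

The raw (1, √2) chain metric overestimates oblique digital lines by up to
+8.2% (worst at 22.5°), and thinned tips sit up to ~2 px inside or beyond
the true root end — both far larger than the few-percent accuracy the
trait layer targets. Reported lengths are therefore measured on a refined
centerline: each chain pixel is moved to the midpoint of the mask
cross-section perpendicular to the locally smoothed tangent (boundary =
0.5 level of the bilinearly interpolated mask, located by bisection); the
refined polyline is smoothed with a 5-point moving average and its
Euclidean arc length summed. At a free tip the chain is trimmed by the
local half-width r̂ (median cross-section half-width) and extended along
the outgoing tangent to the boundary minus r̂ — for a round-capped stroke
the centerline end lies exactly half a width behind the mask boundary.
Junction-side chain ends are neither trimmed nor extended. Chains under
6 px fall back to the raw metric. On stroke-3 synthetic capsules the
refined estimate is within 3% of truth across all orientations and
lengths 20–150 px; refined tip positions feed the RGA/SRGA angles.

## Seed anchoring and tip identification

Seed-anchored paths start at the skeleton location nearest the grain.
When that location is a mid-chain pixel rather than a node — two roots
diverging from the grain thin into a single V-shaped chain — the edge is
split there and a degree-2 anchor node inserted; otherwise the longest
"root" would run tip-to-tip. The primary root is the maximum-length
simple path from the anchor to any endpoint (exhaustive DFS; root graphs
are small), with ties broken toward the lexicographically smallest
terminal. Seminal tips are found by partitioning endpoints by the first
edge of their best seed-anchored path; a group whose members share that
edge is re-partitioned from the far end of it, descending to the actual
divergence node — necessary when crossing strokes pinch a background hole
and the near-grain topology is a loop. Within a group the tip farthest
from the grain wins; groups rank by path length. This length-order rule
(rather than emergence order, which a single frame cannot know) is a
documented choice and can be overridden with manual tip coordinates.

## Emergence detection

Emergence is the first timestamp whose root area (after seed exclusion)
reaches `min_emergence_area_px` (default 20 px ≈ a 7 px root segment at
stroke 3) and stays there for two consecutive frames; the persistence
requirement rejects single-frame speckle. Detection error is bounded by
one inter-frame interval plus the time the root needs to grow past the
area threshold, so the default study conditions use an elongation rate
(2 mm/h at 0.2 mm/px) for which that growth takes under one 40-minute
analysis interval.

## Synthetic study conditions

The generator emulates a monocot seedling in a rhizobox: roots emerge
from a grain point with an initial heading (degrees from the downward
vertical, positive toward image right), elongate at a constant rate
capped at a maximum length, bend with constant curvature plus seeded
per-step Gaussian wobble, and are rasterized by sweeping a disk of half
the stroke width along the centerline (round caps). Full trajectories are
traced once per seed in 0.5 px arc steps; the state at time t is an
exact-arc-length prefix, so frames are mutually consistent and all
outputs are bit-reproducible for a given seed.

Genotype stand-ins contain exactly the two seminal roots whose
inter-heading defines the SRGA: ±54.65° ("GP-like", 109.3°) and ±31.35°
("BCC93-like", 62.7°), first emergence 64 HAS and second 70 HAS (the
observed emergence window), 2 mm/h, 0.2 mm/px, 3 px stroke, 360×260 px
frames. Between-plant variation is modelled as seeded Gaussian noise on
the initial headings; the ground truth tracks the noisy headings, so
recovery tests measure the pipeline, not the noise. Ground-truth hull and
bounding-box values refer to centerline vertices; helpers based on the
shapely-buffered centerline provide the half-stroke-inflated values the
mask-derived traits estimate.

What the generator does not emulate: soil texture or illumination
(masks are ideal, so thresholding robustness to real imagery is not
covered by these tests), root diameter variation, gravitropic response
beyond constant curvature, overlapping root systems of neighbouring
plants, or camera distortion.

## Numerical choices and degenerate inputs

- Convex hull of < 3 or collinear pixel centers: area 0. A mask-pixel
  hull of a thin root is orientation-dependent between the hulls of the
  centerline buffered by (w−√2)/2 and by w/2; tests assert that interval
  rather than a single corrected scalar.
- Bounding-box width uses the inclusive pixel extent (a single pixel is
  1 px wide).
- A frame with no root material yields a zero record with absent angles;
  per-frame failures never abort a series.
- RGA needs one tip; SRGA needs two distinct root groups — absent
  otherwise. A tip coinciding with the grain is an error (undefined
  angle).
- Thinning is deterministic but raster-order passes are tip-asymmetric:
  under 90° rotation skeletons agree exactly except within ~2 px of the
  tips. Trait invariance tests use tolerances accordingly (areas exact,
  lengths to 2%, angles to 1°).
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); equal seeds give byte-identical frames,
  graphs and CSVs.

## Problem sizes in the test suite

Topology checks run on 50 random 64×64 masks; graph-oracle equivalence on
100 random ≤40×40 skeletons against a brute-force maximal-chain
enumerator; longest-path checks on ≥33 small graphs (≤12 edges, trees and
cyclic) against networkx path enumeration; recovery on 20 seeded
single-root scenes plus 6 two-root scenes; the genotype comparison on 200
seeded replicates of 7 vs 4 plants (Mann–Whitney at α = 0.05). These
sizes keep the full suite within a few minutes on one CPU while leaving
every tolerance comfortably non-trivial.
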