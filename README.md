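# rhizotrace

Root-system-architecture (RSA) phenotyping from time-lapse rhizobox images.

Rhizoboxes — thin, glass-fronted soil containers — let a seedling's roots
grow in a quasi-2D plane in front of a fixed camera. `rhizotrace` turns
such frame sequences into quantitative growth curves: each frame is
thresholded to a binary root mask, thinned to a one-pixel skeleton,
converted to a graph of root tips and branch points, and measured. It is
aimed at plant scientists tracking early monocot (e.g. barley) root
development, where the traits of interest are root lengths, spread, and
the angles of the seminal roots.

## The measurements

For a mask *M* with isotropic scale *s* (mm/px), skeleton graph
*G = (V, E)* with pixel-chain edges, and grain (seed) position **g**:

- **root area** — |*M*| · *s*²;
- **total root length** — Σ₍e∈E₎ ℓ(e), where chain length uses the
  geodesic pixel metric (1 per axial, √2 per diagonal step) at graph
  level, and a subpixel-refined centerline estimate for reported traits
  (see `docs/methods.md`);
- **longest root** — the maximum-length simple path in *G* from the node
  nearest **g** to any tip, found by exhaustive depth-first enumeration;
  this path is designated the primary root;
- **primary root angle** — orientation of the principal axis (dominant
  eigenvector of the coordinate covariance) of the primary path's pixels,
  in (0°, 180°] to the image horizontal;
- **convex hull area / bounding-box width** — of the mask foreground;
- **RGA** (root growth angle) — arctan(|Δy|/|Δx|) of the grain→farthest-tip
  line, in [0°, 90°] to the horizontal through the grain;
- **SRGA** (seminal root growth angle) — arccos of the normalized dot
  product of the grain→tip vectors of the first two seminal roots, in
  [0°, 180°];
- **emergence time** — first timestamp (hours after sowing, HAS) at which
  the root area outside the seed region reaches a threshold for two
  consecutive frames.

A parametric generator (`rhizotrace.synthetic`) renders monocot root
systems — grain point, headings, emergence times, elongation rates,
curvature, seeded wobble, stroke width — with exact analytic ground truth,
and is what the test suite measures the pipeline against.

## Worked example

Render a synthetic "GP-like" genotype stand-in (two seminal roots,
inter-heading 109.3°, first emergence 64 HAS) and measure it:

```sh
rhizotrace synth demo --preset gp-like --seed 5 --interval-min 40 \
    --duration-h 12 --start-has 60
printf 'scale_mm_per_px = 0.2\nthreshold = fixed:gray>127\nseed_exclusion_radius_px = 0\nmin_object_px = 10\n' > demo.cfg
rhizotrace emergence demo --grain 180,28 --config demo.cfg
rhizotrace series demo --grain 180,28 --config demo.cfg --out demo.csv
```

which prints

```
emergence: 64.67 HAS
[rhizotrace] 19 frames; emergence at 64.66666666666667 HAS -> demo.csv
```

The first root emerged at 64.0 HAS in the generator; at the 40-minute
analysis cadence the first sustained detection lands one frame later
(64.67 HAS). `demo.csv` holds one row per frame with the trait columns
above; the last frame (72 HAS) of this run measures
`total_root_length = 19.89` mm against a ground truth of 20.0 mm of grown
root, and `srga = 111.76°` against the generator's tip-vector ground
truth of 111.70° (the nominal 109.3° inter-heading plus this seed's
growth wobble).

The same operations are available as library calls
(`rhizotrace.extract_traits`, `rhizotrace.compute_series`,
`rhizotrace.synthetic.render_series`), which is the more convenient route
inside analyses.

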