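# turpeval

Synthetic prostate-phantom imaging and quantitative scoring of transurethral
resection (TURP) performance.

The package generates digital two-zone prostate phantoms (bright
contrast-agent central zone, dimmer peripheral zone, dark water-filled
urethra, agar embedding) as pseudo-ultrasound slice stacks, simulates
skill-parameterized resections with known ground truth, segments the images
automatically, and scores each pre/post case with three morphometric
parameters:

- **preservation** — mean per-slice ratio of post/pre minimum
  peripheral-zone thickness (safety; 1.0 when the peripheral zone is
  untouched, 0 at a perforation),
- **smoothness** — mean cavity solidity (area / convex-hull area; 1 for a
  convex resection boundary),
- **circularity** — mean post/pre ratio of 4πA/P² of the resection cavity
  (symmetry of the resection around the urethra).

Scores are normalized to percent, compared across operators with two-sample
t-tests (α = 0.01) and displayed on a radar chart.  A mechanics submodule
computes the flat-punch indentation modulus E = 2(1−ν²)qa/w used to validate
phantom materials (note: `a` is the punch *radius* and `q` the mean contact
pressure F/πa² — the only dimensionally consistent reading of the formula).

## Layout

| module                  | purpose                                             |
|-------------------------|-----------------------------------------------------|
| `turpeval.phantom`      | phantom geometry, resection simulation, B-mode rendering |
| `turpeval.segmentation` | hierarchical-Otsu + topology slice segmentation     |
| `turpeval.metrics`      | per-slice and aggregated performance parameters     |
| `turpeval.scoring`      | percentage scorecards, t-tests, radar chart         |
| `turpeval.mechanics`    | cyclic indentation traces → elastic modulus         |
| `turpeval.io` / `cli`   | TIFF+JSON bundles, CSV/JSON tables, CLI pipeline    |

## CLI

```sh
# nine-case design: three operators x three phantoms
turpeval simulate --operators expert,fellow,amateur --cases 3 --outdir runs --seed 1

# segment + score one case (or bypass segmentation with ground-truth labels)
turpeval evaluate --case-dir runs/expert_case0
turpeval evaluate --case-dir runs/expert_case0 --use-ground-truth

# scorecards, pairwise t-tests, radar chart
turpeval score --group expert=runs/expert_case0/metrics.json,... --outdir scores

# indentation modulus from a (time, displacement, force) CSV
turpeval modulus trace.csv --header trace.json --out modulus.json

# everything end-to-end from one config/seed
turpeval all --seed 1 --outdir runs
```

All stages accept a YAML/JSON config (`--config`) whose blocks mirror
`PhantomSpec`, `SkillProfile`, `NoiseModel` and `SegmentationParams`; every
block is validated before any stage runs.  One top-level seed reproduces all
label/image/table artifacts byte-identically.

Units: lengths mm, areas mm², pressures Pa.

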