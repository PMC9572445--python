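# nichemetry

Image analysis for 3-D "micro-ruler" cell scaffolds: parametric geometry of
a graded wall-and-niche scaffold, synthetic hyperspectral confocal phantoms
with known ground truth, spectral linear unmixing, per-chamber cell-packing
statistics against an isotropic baseline, and nucleus tracking with
motility gradient maps.

## The problem

Two-photon-polymerized scaffolds made of thin vertical walls create
chambers and niches whose dimensions (niche sizes 10–70 µm, wall
separations 20–55 µm) bracket the size of an epithelial cell (~15 µm).
Imaging cells inside them is hard for two reasons: the polymer
autofluoresces far more brightly than the stains, and "how much does the
geometry influence the cells?" needs a quantitative null.  This package
implements the full analysis chain for such experiments:

1. **Geometry** — closed forms for chamber footprints
   (niche x separation), opening sizes (separation − 15 µm), and the
   *isotropic niche ratio* `min(1, 2·d/s)` with contact depth d = 7.5 µm:
   the fraction of uniformly distributed material expected within contact
   distance of a wall (0.75 / 0.60 / 0.43 / 0.27 for s = 20/25/35/55 µm).
   Measured ratios above this curve mean the scaffold actively recruits
   cells to its walls.
2. **Spectral unmixing** — per-voxel non-negative least squares
   `min ‖E·a − y‖, a ≥ 0` over four endmembers (scaffold, nuclei,
   cytoplasm, background) separates the quenched-but-still-dominant
   autofluorescence from the stain signals in 32-channel lambda-mode
   stacks.
3. **Packing** — per-chamber abundance totals normalized to the 200 µm²
   reference chamber, and niche-contact ratios vs the isotropic curve.
4. **Tracking** — nuclei detected on bottom (7-slice) / top (5-slice)
   partition projections and linked greedily within a radius of N pixels
   (N = 10 → 16.6 µm), two passes, 5-of-6-timepoint minimum; total path
   lengths render into blue-to-red gradient maps clipped at 30 µm.

Everything runs on a synthetic phantom (module `nichemetry.phantom`) that
emulates the acquisition — 12 slices x 2 µm, 1.66 µm/px, 6 timepoints at
65 min — so every statistic is checked against ground truth.  See
`docs/methods.md` for models, conventions and limitations.

## Worked example

```python
import numpy as np
import nichemetry as nm
from nichemetry.pipeline import run_packing_experiment, class_niche_ratios

model = nm.build_scaffold()
print(len(model.chambers), nm.scaffold_volume(model))
# 84 10483200.0        <- 84 chamber classes, 840 x 520 x 24 µm³ bounding box

tables = [run_packing_experiment(200, niche_bias=0.5, seed=s) for s in range(3)]
pooled = class_niche_ratios(tables, endmember="nuclei")
for sep, row in pooled.iterrows():
    print(f"separation {sep:g} µm: niche ratio {row.niche_ratio:.3f}, "
          f"isotropic {row.isotropic_ratio:.2f}")
```

which prints (seeds 0–2):

```
separation 20 µm: niche ratio 0.859, isotropic 0.75
separation 25 µm: niche ratio 0.832, isotropic 0.60
separation 35 µm: niche ratio 0.710, isotropic 0.43
separation 55 µm: niche ratio 0.629, isotropic 0.27
```

Half of the synthetic cells were seeded in wall contact (`niche_bias=0.5`),
and the recovered ratios sit near the analytic mixture
`0.5 + 0.5 x isotropic` — e.g. 0.64 expected vs 0.63 measured at 55 µm —
far above the isotropic null, i.e. the chain detects wall-contact
enrichment quantitatively.

## Analysis drivers

Numbered scripts under `analysis/` run the studies end to end and write
tables/figures to `results/` (use `--out` to redirect):

| script | what it does |
|---|---|
| `01_scaffold_geometry.py` | chamber table, design closed forms, label-mask raster |
| `02_autofluorescence_quench.py` | simulate + fit the exponential UV quench (22% at 150 min) |
| `03_render_and_unmix.py` | hyperspectral phantom, ROI endmembers, NNLS unmixing, masked views |
| `04_cell_packing.py` | niche-bias sweep: densities and niche ratios vs the isotropic curve |
| `05_motility_tracking.py` | time-lapse, tracking, motility table, gradient maps |

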