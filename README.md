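# ptcmorph

Quantitative morphometry of peritubular capillaries (PTCs) — the
postglomerular microvessels supplying the kidney tubules. Chronic
tubulointerstitial injury not only rarefies PTCs but changes their shape:
profiles that are elongated in healthy cortex become rounder with injury.
`ptcmorph` implements the full analysis chain for quantifying this, for
renal physiologists and image-analysis developers:

* **2D segmentation** of endothelium-stained (ring-like) capillary
  profiles: contrast normalisation, Gaussian smoothing (σ = 2.5 px), local
  adaptive thresholding (Bernsen or Phansalkar, r = 35 px), and
  dilate/fill/erode to obtain filled lumens;
* **morphometry**: area, perimeter, bounding box, moment-equivalent
  ellipse, Feret diameters, and the shape factors
  `circularity = 4π·A/P²` (1 for a perfect circle) and
  `roundness = 4A/(π·d_major²)` (the minor/major axis ratio of the
  area-matched moment ellipse), with the 10–8000 µm² size filter and
  area-fraction density;
* **inter-capillary spacing** via a nearest-vessel Euclidean watershed
  partition (mean shortest boundary-to-boundary distance over neighbor
  pairs);
* **shape statistics**: 0.05-bin distribution summaries
  (mean/median/mode/SD/IQR), ROC curves with Youden-optimal cutoffs
  (shipped defaults: roundness ≥ 0.47, circularity ≥ 0.60 per capillary;
  mean circularity ≥ 0.51 per region), Spearman correlation,
  Mann–Whitney / Kruskal–Wallis + Dunn–Bonferroni tests;
* an **oxygen unit-cell model**: steady zero-order diffusion–consumption
  `α·D·∇²PO₂ = R` around one capillary of circular, elliptical (aspect 2)
  or square cross-section in a periodic square tissue cell, Dirichlet
  `PO₂ = P₀` at the capillary surface and no-flux cell edges — predicting
  how cross-sectional shape affects the homogeneity of tissue oxygenation;
* a **3D pipeline** for light-sheet vasculature volumes: isotropic
  resampling, plane-wise Hessian "tubeness" (σ = 4 µm), global threshold
  (t = 100), 3D thinning, and skeleton-graph metrics (volume fraction,
  total length, branch points, segments, mean segment length, tortuosity =
  path length / end-to-end distance);
* **synthetic generators** with analytic ground truth for every stage.

Conventions: images are (row, column) arrays, 0-based, pixel centers at
integer coordinates; every physical output is in µm / µm²; the µm/pixel
calibration is a required input (it is never inferred from magnification).

## Worked example

Generate a control-like (elongated) and an injury-like (rounder) synthetic
scene of 200 ring-stained capillaries each, run the pipeline, and compare:

```python
import numpy as np
from ptcmorph import RunConfig, segment, measure_mask, mean_capillary_distance
from ptcmorph.synthdata import make_scene_2d

for cond in ("control_like", "injury_like"):
    scene = make_scene_2d(200, cond, seed=1)
    cfg = RunConfig(pixel_size=scene.image.pixel_size)
    mask = segment(scene.image, cfg)
    recs = measure_mask(mask, size_min=cfg.size_min, size_max=cfg.size_max)
    print(cond, len(recs),
          round(np.mean([r.roundness for r in recs]), 3),
          round(np.mean([r.circularity for r in recs]), 3),
          round(mean_capillary_distance(mask), 1))
```

prints

```
control_like 201 0.391 0.714 39.2
injury_like 200 0.740 0.973 43.7
```

— 200-odd capillaries recovered per scene; the injury-like population is
much rounder (mean roundness 0.740 vs 0.391, mean circularity 0.973 vs
0.714), matching the generator's analytic truth (0.739/0.378 roundness,
0.950/0.684 circularity) to within a few hundredths, and capillaries are
farther apart. The oxygen model for a circular capillary gives

```python
from ptcmorph.oxygen import UnitCellSpec, solve_po2
f = solve_po2(UnitCellSpec(shape="circle", cell_length=20, capillary_area=80))
print(round(f.mean_tissue_po2, 2), round(f.min_po2, 2))   # 44.24 43.8
```

for the physiological cell (density 80/20² = 0.20) versus a mean of
42.92 mmHg in the pathological cell (62.5/25² = 0.10): sparser, smaller
capillaries lower tissue PO₂, and of the three cross-sections the circle
delivers the most homogeneous PO₂ along the cell edge.

The same stages are available from a shell:

```sh
ptc simulate scene2d --preset injury_like --n 200 --seed 1 -o scene.tif --truth truth.csv
ptc segment scene.tif --pixel-size 0.5 --method bernsen -o mask.tif
ptc measure mask.tif --pixel-size 0.5 -o records.csv --summary summary.csv
ptc spacing mask.tif --pixel-size 0.5 -o distances.csv
ptc oxygen --case pathological --shape ellipse --report oxygen.json
ptc skeleton stack.tif --voxel 1,1,2 -o graph.json
```

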