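# sldt — multiparametric scrape-loading/dye-transfer assay quantification

`sldt` turns three-channel fluorescence micrographs of cut-loaded cell
monolayers into quantitative endpoints for gap-junctional intercellular
communication (GJIC), cell density and viability, and carries them through
control normalization, group statistics and EC50 estimation.

**Who it is for.** Labs running the scrape-loading/dye-transfer (SL-DT)
assay in dishes or microplates: a straight cut through a monolayer loads the
cells along the wound with a gap-junction-permeant tracer (Lucifer Yellow)
and a loading marker (propidium iodide, PI); the tracer then spreads into
neighbouring cells through gap junctions, so the width of the stained band
measures coupling. Outside the cut, PI additionally marks dead cells and
Hoechst 33342 marks all nuclei, giving density and viability from the same
images.

## The quantities computed

Per image (areas in µm², via the scalar µm/px calibration):

* **net dye-transfer area** `A_net = max(0, A_LY − A_PI)` — tracer-stained
  area minus the loaded-cell area restricted to the detected cut band;
* **total cells** — watershed-split nuclei whose centroid lies outside the
  exclusion zone (cut band + 100 µm margin);
* **dead cells, viable = total − dead, % dead = 100·dead/total**.

Per experiment, endpoints are divided by the vehicle-control mean (fraction
of control, FOC; control mean ≡ 1.0), treated groups are compared with the
control by one-way ANOVA + Dunnett (or Kruskal–Wallis + Dunn when normality
or variance diagnostics fail), and concentration–response data are fitted
with a 4-parameter logistic

```
f(c) = bottom + (top − bottom) / (1 + (c / EC50)^hill)
```

one fit per independent experiment, summarized as the geometric-mean EC50
with a t-based 95% CI on the log scale.

A synthetic-image generator renders the whole assay geometry (jittered cell
lattice, wound, loaded row, coupling-dependent tracer band, dead cells,
noise) with exact ground truth, so every stage is testable without
microscope data.

## Worked example

```python
import numpy as np
from sldt import (SimConfig, generate_dose_series, analyze_cut,
                  compute_foc, fit_4pl)

base = SimConfig(image_height_px=675, image_width_px=900, pixel_size_um=1.0,
                 max_transfer_halfwidth_um=250.0, dead_fraction=0.05)
concs = [0.1, 0.25, 0.6, 1.5, 4.0, 10.0, 40.0]
series = generate_dose_series(base, concs, fourpl=(0.0, 1.0, 1.2, 1.5),
                              n_replicates=3, seed=11)

nets, ctrl, cvals = [], [], []
for cs, _ in series:
    net = analyze_cut(cs).net_transfer_area_um2
    (ctrl if cs.meta.is_vehicle_control else nets).append(net)
    if not cs.meta.is_vehicle_control:
        cvals.append(cs.meta.concentration)

recs = compute_foc(nets, ctrl, concentrations=cvals)
print(fit_4pl([r.concentration for r in recs], [r.foc for r in recs]).summary())
```

prints

```
4-parameter logistic concentration-response fit
================================================
experiment: -   n obs: 21
converged:  True   SSE: 0.00470575
------------------------------------------------
param           estimate       std err
bottom        -0.0259767    0.00872909
top              1.02367     0.0127083
hill             1.43062     0.0593743
ec50             1.09063     0.0331948
```

— the pipeline recovered the generating EC50 of 1.2 (here in nM) as 1.09
(−9%) from 24 noisy images, with the top asymptote at the control level
(FOC ≈ 1) and a Hill slope near the generating 1.5.

For whole plates there is a CLI: `sldt simulate` writes a synthetic plate
(TIFFs + ground truth + layout), `sldt analyze --images DIR --layout
layout.yaml --out OUT` writes per-image/per-well CSVs, FOC tables, group
statistics, EC50 summaries and a JSON run log, and `sldt stats` re-runs the
statistics on an existing FOC table.

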