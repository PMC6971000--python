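# Methods

## The assay and its endpoints

In the scrape-loading/dye-transfer (SL-DT) assay a blade cut through a cell
monolayer transiently opens the membranes of the cells along the wound.
These cells take up both a small gap-junction-permeant tracer (Lucifer
Yellow, LY) and a loading marker (propidium iodide, PI, or a high-molecular-
weight dextran that cannot pass gap junctions). The tracer then diffuses
junctionally into neighbouring rows of cells; the loading marker stays in
the loaded row. The per-image GJIC endpoint is therefore the *net*
dye-transfer area

    A_net = max(0, A_tracer − A_loaded),

the tracer-stained area minus the loaded-cell area. Outside the cut region,
PI only enters cells with compromised membranes (dead cells) and Hoechst
33342 stains all nuclei, so the same three channels also yield cell density
(total nuclei), dead cells, viable cells (total − dead) and % dead
(100·dead/total). All areas are converted to µm² by a scalar square-pixel
calibration; the documented default is 1396 µm / 1936 px ≈ 0.72107 µm/px,
under which a 1936 × 1460 px field spans 1396 × 1053 µm.

Endpoints are normalized per experiment to the mean of the matched vehicle
controls (fraction of control, FOC; control-group mean ≡ 1.0 by
construction). % dead is reported unnormalized.

## Image analysis

Both measurement primitives share one segmentation: Gaussian smoothing
(default σ = 1 px) → global threshold (Otsu by default; triangle and fixed
offered) → Euclidean closing (1 px) → hole filling → removal of objects
below a minimum area (100 µm² for tracer fragments, 30 µm² for nuclei —
debris exclusion at 10× magnification). The smoothing σ of 1 px was chosen
after a bias analysis on simulated disks: σ = 2 px bridges near-touching
cells in the dense loaded row and inflates its area by ~8%, while σ = 1 px
keeps both tracer and loaded areas within ±1.5% of geometric truth. All
morphology uses distance-transform operators, which are exact Euclidean and
fast at any radius.

Auto-thresholding a signal-free channel would binarize noise, so a contrast
guard (foreground–background mean separation below 3 background SDs)
returns an empty mask with a `blank_channel` QC flag instead of raising.

Nuclei are counted by refining the foreground mask with a watershed on the
smoothed (σ = 1 px) Euclidean distance transform, seeded at local maxima
with a minimum separation of one nucleus radius (5 px default); ties
resolve in row-major order, making the labelling deterministic. Objects are
attributed to regions by the centroid-in-region rule, which keeps boundary
handling unbiased; nuclei fused beyond what the distance transform can
separate count as one — no heuristic over-splitting.

The cut band is detected on the red channel: closing with a 20 µm radius
merges the loaded-row cells into one structure; the largest connected
component qualifies as a cut if its major/minor axis ratio is ≥ 5
(distinguishes the loading row from scattered dead cells), and is dilated
by 5 µm into the measurement band. The loaded-area measurement is restricted
to this band by default (a config switch measures the whole-image red mask
instead). If no sufficiently elongated structure exists the image is flagged
`cut_not_found` and callers fall back to the whole-image red mask. The
exclusion zone for density/viability is the detected band dilated by a
100 µm margin — wide enough that loading-derived PI signal in the first
rows is never scored as death — and the same zone object is shared by both
counters so the two counts refer to the same region. Negative net areas are
clamped to zero with a `clamped_negative` flag (negative transfer is
physically meaningless; the flag preserves auditability).

## The synthetic-data generator

The generator renders assay *geometry*, not photophysics: cells are disks
(radius 10 µm) on a square lattice (spacing 25 µm ≈ a confluent epithelial
monolayer, ~1600 cells/mm²) with uniform per-axis jitter (default ±10% of
the spacing). A straight cut line crosses the field; for axis-aligned cuts
the lattice is anchored on the line, so the wound (half-width 12 µm)
scrapes exactly one cell row and the loaded row is the complete adjacent
row — mirroring the single loaded row seen in real cut regions. Tracer
stains the whole-cell disks of all cells within `loaded row + g·D_max` of
the line, where g ∈ [0, 1] is the gap-junction coupling and D_max (default
250 µm) the maximal spread at full coupling. The red channel holds the
loaded row as whole-cell disks (scrape loading fills the cytoplasm with PI)
plus nucleus-sized disks (radius 5 µm) for dead cells, drawn Bernoulli(f_d)
among cells outside the exclusion zone; the nuclear channel stains every
surviving nucleus. Rendering uses two intensity levels (foreground 1000,
background 100 on a 16-bit scale) plus additive Gaussian noise (default
SD 90, i.e. SNR ≈ 10) and optional Poisson shot noise.

Ground truth is computed from the noiseless masks before noise is applied,
so it is exact by construction: the rendered foreground pixel set *is* the
geometric mask that defines the truth. Because loaded cells carry the same
whole-cell disk in both channels, `true_transfer = tracer mask − loaded
mask` holds as a pixel identity and is zero at g = 0. The ground-truth
exclusion zone is measured from the realized outer edge of the loaded row
(max loaded-centre distance + cell radius + margin); the analyzer's
detected zone differs from it only by morphological fuzz of a few µm at the
edge. Count truths use the same centre-in-zone rule the analyzers apply to
centroids.

Dose series set `g(c) = bottom + (top − bottom)/(1 + (c/EC50)^hill)` per
concentration, with vehicle controls at `g = top`; per-image seeds derive
from the master seed through counter-indexed `SeedSequence` children, so a
whole plate is reproducible from one integer.

What the generator does **not** emulate: continuum dye-diffusion kinetics,
optics/PSF blur, photobleaching, illumination gradients, cut-end artefacts
(only mid-cut fields are rendered), irregular cell shapes, and clustered
death. Passing tests therefore demonstrate the correctness of the
measurement pipeline on well-posed geometry, not robustness to every
pathology of real micrographs; the segmentation parameters remain
config-overridable for that reason.

## Statistics

Treated groups are compared with the vehicle control following a
diagnostics-driven tree: Shapiro–Wilk normality per group (n ≥ 3; smaller
groups cannot be tested and are not treated as rejections) and a
Brown–Forsythe (median-centred Levene) equal-variance test, both at the
comparison alpha. If all pass: one-way ANOVA with Dunnett's many-to-one
test (`scipy.stats.dunnett`, multivariate-t formulation, seeded quadrature),
or a two-sided t-test for two groups. Otherwise: Kruskal–Wallis with Dunn's
many-to-one rank test (tie-corrected z statistics, Bonferroni-adjusted over
the k comparisons — the standard nonparametric analogue of Dunnett), or
Mann–Whitney U for two groups. Any group with fewer than two observations
forces the rank branch with a QC note; fully degenerate data short-circuit
to p = 1 with a `degenerate_variance` flag. On a simulated null the
procedure's family-wise error sits at ~0.05 by construction of the Dunnett
adjustment; individual comparisons are necessarily more conservative.

The 4-parameter logistic is fitted by least squares (`scipy.optimize.
curve_fit`) with EC50 parameterized as log10(EC50); initial values come
from the data (top/bottom from extreme group means, EC50 from the
concentration nearest half-range, Hill ±1 by response direction). All four
parameters are free by default; the top asymptote can optionally be anchored
(e.g. at FOC = 1). Vehicle controls (c = 0) are excluded from the
likelihood — they anchor the top through the normalization itself. Flat
data (group-mean span < 0.1 FOC), optimizer failure, or an EC50 outside
100× the tested concentration range (no plateau information — any such
value would be an extrapolation) are reported as non-converged with NaN
EC50, never a fabricated number. Stimulators (FOC rising with
concentration) are the same model with negative Hill slope. Fits are
per independent experiment; experiment-level EC50s are combined as
`exp(mean(ln EC50))` with a t-based 95% CI on n − 1 df. The standard error
of EC50 is obtained from the log-scale covariance by the delta method.

## Problem sizes and numerical choices

Tests and the acceptance script simulate 675 × 900 µm fields at 1 µm/px
(425 × 600 for pure area checks), sized so that ≥ 200 cells per field
remain outside the exclusion zone — enough for % dead to be dominated by
binomial sampling (SD ≈ 1.4 pp at f_d = 0.1) rather than counting error —
while a full dose series (7 concentrations × 3 replicates + 3 controls)
renders and analyses in under a minute on one CPU. Field heights are chosen
so the anchored lattice never places a cell centre on an image border,
making count ground truth unambiguous. End-to-end EC50 recovery on such
series is within ±15% of the generating value (quantization of the transfer
band to whole cell rows is the dominant error source); fitting the
noiseless generating curve recovers EC50 to < 0.01%.

## Known limitations

* The transfer band advances in discrete cell rows, so simulated
  concentration–response curves carry row-quantization noise absent from a
  continuum model.
* Dead cells inside the tracer band are still rendered as tracer-positive;
  dying cells' loss of coupling is not modelled.
* Non-axis-aligned cuts do not use the anchored lattice, so their loaded
  row is ragged; area semantics are unchanged but count ground truth near
  the band is fuzzier.
* The comparison tree applies diagnostics at fixed alpha without accounting
  for the pre-testing (the usual practice it mirrors).
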