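# Methods

## Spatial model

A tissue map is a set of cells (point + radius, or labelled mask objects)
plus zymosan particles, which are immobile reference objects and never count
as cells. Two objects are **adjacent** when their boundary-to-boundary
distance is at most `threshold_px` (default 4 px, the neighborhood radius
used in this assay family).

* *Point mode* (cell tables): boundary distance = centre distance − r_a −
  r_b, with per-cell radii recovered from the area column.
* *Mask mode* (label images): pixels are modelled as unit squares, so the
  boundary gap between two objects is their minimal pixel-centre distance
  minus 1. Two 1-px objects with a 4-px gap of empty pixels are adjacent;
  with a 5-px gap they are not. Candidate pairs come from a KD-tree over
  object pixels, making the construction exact rather than an approximation
  through morphological dilation.

### Interaction likelihood and relative distance

For types A and B the observed count `c_obs` of unordered A–B edges
(within-type pairs are excluded from cross-type counts) is referred to a
null distribution generated by uniformly permuting the phenotype labels over
the fixed cell positions; zymosan labels are pinned. With `n_perm` draws
(default 1000) the mid-p likelihood is

    L = (#{c_perm < c_obs} + 0.5 · #{c_perm = c_obs}) / n_perm

and the relative distance is `d = 2(1 − L)`. Counting ties at half weight
makes L exactly unbiased under exchangeability (E[L] = ½, hence E[d] = 1 for
spatially random labels) and pins the endpoints: complete enrichment gives
L = 1, d = 0; complete avoidance with no tied permutations gives L = 0,
d = 2. If all cells carry one label the null is degenerate; the function
warns and returns the neutral L = ½, d = 1.

Note that `d` is a *calibrated rank*, not a concentration estimate: for a
single map whose labels are truly random, L is (discretely) uniform on
[0, 1], so a single-map d scatters over [0, 2] even under the null. Stable
architecture readouts therefore average d over replicate maps, exactly as
replicate animals are averaged in practice; the null-calibration test checks
the mean over 100 maps, not single draws.

`d(zymosan, M2-like)` is the **PI-region size**; intervention effects are
reported as percent of the matched control mean. The **dual-centered
network** places each phenotype at its relative distances to two anchors
(zymosan and M2-like by default; self-distance 0 by convention) and links
phenotype pairs with mutual d ≤ `link_threshold` (default 0.5).

## Resolution score

Input: paw-withdrawal latencies (seconds, 20 s cutoff) per animal, group and
timepoint, with a 0 h baseline.

* **Score 1** — two-way ANOVA (group × time) on the post-injection records
  (the 0 h baseline is excluded as a level; it enters only through Score 2's
  contrasts). Group contrasts at 24/48/72 h use the model's pooled residual
  variance and are Bonferroni-corrected over the three scoring timepoints
  (m = 3, α = 0.05). Significant increase toward baseline → +1, significant
  decrease → −1, otherwise 0. Cells with zero within-cell variance are
  rejected as degenerate.
* **Score 2** — per group, a one-way ANOVA across timepoints; each
  post-injection timepoint is contrasted against the group's own baseline
  (pooled variance, Bonferroni over the post-injection timepoints). The
  return-to-baseline time is the earliest timepoint from which the contrast
  is non-significant *at that timepoint and all later ones* — requiring
  persistence prevents a single noisy dip from counting as recovery. Each
  full day (24 h) the intervention returns earlier than control scores +2,
  each day later −2; fractional day gaps truncate toward zero. A group still
  significantly off baseline at the last timepoint gets an open-ended
  recovery, which is scored as one day past the observation horizon (the
  score cannot be driven arbitrarily far by an unobserved recovery); if
  neither group returns, Score 2 is 0 with a warning. When the pooled MSE is
  exactly zero (noise-free data) contrasts degenerate to exact comparisons
  of means.

The final score is the sum. Both components are antisymmetric under swapping
the group roles, and invariant to adding a constant to every latency.

## Phenotyping

Mean marker intensities are z-scored per marker over all cells (population
SD; zero-spread markers map to zero). A marker is "+" when z exceeds a
threshold (default 0 — the simplest reproducible surrogate for
cluster-annotation calls, exposed as a parameter). Gates, evaluated in
priority order with first match winning: neutrophil Ly6G+/F4-80−;
eosinophil SiglecF+; M1-like SiglecF−/F4-80+/CD86+/CD206−; M0
SiglecF−/F4-80+/CD86+/CD206+; M2-like SiglecF−/F4-80+/CD86−/CD206+; DC
CD11c+/F4-80− (the DC gate is a placeholder convention — no printed
definition exists for it). Unmatched cells are "other".

The clustering alternative builds a symmetrised k-nearest-neighbour graph on
the marker vectors (k = 20; the conventional range is 15–30), weights each
edge by the Jaccard overlap of the two cells' neighbour sets
(shared-neighbour weighting sharpens boundaries between marker populations)
and maximises weighted modularity greedily (resolution 0.8 — low enough that
well-separated populations are not split, high enough that the major myeloid
types separate; agreement with the gating labels on default synthetic maps
is ARI ≈ 0.83–0.97).

## Image preprocessing

Post-bleach subtraction is `max(fluor − postbleach, 0)` element-wise.
Optional flat-field correction divides by a σ = 50 px Gaussian blur
normalised to unit mean. Segmentation: Otsu threshold on the nuclear
channel, removal of components below `min_area_px` (default 5), watershed on
the distance transform seeded at local maxima (minimum separation 4 px),
then label expansion by `expand_px` (default 2) to approximate the cell
body, optionally restricted to the Otsu foreground of a membrane channel
(CD45) — membrane constraint is optional because CD45 is absent on
non-immune cells. A blank nuclear image yields an empty mask, not an error.

## Synthetic data

The generator emulates the study conditions, not microscopy physics.

**Tissue**: concentric regions around the field centre — core disk covering
30 % of the 512×512 px field (r ≈ 158 px), PI annulus to r ≈ 201 px, AI
annulus to r ≈ 251 px. 60 zymosan particles (radius 5 px) are placed
uniformly in the core; this density gives the core ~25–35 direct
cell-contact sites so the zymosan-centered statistics resolve the layering.
Per phenotype and region a Poisson count (density × area / 10⁴ px²) of cells
is placed uniformly, with minimum centre spacing 1.5 cell radii and no
zymosan overlap, by rejection sampling (10⁴ retries, then error). Default
densities (cells/10⁴ px²) put neutrophils in the core (8), M1-like in core
(3) and PI ring (8), M2-like in the AI ring (8), with M0, eosinophils and
DCs interspersed — no absolute densities are published for this model, so
these are order-of-magnitude choices that reproduce the qualitative
layering. `ring_offsets` translates one phenotype's sampling annulus
radially (negative = inward) and is how AI-ring displacement interventions
are emulated. Marker intensities are lognormal with per-phenotype means
(100 for "+" markers, 5 % of that for "−" markers) and CV 0.2; no published
intensity distributions exist, and lognormal with moderate CV is typical of
immunofluorescence. Optional rendering paints cells as disks per channel
(nuclei at half radius so neighbouring nuclei stay separable) and a label
mask; zymosan is not rendered.

**PWL**: latency starts at the 10 s baseline, drops by `drop_s` (default
6 s) at 24 h and relaxes linearly to baseline at the group's recovery hour;
per-group constant or per-timepoint offsets model intervention effects;
Gaussian residual noise (default 0.5 s) is added and values are clipped to
(0, 20 s]. Noise is **yoked across groups** (common random numbers per
animal index and timepoint): groups with identical effects are identical,
and group contrasts equal the designed effects exactly. This is a
variance-reduction design: within-group statistics keep independent noise,
but between-group significance tests see exactly the designed effect sizes,
so rule-level tests are not confounded by sampling luck.

**What passing tests do and do not show.** Regions are ideal annuli whereas
real lesions are irregular — acceptable because every downstream statistic
is geometry-agnostic. Markers are conditionally independent given the
phenotype, cells are disks, there is no autofluorescence, bleaching
kinetics, section artefacts or cell-shape variation; segmentation and
gating performance on these maps is therefore an upper bound, and the
round-trip test (±10 % phenotype-proportion recovery) validates the
plumbing, not real-tissue robustness.

## Pipeline

Interventions are compared against a shared control: per replicate
("animal", default 5) control and intervention maps share seeds so the only
systematic difference is the configured perturbation; PI sizes are averaged
over replicates before the percent-of-control ratio. Band assignment on the
percent change: |Δ| < 30 % small change; 30–50 % decrease moderate;
otherwise (stronger decrease, or an increase ≥ 30 %) strong change.
Cutpoints are configuration, not constants. Presets: `g2a_like` shifts the
M2 ring 64 px inward — calibrated on the generator so the expected PI-size
decrease is ~40 %, inside the moderate band — with recovery one day early
and small positive latency offsets; `meloxicam_like` shifts it 100 px inward
(>65 % decrease) with persistently lowered latencies.

## Numerical conventions and problem sizes

One master seed per run; all component seeds derive from it via seed
sequences (kept below 2³¹). Identical config + seed reproduces outputs
bit-for-bit. Z-scores use population (ddof 0) SD. Permutation defaults:
n_perm = 1000 for reported distance maps; the test suite uses 150–500 where
only calibration or ordering is asserted, 10⁴ for the exhaustive-oracle
comparison (maps of ≤ 8 cells, where full label enumeration is feasible).
Calibration and recovery suites use 100 spatially random maps (256² px), 20
replicate maps per ring displacement, and 200 simulated PWL experiments
(four designed effect grids × 50 seeds, n = 6 per group, 0.5 s noise) —
sizes at which the checked quantities' Monte-Carlo error is well inside the
asserted tolerances.

## Known limitations

* The continuous mid-p transform d = 2(1 − L) matches the printed 0–2 scale
  endpoints, but whether the original analysis used a continuous transform
  or significance bands is not documented; d values between the endpoints
  are this package's definition.
* With few zymosan contact sites, d is coarsely quantised; single-map
  mid-band values carry large variance (see above) and should be averaged
  over replicates.
* The ANOVA families (m = 3 scoring timepoints for Score 1; all
  post-injection timepoints for Score 2's contrasts) are conventions; the
  source protocol names the tests but not the correction families.
* Mast cells and "other" clusters have no printed marker definitions and are
  not generated or gated.
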