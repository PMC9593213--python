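# Methods

This note documents the models, parameter choices and numerical decisions
behind `neutromig`, and what its synthetic data does and does not
establish.

## Trajectory model

Cells are simulated as discrete-time random walks at the recording's frame
interval (default 10 s). A fraction `frac_responder` of cells senses the
gradient: their step directions are drawn from a von Mises distribution
centered on the gradient axis (+x in image coordinates, chemoattractant
increasing toward larger x) with concentration `kappa` (unitless, >= 0;
kappa = 0 is an unbiased walk). Non-responders draw uniform directions.
The von Mises family was chosen because it gives a single concentration
knob and a tractable Monte-Carlo oracle for the expected chemotactic
response, which is defined as P(net displacement along the gradient > 0)
and has no convenient closed form for finite walks.

Step lengths are Rayleigh distributed — the natural law for the magnitude
of an isotropic 2-D displacement — with scale set so the mean step equals
`speed x frame_interval`. Each cell's mean speed is drawn from
N(`speed_mean`, `speed_sd`) truncated at zero. Defaults are 8 ± 2 um/min:
primary human neutrophils in chemotaxis chambers typically migrate at
roughly 5–15 um/min, and no speed distribution is published for this assay,
so the default is an illustrative mid-range choice and is not revisited.

Arena walls reflect, conserving cell count as a closed chamber does.
Reflection is applied per step: a cell whose step crosses a wall is folded
back across it, and a gradient-biased cell therefore presses against the
far wall rather than bouncing backward. (Folding the *cumulative* walk,
an earlier implementation, silently reverses drift after wall contact; the
Monte-Carlo oracle exposed the error.) Consequence: in drift-dominated
settings the response saturates slightly below 1 because cells that start
near the far wall can end marginally behind their start.

## Rendering and segmentation

Cells are rendered as anti-aliased disks (coverage-weighted edge
intensities) of radius `cell_radius` (default 4 um) on a constant
background, plus additive Gaussian noise. Anti-aliasing is what makes
sub-pixel centroid recovery — and hence the <5% speed-error target —
possible at all; hard-rasterized disks quantize centroids to ~0.3 px.

Segmentation follows a three-class contract (background / cell boundary /
cell interior) so that externally produced probability maps can be dropped
in. The built-in generator is classical and deterministic: Gaussian
smoothing (sigma 1 px), a logistic intensity ramp between the robust
background level (median) and the bright-cell level (99.9th percentile)
for the foreground score s, and the normalized Sobel gradient magnitude for
the boundary score b; the triple ((1-b)(1-s), b, (1-b)s) sums to 1 by
construction. A frame whose 99.9th percentile lies within 6 robust noise
SDs of the median is declared empty (all background). Instances are
connected components of the foreground argmax with boundary pixels removed
first (splitting touching cells) and then re-assigned to the nearest
instance; components below `min_area` (default 20 um^2, about one third of
a neutrophil cross-section) are dropped. Centroids are intensity-weighted
after background subtraction.

## Linking

Per frame, open tracks are matched to detections by Hungarian assignment on
centroid distance with a hard gate of `max_disp` per elapsed frame. Pairs
left unmatched by the primary gate enter a second assignment pass at 3x the
gate: Rayleigh step lengths are heavy-tailed (P(step > 3 x mean) ~ 1e-3),
and without the rescue pass roughly 7% of tracks fragment over a 90-frame
window even at trivial densities. The relaxed pass only sees detections and
tracks the strict pass could not pair, so it cannot steal a confident
match. Tracks unseen for more than `max_gap` frames (default 2; at 10-s
sampling longer gaps are ambiguous) are closed; leftover detections start
new tracks.

## Quality control

Frames are 0-based; the analysis window runs from minute 15 to minute 30
inclusive — frames 90..180 at 10 s, i.e. 91 frames — because the gradient
is considered unstable earlier. A track observed in fewer than 50% of the
window's frames is removed (strict "<": 45 of 91 is removed, 46 kept).
Experiment flags:

* `low_cell_number` — fewer than 25 surviving tracks;
* `lateral_flow` — |median lateral migration index| (net displacement
  perpendicular to the gradient / path length) > 0.3. The underlying
  criterion in practice is visual; 0.3 marks flow strong enough to
  dominate a typical path;
* `pre_activated` — more than half of surviving tracks travel less than
  one cell diameter (default 8 um) in total; such cells have typically
  become stationary before the recording.

QC is idempotent: cropping and filtering a filtered set is a no-op.

## Features

Speed is the mean step speed (path length / elapsed time), not net
displacement over time: it is the standard single-scalar "speed" and is
insensitive to direction changes. Gradient precision is the forward
migration index, the standard directionality measure in chemotaxis
chambers. A net displacement projecting to exactly 0 counts as not
directed (conservative tie-break; only degenerate fixtures hit it).
Trajectories with fewer than two detections or zero path length are
excluded as non-movers.

Texture contrast is the grey-level co-occurrence contrast at distance 1
(four symmetric directions averaged) computed after quantizing in-mask
intensities to 16 levels, with an extra reserved level for out-of-mask
pixels whose co-occurrence rows/columns are discarded — only pixel pairs
fully inside the instance contribute, and a uniform instance scores
exactly 0.

Experiment profiles average every dynamic feature over tracks (morphology
is averaged per track over frames first, so long tracks do not dominate)
using compensated summation, making aggregation exactly
permutation-invariant. The chemotactic response is the fraction of
directed tracks.

## Harmonization

Order is fixed: correlation pruning -> covariate residualization ->
z-normalization. Pruning: while any pair has |Pearson r| above the
threshold (default 0.85), the member of the worst pair with the higher mean
|r| against all other remaining features is dropped; ties keep the earlier
column, making the operation deterministic and idempotent. Selection runs
on the experiment-level matrix (the analysis object); a single-cell-level
run is available by passing that matrix instead.

Residualization fits each feature by OLS on an intercept, linear age,
and indicator contrasts for gender, season (four levels) and batch;
measurement dates enter as days since the earliest measurement, linearly.
Rank-deficient designs drop aliased columns with a warning; rows with
missing covariates are excluded from the fit and get missing corrected
values. Z-scores use the population SD (ddof = 0) pooled over all
experiments of all chemokine arms, so a positive value reads "above the
cohort mean". Cytokines are natural-log transformed first (the log base is
a free choice; natural log is the convention for lognormal serum panels);
nonpositive concentrations are flagged missing, with optional imputation at
half the analyte minimum.

## Landscape and phenotypes

UMAP with n_neighbors = 15, min_dist = 0.1, Euclidean metric and a recorded
seed (UMAP is only reproducible single-threaded with a fixed seed — the
package accepts that cost). Clustering uses DBSCAN on the 2-D embedding as
a reproducible substitute for visual cluster delineation. The default eps
is 1.5x the median distance to the min_pts-th nearest neighbor (the k-dist
heuristic, min_pts = 5): a multiple of the *first*-neighbor distance was
tried and rejected because it labels the tails of perfectly separated
Gaussian groups as noise. An optional outlier rule (mean distance to the
5 nearest neighbors > 3x the cohort median; off by default) mirrors the
manual exclusion of extreme profiles.

Th1 classification computes type-7 (linear interpolation) 75% quantiles of
normalized IL-2 and IFN-γ over all donors with valid readouts for both
analytes — not asthmatics only; the choice is switchable via masking the
input — and requires strict exceedance of both for "high", neither for
"low", exactly one for "intermediate". Healthy controls are labeled but
excluded from Th1 contrasts. ICS classes from daily fluticasone-equivalent
dose: control; naive (zero dose, no on-demand use); low (< 200 ug/day under
12 years, < 250 ug/day otherwise, or on-demand-only); high (everything at
or above — medium and high doses are pooled, reflecting small class sizes
in practice). Group comparisons use the Welch t-test (robust to unequal
variances; a plain "t-test" is underspecified) or the Wilcoxon rank-sum
test, two-sided, starred at 0.05 / 0.01 / 0.001.

## What the synthetic data establishes — and what it does not

The simulator reproduces the statistical skeleton the analysis assumes:
directionally biased walks with a known responder fraction, rendered blobs
with known positions, covariate and batch effects that are linear on the
feature (or log-cytokine) scale, and a Th1-high subgroup planted 5 log-SDs
above baseline so it exceeds the 75% quantile with probability >= 0.99.
Green tests therefore establish that the pipeline recovers known structure
under its own model assumptions. They do not establish performance on real
recordings: real neutrophils change shape while moving (the simulator's
disks do not), touch and occlude each other, drift out of focus, and real
covariate effects need not be linear or additive. The classical
probability-map generator matches the three-class contract of a trained
network but not its robustness to uneven illumination or debris.

## Known limitations

* Morphology on simulated renders is nearly constant by construction
  (disks), so morphology features only discriminate on real or
  externally provided imagery.
* The linker is purely distance-based; no motion model. At densities far
  above ~50 cells/frame identity preservation degrades.
* Cluster labels from DBSCAN depend on embedding geometry; only the
  planted-structure recovery rate is tested, not cluster shape.
* The pipeline models one experiment per donor and chemokine; repeated
  measures are averaged upstream rather than modeled (no random effects,
  matching the fixed-effect linear correction).
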