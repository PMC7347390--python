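# Methods

`wormstates` reimplements a whole-organism behavioral-profiling pipeline for
*C. elegans*: per-frame extraction of posture and physiological events from
brightfield video of a single freely moving adult, followed by unsupervised
discovery of long-lasting behavioral states from the posture time series.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Posture representation

Frames are segmented by a global threshold (Otsu's between-class-variance
rule by default, overridable by a fixed value), morphologically closed
(disc, radius 2 px), and reduced to the 8-connected component inside the
20,000–100,000 px² area range nearest the frame center.  The component is
thinned to a skeleton; a cyclic skeleton graph marks the frame
*self-intersecting* (omega bend) and its posture missing.  Side branches
are pruned shortest-first (ties broken toward the brighter endpoint, which
favors removing noise spurs at the body edge).  Because thinning retracts
the skeleton by roughly half a body width at each end, both ends are
prolonged along their local tangent to the mask boundary before smoothing;
without this the measured body length is biased ~2% short.  The path is
smoothed with a 31-sample running mean and resampled to 1001 evenly spaced
points.

The 1000 inter-point tangent angles (unwrapped) are fit by ordinary least
squares onto a quadratic B-spline basis with 14 components on an open
uniform knot vector.  The basis is a partition of unity, so subtracting the
reconstruction mean from the coefficients mean-centers the angle profile
exactly; the subtracted mean is recorded as the worm's overall orientation.
No smoothing penalty is used — 14 components are already a strong
low-pass.  Curvature is the arc-length derivative of the tangent angle
(1/µm).  Half widths are the perpendicular centerline-to-edge distances on
each side at the 1001 points, compressed to 30 spline coefficients per
side by the same construction.

Head/tail assignment is three-staged: (1) within contiguous valid blocks,
a frame whose mean angle jumps by more than π/2 from its predecessor is
flipped (a worm cannot reverse its orientation in one 50 ms frame
period); (2) each block is flipped wholesale if the reverse of its mean
centerline-intensity profile correlates better (Pearson) with the previous
block; (3) a global flip resolves which end is the head — either a
user-supplied flag (the stand-in for checking one frame by eye) or the
`"auto"` heuristic, which requires the darkest intensity landmarks (the
pharyngeal grinder and posterior bulb) to sit in the anterior quarter.
The flip operation adds ±π choosing the sign that keeps the mean angle in
(−π, π], which makes it an exact involution.

Locomotion: speed is |Δcentroid|/Δt, velocity its signed projection on the
forward body axis (positive = toward the head), angular velocity the
unwrapped derivative of the movement direction; each over centered 1-s and
10-s windows.  Lawn distance is 0 inside the annotated polygon, else the
Euclidean distance to its boundary.

## Event detectors

All detectors consume extracted geometry, not pixels, so they are invariant
to uniform brightness scaling; the grinder locator works on the
contrast-normalized intensity profile along the centerline.

**Pumping.**  Frames whose body length exceeds the rolling (centered)
90th percentile of the surrounding 10 min by ≥30 µm are excluded as
tracking artifacts (usually eggs touching the nose or tail).  The profile
over the first quarter of the body is spline-upsampled to ~0.2 µm; among
its four darkest local minima (with a 2%-of-range prominence floor that
rejects interpolation ripple), a pair separated by 8–17 µm is the grinder
distance; otherwise the frame is missing.  Each contiguous defined stretch
is bandpass filtered (2nd-order Butterworth, 0.2–0.8 of Nyquist — 2–8 Hz
at 20 Hz sampling, bracketing the 4–5 Hz pump band) with zero-phase
forward–backward filtering so event times are not lagged; excursions
deeper than 0.6 µm below zero count as pumps, at most one per 50 ms.

**Defecation.**  The proportional body-length fluctuation (length minus
its 50-s moving median, divided by the median) is correlated with a
zero-mean matched filter of two negative Gaussian lobes (σ = 0.9 s) 3.5 s
apart — the paired contraction of the defecation motor program.  Peaks
above 5 robust (MAD-scaled) SDs with a 10-s refractory period are events.
The threshold is a parameter; 5 MADs is scale-free and conservative.

**Egg laying.**  A frame is a candidate on a side iff, within a 100-ms
window: worm area does not decrease; body length changes ≤5%; some width
segment 15–20 on that side jumps ≥6 px; and the vulva-tuned region filter
(250-ms differenced mean widths of 5 anterior / 5 vulval / 5 posterior
segments, weighted 1, 2, 1) crosses a threshold.  That threshold is not a
physical constant; it was calibrated once on synthetic fixtures
(`scripts/calibrate_egg_threshold.py`) to 2.5 px, where record-level
recall is 1.0 at 0 false positives per 10 min, and remains exposed as
`DetectorParams.egg_filter_threshold_px`.  The side with more candidates
is labeled ventral (eggs exit only through the ventral vulva) and dorsal
candidates are dropped.  Candidate runs are merged (1-s gap) and confirmed
against ground truth (tests) or an operator review CSV — the programmatic
stand-in for manual verification, which also supplies per-event egg counts
(simultaneous multi-egg events are one event with count > 1).

## State discovery

**Compendium.**  Observed 14-vectors are Ward-clustered; cutting the tree
at sizes 1–200 and averaging each cluster's members gives candidate
compendia.  Variance explained is 1 − SS_within/SS_total; the selected
size is the smallest explaining ≥75% while the next posture adds <1%.
Under Ward's objective each merge of height h raises SS_within by h²/2,
so the whole selection curve follows from the linkage heights.  The tree
is built on a 10,000-vector random subsample (Ward linkage on the full
100k input would need a ~40 GB condensed distance matrix); the prototypes
are then refined by two Lloyd iterations on the full input — prototypes
are defined as cluster means, so recomputing means under full-data
assignment applies the same definition — and the reported variance
explained is evaluated on the full input under nearest-prototype
assignment.

**Posture groups.**  The posture-to-posture transition matrix (consecutive
valid frames, self-transitions ignored, rows normalized) is clustered by
k-means on its rows, 500 restarts per candidate count k = 2–10; the
criterion is the mean intra-group over mean inter-group off-diagonal
transition probability, invariant to simultaneous row/column permutation.
The k and restart maximizing the criterion are kept.

**Coarsening.**  Each 3-s bin (60 frames at 20 Hz) is summarized by its
posture-group composition vector; bins more than half missing are missing.
k-means over the composition vectors with silhouette-selected k maps each
bin to a cluster; when the cluster→dominant-group mapping is one-to-one
the bin symbols are the dominant-group ids.

**HMM.**  A discrete-emission HMM over the coarsened symbols is fit by
Baum–Welch (scaled forward–backward, numba-compiled; the EM trajectory is
verified against hmmlearn to 1e-13 from a shared initialization in the
test suite).  The initial-state distribution is fixed uniform; tolerance
1e-4 on the log-likelihood, at most 500 iterations.  Initialization
matters for sticky-state models: from fully random matrices EM crawls
through long plateaus and, at realistic restart budgets, rarely reaches
the optimum.  Restarts therefore alternate between (a) emissions seeded by
k-means on 1-min sliding-window symbol histograms with a 0.9-diagonal
sticky transition start, and (b) fully random Dirichlet rows with the same
sticky start; the best restart by likelihood wins.
BIC = −2 logL + p ln n with p = N(N−1) + N(M−1) (the fixed uniform start
is not counted); the state count minimizing the median BIC over restarts
is selected.  Decoding is Viterbi per contiguous segment with a 1e-8
emission floor (renormalized) applied at decode time only.  States are
labeled post hoc: highest mean velocity → roaming; the rest are dwelling
sub-modes ordered by occupancy.

**Dwelling-model comparison.**  Three generators of synthetic posture
sequences (group-HMM with empirical within-group hopping; empirical
transition matrix alone; similarity-kernel transitions with
P(i→j) ∝ exp(−d²/2σ²), σ = median inter-prototype distance) all draw
per-posture dwell times from the empirical duration distributions.  The
summary statistic is the mean first-passage-time matrix between posture
pairs; a model's error is the summed squared difference from the real
matrix over pairs defined in both.

## Downstream analyses

Eigenworms are the principal components of the mean-centered posture
matrix.  Bend phase is the angle of the frame's projection onto the two
dominant eigenworms, signed so phase advances during forward locomotion;
bend depth is the per-frame SD of the 14 angles.  Phase locking of events
is tested with the Rayleigh z = nR² (small-sample-corrected p; matches
`pingouin.circ_rayleigh` in the tests).  Velocity-binned profiles use
0.05 mm/s bins spanning −0.25 to 0.45 mm/s; per state × bin, egg rates are
eggs per time-in-bin with bins under 4 min of data per animal excluded,
95% CIs by bootstrap over animals (1,000 draws), roaming-vs-dwelling
differences by a within-bin permutation of egg state labels (5,000 draws,
Bonferroni-corrected), and the within-state velocity association by a
bootstrap of the fitted slope.  Egg dispersal is quantified by the mean
distance to the k nearest eggs (k = 1–10) and by the fraction of
path-visited grid cells (default 0.5 mm, parameterized) containing at
least one egg.

## The synthetic forward model

The generator inverts the analysis stack so every stage has ground truth.
Defaults are the study conditions: 20 Hz, 1.44 µm/px, 1 mm adult with a
~22 px maximal half width, grinder landmarks resting 12 µm apart
oscillating ±1.5 µm at 4.5 Hz, a defecation motor program every ~45 s
(two 2% contractions 3.5 s apart), vulva at 55% of body length, and a
9-state / 8-group behavioral HMM: one roaming state (self-transition 0.97,
stationary occupancy 0.25, speed 0.25 mm/s) whose posture repertoire is an
even split over four groups, and eight dwelling sub-modes (self-transition
0.95, 0.03 mm/s) each concentrated (0.85) on one group.  Roaming's
repertoire is deliberately spread over several groups: concentrating it on
one or two both misstates the biology (roaming is stereotyped forward
waves across bend phases) and couples those groups so strongly that the
block criterion would merge them.  Egg laying is a state-modulated Poisson
process, 0.5/min roaming and 0.083/min dwelling (ratio 6, ~65 eggs per
6 h — the top of the typical 20–70 per overnight dataset).  Reference
postures are smooth random bend waves plus a smooth idiosyncratic
component; frame-level posture noise is scaled so the reference postures
explain 76% of postural variance, and low-passed over 0.15 s because real
bodies deform continuously.  Posture groups are assigned by geometric
k-means of the prototypes: groups are sets of similar shapes an animal
oscillates among.

Rendering draws the body as a union of discs along the reconstructed
centerline with the half-width template, grinder spots as sub-pixel
Gaussian darkenings, eggs as dark ellipses (~54 × 34 µm) pressed lightly
against the ventral body wall at laying time (deep enough to join the
thresholded component, shallow enough not to drag the skeleton), Gaussian
blur σ = 1 px, and additive noise.  Frames are worm-centered, as a
tracking microscope keeps them, so laid eggs drift out of view.

What the generator does **not** emulate: bacterial-lawn texture, omega-bend
self-occlusion imagery (self-intersection is emulated by dropping posture
validity, not rendered), illumination gradients, condensation, multi-worm
scenes, and the posture-dependent statistics of real pump/defecation
timing.  Tests passing on these fixtures therefore demonstrate that the
algorithms recover the structure they assume, at the stated noise levels —
not that segmentation or event detection is robust to every real-world
imaging artifact.

## Problem sizes and numerical choices

Model-selection runs use 6 animals × 7,200 three-second bins (six hours
each) for BIC, a one-hour record for the group and coarsening selections,
three 6-h animals for the end-to-end egg-rate-ratio recovery, and 100,000
posture vectors for the compendium; rendered-video tests use a 20-s scene
at 768² px.  Ties in nearest-prototype assignment go to the lowest index;
all stochastic steps take explicit seeds and are reproducible; degenerate
inputs (constant images, single-composition bins, empty masks) return
flagged empty/missing results rather than raising wherever the pipeline
can continue.

## Known limitations

Omega-bound postures are not resolved (frames are flagged and skipped, as
in the original design).  The egg region-filter threshold and the
defecation peak threshold are calibrated/parameterized, not derived.  The
compendium subsampling makes the selection curve an estimate whose
variance grows for K near the sample size.  Multi-worm tracking, live
acquisition, and genotype-comparison statistics are out of scope.
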