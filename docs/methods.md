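# Methods

`reomap` implements the computational analyses used to study how hippocampal
CA1 place cells support two tasks at once when a disoriented animal is
returned to one of two visually distinct but geometrically identical
rectangular chambers: recovering heading (which way am I facing?) and
recognizing context (which chamber am I in?).  Because the original
recordings are not publicly archived, the package ships a synthetic-session
generator with full ground truth; every analysis is exercised and validated
against that generator.

## The experimental structure being modeled

Each animal runs 12 trials per day for 3 days, alternating between contexts
A and B (6 trials each), in a 20 × 30 cm chamber.  A reward is buried in one
corner cup (C); the diagonally opposite corner (G) is geometrically
indistinguishable from C, while the remaining two corners (N, F) lie on the
unrewarded axis.  The animal is disoriented before each trial, so its
internal heading estimate can align with the chamber geometry in either of
the rectangle's two congruent orientations, 0° or 180°.

## Rate maps

Activity is binned on a 1 cm grid (20 × 30 bins).  Only samples moving
faster than 2 cm/s contribute.  Activity and occupancy maps are smoothed
with an isotropic Gaussian (σ = 3 cm, truncated at 4σ and renormalized
inside the chamber so no mass bleeds across walls) and divided; pixels with
smoothed occupancy below 0.05 s are masked as unsampled and excluded from
every downstream statistic.  The order of smoothing and division is
ambiguous in prose descriptions of this procedure; we smooth numerator and
denominator separately and then divide, which avoids ratios of nearly-empty
bins, and expose `smooth_mode="divide_then_smooth"` as the alternative.

For rotation analysis the rectangle is compressed to a 20 × 20 square by
re-binning the raw speed-filtered samples anisotropically (1 cm × 1.5 cm) —
not by resampling the smoothed map — so quarter-turn rotations are well
defined and total event weight is conserved before normalization.

Place fields are 4-connected components of pixels exceeding the map's 95th
percentile (computed over sampled pixels, linear interpolation); ties in
component ordering break by area, then peak rate.  The *center-out angle*
is the direction from the chamber center to the largest field's
rate-weighted centroid (0° toward +x, counterclockwise, in [0, 360)).

## Rotation statistics

**Best-match rotation (BMR).**  For each cell and trial pair the square map
of the first trial is rotated 0/90/180/270° and Pearson-correlated with the
second over jointly sampled pixels (minimum 20; fewer, or a zero-variance
map, flags the comparison undefined).  The maximizing angle is the BMR;
ties break toward the smaller angle.  A 12-trial session yields 66 pairs
per cell.  **Coherency** of a trial pair is the share of simultaneously
recorded cells (active in both trials) agreeing on each rotation, ranked
1st–4th; independent rotations give 25% per rotation.  Joint 1st/2nd-BMR
distributions are averaged per animal, then across animals.

**Center-out differences** validate BMR without compression: pairwise
circular differences of per-trial center-out angles.  Because geometric
alignment makes these distributions bimodal at 0°/180°, angles are doubled
modulo 360° before computing the mean resultant length.

## Context similarity and FI/FS classification

Within each context, a cell's trial maps are brought to a common
orientation by exhaustively searching per-trial 0/180° assignments (first
trial anchored; ≤ 2⁵ assignments for 6 trials) for the maximum mean
pairwise correlation.  The per-context average aligned maps are then
compared at 0° and 180°; the better correlation is the cell's *context
similarity*.  Cells need a place field in each context for the score to be
defined.  Cells at or below 0.3 are *feature-sensitive* (FS, remapping
across contexts); the rest are *feature-insensitive* (FI).

The 0.3 threshold is also recomputable from data: cells are split into
deciles of the similarity distribution; per decile (≥ 3 cells) the Pearson
R between members' within- and across-context correlations gives a 10-point
curve fit with asymptotic regression y(x) = a − (a − b)e^(−cx) (16
deterministic multi-starts over a log-spaced rate grid; Gaussian
log-likelihood; AIC with k = 4; RSE with n − 3 df).  The decile containing
the fitted curve's half-life (ln 2 / c), root (when a and b differ in
sign), and maximal-relative-growth locus marks the FS/FI boundary, and its
empirical upper edge is the selected threshold.  `compare_model_families`
accepts alternative model families for AIC comparison.

Note an identifiability limit inherent to the procedure: a cell whose
fields rotate exactly 180° across contexts is indistinguishable from a
stable cell, because 180° is the chamber's own symmetry and is absorbed by
the alignment.  Such a cell is classified FI.

## Population similarity and decoding

**Normalized dot product.**  Stacking all cells' average aligned maps gives
an across-cell population vector per pixel and context; the per-pixel
cosine between contexts (in [0, 1] for nonnegative rates) measures
population similarity.  Pixels with a zero vector in either context are
flagged undefined.

**Context from firing location.**  Leave-one-out: context averages are
recomputed without the withheld trial, the withheld maps are aligned to
each candidate average by their best of {0°, 180°}, and the context with
the higher mean normalized dot product (over cells, then pixels) wins;
exact ties are broken by a seeded coin flip recorded per trial.

**SVM decoders.**  Heading (C vs G dig) is decoded from per-cell
(sin, cos) center-out angles; context (A vs B) and heading are also decoded
from per-cell mean rates (cells need fields in ≥ 4 trials, ≥ 2 per
context).  All use a linear SVM, C = 1, class priors at their empirical
frequencies, validated leave-one-out; cross-day transfer fits once on a
training day and scores the test day over cells registered on both.
Missing angles/rates impute zeros (an indicator-column policy is
available).  Rate features are z-scored by default: with C fixed at 1, raw
rate features (small trial-to-trial variance) put the classifier in an
underfit regime where leave-one-out predictions collapse onto the training
majority and chance-level sessions score far below 50%; standardization is
label-free, restores 50% calibration, and makes accuracy invariant to
uniform rate rescaling.

Chance calibration is assessed by independent fair-coin relabeling of
trials, under which any leak-free decoder is exactly 50% in expectation.
Within-session label permutation is also available but is known to bias
leave-one-out accuracy below 50% (fixed class counts anti-correlate the
held-out label with the training composition); this small-sample artifact
is a property of the procedure, not of an implementation.

## Rate remapping

Per cell, the 12 × 12 matrix of absolute mean-rate differences between
trials is split into within-context (A–A and B–B pooled) and
across-context pairs; their means, and per-animal cellwise mean matrices,
quantify rate remapping.  No normalization by pooled rate is applied.

## Behavioral Bayes factors

First digs are scored under two Bernoulli models.  The C/G model tests the
rewarded-axis probability against the point null θ₀ = 0.5 with the
alternative integrating θ uniformly over (0.5, 0.9); the C model tests the
rewarded-corner probability against θ₀ = 0.25 over (0.25, 0.9).  The
Bayes factor

BF = [1/(b−a) ∫ₐᵇ θᶻ(1−θ)^(N−z) dθ] / [θ₀ᶻ(1−θ₀)^(N−z)]

is evaluated in closed form via regularized incomplete-beta differences
(adaptive quadrature is retained as a test oracle; agreement to 1e−10).
Natural logs throughout; log BF > ln 3 is substantial evidence for
learning, < −ln 3 for chance, with the exact ln 3 bound rather than the
rounded 1.1.  Group evidence is the product of per-animal BFs (sum of
logs).  Trials without a first dig are excluded from both z and N.

## The synthetic generator

The generator emits post-extraction data: trajectories, per-cell event
trains, trial metadata, and ground truth (cell classes, field centers,
per-trial ensemble orientation, per-cell applied rotation, per-trial digs).

* **Trajectory**: Ornstein–Uhlenbeck velocity (stationary speed scale
  6 cm/s, relaxation 1 s), positions folded reflectively into the chamber;
  speeds naturally dip below the 2 cm/s filter.
* **Tuning**: Gaussian fields (σ = 3 cm, peak 5 Hz, baseline 0.1 Hz),
  centers ≥ 4 cm from walls and ≥ 6 cm from the chamber center.  Each
  trial's ensemble orientation is drawn uniformly from {0°, 180°}; each
  cell follows it with per-day probability `coherence_by_day`
  (0.75/0.85/0.95), otherwise flips — coherence rising over days as the
  map stabilizes with learning.
* **FS remapping**: an FS cell's context-B field sits 10 cm
  (`fs_remap_shift_cm`) from the 180°-rotated image of its context-A
  field, far from the A field itself.  A pure 180° offset alone would be
  unidentifiable (see above); the displacement makes the remapping
  detectable while the rotation concentrates across-context BMRs on the
  flipped geometric axis.  FS cells keep FS behavior across days with
  probability 0.8 and resample their B field each day; FI identities
  persist.
* **Rate gain**: context-B intensities scale by `rate_gain_by_day`
  (1.0/1.25/1.5) raised to a per-cell ±1 power — no rate code on day 1,
  growing with experience.
* **Digs**: the first dig is categorical over C/G/N/F with per-day weights
  ((.375,.375,.125,.125), (.55,.25,.10,.10), (.65,.20,.075,.075)):
  75% on the rewarded axis from day 1 (geometry is learned early), with
  the C share growing as features are learned.  A rewarded-axis dig
  matches the orientation-implied corner (0° → C, 180° → G) with
  probability `p_dig_follows_orientation` (default 0.8; 0.5 = exact
  independence).
* **Determinism**: one RNG substream per (animal, day, trial, stage)
  derived from the master seed; identical configurations are bit-identical.

What the generator does *not* emulate: out-of-field theta modulation,
multi-field cells, field-size heterogeneity, imaging noise and
deconvolution artifacts, cell-registration errors (identities are ground
truth), behavioral trial truncation at reward discovery, and any continuous
(non-axial) map rotation.  Passing tests therefore validate the analysis
chain and its statistical behavior under the assumed structure, not
robustness to those real-data complications.

## Problem sizes and numerical choices

Simulation-based tests use 10–25 cells per session, 120 s trials at 10 Hz,
and 4–20 sessions per check; the chance-calibration suite uses 100 fresh
sessions × 10 relabelings (1000 replicates per decoder); the acceptance
script uses 1000 replicate sessions at the default 50-cell condition.
Percentiles interpolate linearly; BMR and rank ties break toward the
smaller angle; undefined comparisons (insufficient overlap, zero variance,
empty occupancy) are flagged and excluded rather than coerced to zero.
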