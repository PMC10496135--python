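# Methods

## Input model

The pipeline consumes DLC-3D tracking CSVs, one per recording session, and
uses only the vertical (z) coordinate of six hotspots in a fixed canonical
order: nose, eyes, neck, mid back, lower back, tail attachment. Two header
dialects are auto-detected from the first cell of the file: the native
three-row header (scorer / bodyparts / coords with x,y,z triplets per body
part) and a flat one-row header with one z column per hotspot. Files are
UTF-8, comma-separated, decimal point. Frames with any absent or
unparsable z are flagged as *missing* but kept in the timeline, so frame
indices stay aligned with the source video; missing frames are excluded
from clustering and labeled with the sentinel 0 ("unassigned") downstream.
DLC likelihood columns are ignored (an optional pre-threshold is a
non-goal here; users can blank low-confidence cells upstream).

Cohorts live in a "mother folder": one subfolder per animal id, session
CSVs named so they contain the id. Session order is the lexicographic
order of file names after zero-padding digit runs — a pure function of the
names, never of file-system timestamps. Discovery skips the pipeline's own
output folders ("Mean Distances", "Modules", "ground_truth") and output
file prefixes (Clustered*, Mouse*, Frequencies*, truth_*), so a processed
folder can be re-run from the raw tracking files. All subjects must supply
the same number of sessions and, per session ordinal, the same frame
count; validation reports every offending (subject, session, count).

## Step 1 — posture extraction

For one subject, sessions are concatenated in session order and each frame
is mapped to the 15 signed pairwise differences z_i − z_j over all
unordered hotspot pairs (i < j in canonical order, i outermost). For any
vector v, Σ_{i<j}(v_i − v_j)² = 6‖v‖² − (Σv)², so a constant shift of all
hotspots — the first-order effect of body size — cancels exactly; the test
suite asserts this to 1e-12. Signs are retained because which hotspot is
higher is the behavioral signal (nose above vs below the tail line);
an absolute-value mode is available behind a flag but is not the default.
No further standardization is applied before clustering.

Clustering uses k-means (k-means++ initialization, best of `replicates`
restarts per k, seeded; ties in point assignment resolve to the lowest
cluster index inside the engine). The number of postures is chosen by the
elbow criterion: the smallest k with explained-variance fraction
V(k) = 1 − WCSS(k)/WCSS(1) ≥ `variance_cutoff`. Defaults: cutoff 0.95,
k_max 20, 10 replicates, max 300 Lloyd iterations. When WCSS(1) = 0 (all
frames identical) k = 1; when the cutoff is never reached, k_max is used
and a warning logged; k_max is clamped to the number of distinct rows.
The search stops at the first k that satisfies the cutoff — sweeping
further cannot change the selection, since the criterion is "smallest
such k"; `full_curve=True` computes the whole WCSS curve for diagnostics.
Posture ids are renumbered 1..P by descending frame count (ties by raw
cluster index) so numbering is stable and meaningful. Centroids reported
downstream are recomputed as the exact mean of member feature rows.

## Step 2 — module matching

All subjects' posture centroids are pooled (unweighted by default; a
weighted option uses frame counts as sample weights) and clustered by the
same seeded k-means engine at a fixed, user-chosen k — no elbow. The
recommended choice is k = min(per-subject posture count) + 1: one more
module than the sparsest repertoire leaves room for every subject's
postures to separate while keeping modules replicated across animals. Two
postures of one subject may land in the same module; this is allowed and
logged (their frames merge downstream). Module ids are numbered by
descending total frame count across the cohort.

## Step 3 — frame labeling and frequencies

Each frame's posture id maps through the (subject, posture) → module table;
the sentinel 0 propagates. One labeled CSV is written per original tracking
file, and one frequency table per subject counts frames per (module,
session); every module 1..k gets a row even when empty so files are
comparable across subjects, and an "unassigned" row is appended only when
missing frames exist. Column sums always equal session frame counts
(conservation is property-tested).

## Bout analytics

A bout is a maximal run of consecutive frames with the same module id;
run-length encoding tiles each session exactly and decoding reproduces the
stream. Bouts never span session boundaries. Sentinel (module 0) bouts are
excluded from bout statistics by default (`include_unassigned` overrides).
Durations convert as n_frames × 1000 / fps milliseconds (40 ms per frame at
the default 25 fps). The short-bout share is
Σ(length of bouts shorter than the threshold) × 100 / total frames, with
the threshold defaulting to 3 frames (120 ms); it is monotone in the
threshold and bounded in [0, 100]. Duration distributions report counts by
exact length, the median over bouts (not frames), and the cumulative
fraction of bouts with length ≤ L, optionally stratified by module.

## Session statistics

Module expression in a test session is scored against a reference session
(habituation or SHAM, chosen per experiment) with (a − b)/(a + b), a and b
being frame counts; the score lives in [−1, 1], is antisymmetric and
scale-invariant, and is defined as 0 when a = b = 0 so downstream heatmaps
stay finite. Values are stored as fractions; ×100 for percent display is
presentation only. The ethogram correlation computes the Pearson
product-moment r (two-sided t-distribution p) between per-subject total
frames in each module and the manually scored time in each category, over
≥ 3 matched subjects; constant vectors yield NaN flagged `undefined`,
never a silent 0. Frames vs seconds is immaterial at fixed fps — r is
unit-invariant.

## Synthetic cohorts

The generator emulates the upstream tracking: per animal, a semi-Markov
state sequence over a subset of posture archetypes (geometric dwell with
configurable mean, default 10 frames; uniform jumps to a different state),
z = archetype profile + per-animal additive size offset (Normal, sd 1.0) +
i.i.d. Gaussian tracking noise (sd 0.5 camera units per hotspot), and
missing frames blanked at rate 0.01. Defaults are validation scale: 12
subjects × 5 sessions (habituation, SHAM, T1–T3) × 4500 frames at 25 fps,
9 archetypes with at least 8 expressed per animal. Generation is
bit-identical under a fixed seed; per-subject streams come from spawned
seed sequences.

The nine bundled archetype profiles keep the qualitative character of
recognizable postures (rearing: nose high, tail low; hunched: mid-back
apex; head-dip: nose lowest; climb: rear highest) but the set is
numerically uniformized so every pair of archetypes is comparably far
apart in the 15-dimensional feature space — minimum pairwise separation 28
units, about 10× the within-cluster RMS spread (√(15·2)·noise_sd ≈ 2.74)
at the default noise. This uniformity is what makes a fixed
explained-variance elbow well-posed: with it, merging even the closest
pair of planted clusters costs ≈ d²_min/(2A·T) ≈ 7% of total variance
(> the 5% slack of the 0.95 cutoff), while the residual noise variance at
the true k is ≈ 1% (< the slack). A fixture with two nearly coincident
archetypes next to a few extreme ones would be unrecoverable at any fixed
cutoff — by design this generator plants an unambiguous partition. That is
also its main limitation as a model of real data: real postures are not
equidistant, dwell times are not memoryless, noise is not isotropic or
homoscedastic, and real repertoires drift between sessions. Passing the
planted-recovery tests therefore shows the pipeline machinery is correct
and deterministic, not that real recordings will yield nine clean modules.

Geometric dwell means bout lengths of the *planted* states average 10
frames; observed label streams on real mice are burstier, with a median
bout of a few frames. The dwell mean is configurable for studies of the
bout analytics themselves.

## Problem sizes and determinism

The planted-recovery integration test runs 12 subjects × 5 sessions × 1500
frames; the acceptance script runs the full 12 × 5 × 4500. Both finish in
well under a minute on one CPU. Every stochastic component (generator,
k-means restarts for each k, the pooled matching) derives its stream from
an explicit seed via seed sequences, so complete runs are reproducible
bit-for-bit; re-running step 3 on existing step-1/step-2 outputs is
idempotent.

## Known limitations

- Only z is used; lateral kinematics, velocity and multi-animal tracking
  are out of scope.
- The elbow cutoff is a global variance criterion: repertoires containing
  both very distinct and very similar postures will merge the similar ones
  at the default 0.95. The cutoff, k_max and replicate count are exposed.
- The subtraction removes only additive size effects; multiplicative
  (allometric) scaling of posture amplitude is not corrected.
- Group-level inferential statistics (Friedman/Wilcoxon batteries and
  post hoc schedules) are deliberately not reimplemented; the frequency and
  normalization tables are tidy inputs for any stats package.
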