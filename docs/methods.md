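# Methods

## The similarity decomposition

A unit is one subject-session (pooled mode: the session's rest, go/no-go
and anhedonia runs are concatenated in that fixed order before FC) or one
subject-session-task run (per-task mode).  FC per unit is the Pearson
correlation matrix of the ROI time courses, Fisher transformed with
`z = atanh(r)` after clipping `|r| <= 1 - 1e-7`; the clip keeps a
numerically perfect correlation from injecting an infinite z into the
similarity averages.  The unit-by-unit similarity matrix holds the
Fisher-z correlation between every pair of units' upper-triangle FC
vectors (row-major order, (0,1), (0,2), ..., length `P = R(R-1)/2`).  The
matrix diagonal is unity by construction and is excluded from every
average.

Effect masks select off-diagonal cells; unordered pairs are counted once
(double-counting symmetric cells would cancel in the mean anyway).  Group
and session masks are restricted to different-subject pairs, so that the
session effect measures consistency across participants within a session
rather than inheriting the large within-person similarity; a switch
(`include_within_individual_in_group_masks`, default off) includes the
within-subject cells for sensitivity analyses.  One consequence, visible
in both synthetic output and the kind of data this models, is that the
session mask average can fall below the common average — the common mask
contains the within-subject cells, the session mask does not — in which
case the session effect is floored at zero.

In per-task mode the within-subject block partitions exactly into
individual (different session and different task), individual x session
(same session, different task) and individual x task (same task,
different session); the partition is enforced by a property test.  The
"pure" individual mask (excluding same-task and same-session cells) was
chosen over the full within-subject block precisely so these three
effects are disjoint.

Baselines form a ladder: common vs 0; session and the group mains vs
common; the group two-way interactions vs the larger of their constituent
mains; individual vs the largest main or group interaction present; the
within-subject interactions vs individual.  Ties among candidate
baselines are value-identical, so `max` is unambiguous.  Corrected
magnitudes are floored at zero and normalised to sum to 100%; if every
corrected magnitude is zero the normalisation is reported as undefined
rather than invented.

Participant-level averages restrict a mask to the rows of one subject's
units.  Group masks already exclude a subject's own cells, matching the
intent that a participant is compared with *other* members of their
group.  Subjects whose rows miss a mask produce a missing value with a
warning and are dropped listwise by the t test.

## Inference

The dependent-sample t statistic `t = mean(d) / (sd(d)/sqrt(n))` with
`d = a - b` is referred to a permutation null generated by independently
swapping the two effects' values within each participant — equivalently a
random sign flip of each `d_i`.  The p value is two-sided with add-one
smoothing, `p = (1 + #{|t*| >= |t|}) / (1 + n_perm)`, which keeps p in
(0, 1] and makes the test exact-level under exchangeability; with 1,000
permutations the rejection probability at alpha = 0.05 is 50/1001.
Cohen's d for paired data is `mean(d)/sd(d)`.  Sign conventions: both t
and d are computed from `(a - b)` as listed in the comparison; published
tables of this kind sometimes mix sign conventions between t and d, which
is documented rather than imitated.  Default suites: 4 comparisons for a
controls-only sample, 10 when a two-level group factor (diagnosis or
response) is present, plus 3 within-subject comparisons in per-task mode;
BH-FDR at q = 0.05 is applied across the suite of one sample-mode run.
The BH implementation is statsmodels' step-up; tests compare it against a
brute-force "largest k with p_(k) <= kq/m" rule.

The summary-statistics ANOVA reconstructs a 2 x 2 between-subjects ANOVA
from per-cell (n, mean, SEM): `sd = sem * sqrt(n)` recovers the within-
cell sums of squares, and unweighted-marginal-means (Type III) contrasts
on the cell means test the two mains and the interaction with 1 and
`N - 4` degrees of freedom.  Type III was chosen because it reproduces
published F statistics for unbalanced designs of this kind to printed
rounding; a round-trip test against statsmodels' Type-III ANOVA on raw
data confirms exactness when summaries are unrounded.

## Preparation

FIR task regression builds one indicator column per event type and lag
(onset sample `floor(onset/TR)`, 0-based; lag 10 samples = 20 s at
TR = 2 s, the conventional response duration), truncated at the run end.
Rank-deficient columns — endemic to overlapping FIR blocks — are dropped
by pivoted QR with relative tolerance 1e-8 and recorded; OLS residuals on
the retained columns are the task-regressed series.  No intercept is
included: demeaning is an explicit separate step, and
regress-then-demean equals demean-then-regress whenever the design
columns are themselves demeaned (property-tested).  Voxel-to-parcel
extraction is the unweighted per-time-point mean over a parcel's voxels,
parcels in ascending id order; parcels with fewer than `min_voxels`
voxels can be excluded (strict `<`).

## Synthetic cohort and the analytic oracle

Each unit's latent FC vector is a weighted sum of i.i.d. standard-normal
patterns of length P: one common pattern; one per diagnosis, sex and
response level; one per session and task; one per individual and per
individual-session cell; plus fresh unit noise.  The weights are standard
deviations.  Under this additive model the correlation between two units'
vectors converges (P large) to

    rho(u, v) = sum of squared weights of shared components
                / sum of squared weights of all components (incl. noise),

and every effect's expected mask average is the cell-count-weighted mean
of `atanh(rho)` over its mask — a closed-form oracle that parameter-
recovery tests check to within 3 Monte-Carlo standard errors across
seeds.  Vector-mode output is emitted directly in z-scale without a tanh
round-trip: the decomposition depends only on correlations between
vectors, not their marginal scale.

Default weights (the study conditions for all drivers and tests): common
1.0, individual 0.95, diagnosis = sex = response 0.1, session 0.05, noise
0.35; task 0.30 and individual-session 0.20 apply only to per-task units.
They encode the qualitative structure the method is designed to expose —
common and individual variation dominant, group effects real but small —
with magnitudes chosen once as plausible for multi-site fMRI; they are
not fitted to any dataset.

Cohort composition defaults to the modelled trial: 42/26 female/male
patients (33 responders) and 21/18 female/male controls, three sessions
(baseline, week 2, week 8), three tasks (rest 588 s, go/no-go 588 s,
anhedonia 690 s at TR = 2 s, i.e. 294/294/345 samples, 933 concatenated
per session).  Patient MADRS baselines are integer scores from a normal
(29, 3) truncated at the entry criterion of 24; week-8 scores are drawn
to satisfy or violate the responder rule by construction (strictly more
than 50% decrease; an exact 50% decrease is a nonresponder), with a
rounding fix-up so the label is always reproducible from the stored
scores, and exactly `n_responders` patients respond.

In time-series mode each run's latent vector is mapped through `tanh`
into (-1, 1), assembled into a symmetric unit-diagonal matrix, projected
to the nearest positive-definite correlation matrix (eigenvalue floor
1e-6, diagonal rescale), and realised as T i.i.d. Gaussian samples with
that correlation (Cholesky).  Task runs add a task-locked FIR-shaped
response: per event type, a random 10-lag response shape (Hann-windowed)
times a random ROI loading, scaled by `task_signal_amplitude` (default
1.0, i.e. comparable to the background signal — strong enough that raw FC
is visibly task-inflated and FIR regression is doing real work).  Event
tables are deterministic: 16 go/no-go blocks (instruction slide + one of
four block types), and 16-second anhedonia trials cycling cue
(reward/no-reward), target, and four feedback types.

What the generator does *not* emulate: head motion, censoring, scanner
and site effects, hemodynamic nonlinearity, spatial voxel structure,
autocorrelated noise spectra.  Passing tests therefore certify the
statistical machinery — masks, baselines, inference, calibration,
recovery of known structure — not robustness to those artefacts.

## Reliability

Runs are cut into whole 150-second segments (75 samples at TR = 2 s; the
trailing remainder of each run is discarded to keep segments
homogeneous).  Each subject's segments are split into two disjoint pools
by alternating assignment with a pseudorandom phase per run, re-drawn
until both pools contain every task and both temporal run-halves.  The
reference FC uses the whole first pool; for each grid length, that many
test-pool segments (selected to cover all tasks and both halves) yield a
test FC, and the curve value is the Pearson correlation between the two
z-vectors.  With study-length runs, whole-segment division leaves at
least 12 segments (30 min) in the worst-case test pool, so drivers and
tests use a 5-30 min grid.  The analysis is run on control participants
only, since treatment is expected to change patient FC over time.

## Problem sizes and numerical choices

Tests and drivers run at deliberately scaled-down sizes chosen for rapid
iteration while keeping every estimate well-conditioned: P ~ 1e4 (142
ROIs) for study-sized parameter recovery, 10-40 ROIs for time-series
simulations, 500 replicates x 500 permutations for type-I calibration
(the add-one p makes the attainable level 25/501 ~ 0.0499), 8-10 seeds
for Monte-Carlo standard errors.  The 326-ROI study scale is available
via `n_rois=326` and changes nothing structurally.  All randomness
derives from one master seed per entry point (NumPy `SeedSequence`
substreams per stage), and every pipeline output is byte-reproducible
under a fixed seed.

## Known limitations

Only categorical factors are decomposed (no continuous covariates such as
age or symptom severity); similarity is full-matrix Pearson (no partial
correlations or dynamic FC); the ANOVA reconstruction assumes the printed
SEMs are from the same cells it tests; the permutation test assumes
exchangeability of the two effects within participants, not independence
across them; and the baseline ladder, while principled, is one of several
defensible conventions — its choices are isolated in `baseline_for` and
documented above.
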