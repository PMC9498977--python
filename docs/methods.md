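# Methods

## Device model and conventions

The instrumented cube reports, at an irregular rate of roughly one sample
every 203 ± 113 ms, a binary tactile map per face (6 faces × 16 capacitive
cells, 1 = touched) and a unit quaternion for its spatial orientation.
Faces are numbered 1..6 with outward body-frame normals +X, −X, +Y, −Y,
+Z, −Z; cells are 0..15 in row-major 4×4 order. Quaternions are
scalar-first (w, x, y, z) and encode the active body→world rotation. The
participant frame defaults to world +Z = up, +X = front, +Y = left
(right-handed); absolute (cardinal) labels use an East-North-Up world.
These conventions are declarations, not inferences — orientation labels are
only interpretable relative to a declared frame.

## Resampling and trimming

All analysis runs on a constant 0.2 s grid, close to the device's mean
rate. Binary maps cannot be averaged without creating non-binary states the
SMC cannot consume, so tactile maps are resampled by zero-order hold (the
latest raw map at or before each grid time); orientations are resampled by
SLERP along the shortest arc. Trials are trimmed by removing leading and
trailing grid samples with fewer than two active cells (whole-cube count) —
an automated form of the usual manual cutting of pick-up and put-down
phases, applied to leading/trailing runs only so interior pauses are kept.
Interior raw gaps are held, with a logged warning beyond 2 s.

## Explorative-touch filter and touch metrics

Explorative touches (probing a face) are spatiotemporally variable;
holding touches (supporting the cube) are stable. Per grid sample the SMC
of each face against the previous sample is computed; the face(s) attaining
the minimum are explored, unless the SMC is 1 everywhere (cube untouched or
still). Ties keep all tied faces; their active cells are summed. The first
grid sample has no predecessor and is excluded.

Derived per-trial metrics: exploration duration (first to last active
sample); number of touches, defined as 0→1 transitions of single cells on
explored faces (the only event definition robust to the binary,
sample-rate-limited data); touch frequency; per-face exploration-duration
mean and SD across all six faces (never-explored faces count 0, which makes
the SD sensitive to focused exploration); mean active cells per sample on
explored faces (excluding inactive samples); mean of the minimum SMC.

## Rotation metrics

The printed per-step angle formula (arctan of |cross/dot|) is singular at
90° and ambiguous beyond; the implementation uses atan2(‖cross‖, dot),
identical on (0°, 90°) — per-step angles at 5 Hz are far below 90° — and
well-defined everywhere. Amount of rotation is the maximum over the three
face-normal axes of the summed per-step traversals; it can only lose path
length under discretization. Rotation speed divides per-step angles by
0.2 s; an instant is "in motion" when the cross-axis mean exceeds 1 °/s
(a single motion state per instant), and the speed is the mean of per-axis
speeds over the three axes and in-motion instants, so static phases do not
dilute the estimate.

Face labels: each body axis is matched to the reference axis (participant
or cardinal frame) with the largest |dot|. A plain per-face argmax is not a
bijection at 45° ties, so the assignment is greedy over the 3×3 magnitude
matrix with the fixed label order (up, down, front, rear, left, right) as
tie-break; the result is always a bijection and equals the argmax away from
ties.

## Episodes and transition matrices

Maximal runs of a constant explored face (ties resolved to the lowest face
id) form episodes; samples with no explored face break runs. Episode labels
are the modal relative label, ties resolved to the label at episode start.
Transitions are counted between consecutive episodes and normalized to
percentages; consecutive episodes of the same face (possible only across an
untouched gap) count as a return but not a transition — an untouched gap
means the cube was resting, and resuming the same face is a revisit, not a
movement between orientations. Scores: maximum diagonal percentage, number
of strictly positive cells, number of returns (episodes minus distinct
faces).

## Statistics

The observation unit defaults to trial level (consistent with post-hoc
degrees of freedom in the tens for cohorts of ~30 participants), with
participant-mean aggregation available as a switch. For the synthetic
cohort the analysis scripts report Welch post-hocs at participant level:
synthetic trials within a participant share that participant's jittered
preset, so trial-level pairwise tests would treat clustered draws as
independent and overstate evidence. MANOVA/LDA are reported at trial level;
at participant level (n = 32, p = 12) the within-group scatter matrix has
29 degrees of freedom and the discriminants overfit near-constant
variables.

Roy's largest root is the top eigenvalue of W⁻¹B (within/between SSCP),
with the conventional union-intersection F upper bound on
(r, n − g − r + g − 1) degrees of freedom, r = max(p, g − 1). The LDA
solves the same generalized symmetric eigenproblem; coefficients are scaled
so the within-group covariance of the scores is the identity (normalized
coefficients), signs fixed so each discriminant's largest-|coefficient|
entry is positive, and the "percentage of separation" is each eigenvalue's
share of the trace. Both are authored here (eigen via scipy) and
cross-checked in the tests against statsmodels' MANOVA and scikit-learn's
eigen-solver LDA as independent oracles.

The accuracy Bayes factor uses a Box-Cox transform with λ maximized on a
grid [−2, 2] step 0.01 (zeros shifted by 10⁻³), then the BIC approximation
BF01 = exp((BIC_group − BIC_null)/2) — a closed-form stand-in for the
default mixture-prior factor with the same decision direction. Pairwise
comparisons use Welch (unequal-variance) t tests; FDR families are one per
analysis block (follow-up ANOVAs; pairwise tests per variable; the
correlation pair), with Benjamini–Hochberg adjustment and α = 0.05.
Directed correlations report one-tailed Pearson p values in the declared
direction.

## Synthetic exploration traces

The generator emulates what the analysis assumes: episodic face-by-face
exploration with reorientations between episodes; a support face holding a
constant two-cell pattern; a spatiotemporally variable explored face;
truncated-Gaussian sampling intervals (203 ± 113 ms, minimum 50 ms); and
1 s one-cell lead-in/tail phases that exercise trimming. Each trial is
planned as an episode sequence (faces drawn from the five non-support
faces, target orientations drawn from a concentration policy over the six
egocentric labels), executed as SLERP keyframes at the preset rotation
speed; when the reorientations cannot reach the per-trial rotation target,
in-place spins about the explored face's normal (which preserve its label)
make up the deficit, and when the budget is exhausted later episodes are
explored wherever they already are. The script records the exact per-axis
traversal of every planned segment as ground truth.

Touch dynamics on the explored face are controlled to hit two targets at
once. The active-cell count follows an always-moving ±1 walk that ramps
toward a truncated-Poisson target refreshed every three redraws; the
Poisson rate is root-solved so the truncated mean equals the preset, and an
error accumulator steers the on-target oscillations so the time-averaged
count is exact. The per-step SMC is controlled by flipping k cells per
redraw with k tracking 16·(1 − target SMC) through a second accumulator
(flip counts are parity- and budget-constrained per step; the accumulator
keeps the long-run mean exact). Moving every step keeps k odd and ≥ 1, so
every redraw is an explorative event — a scheme in which the count can
rest would have to skip low-count frames selectively and bias the measured
mean upward. The map advances at most once per 0.2 s analysis window, so
consecutive distinct grid maps differ by exactly one controlled redraw and
the grid-level SMC is unbiased. Combinations whose SMC target demands more
mismatching cells than two maps of the given density can sustain
(16·(1 − SMC) > 2 × target cells) are rejected as infeasible.

Cohorts jitter each participant's targets by centered Gaussian deviates
(SD 5% of each target, standardized to zero mean within group): each
realized cohort then exhibits the group-level targets exactly while keeping
realistic between-participant spread — a variance-reduction choice;
without it the group-mean jitter of the two closest groups is comparable
to their planted difference, and individual cohorts routinely misrepresent
the conditions they are meant to embody. An optional coupling exponent
shortens a participant's trials as their active-cell target grows, planting
the negative correlation between active cells and exploration duration.

What the generator does not emulate: pressure or finger kinematics,
multi-face holding grips, drift or noise in the orientation estimate,
response processes (recall responses are Bernoulli draws at the preset
accuracy), and trial-to-trial strategy changes within a participant beyond
episode-sequence randomness. Passing tests therefore certify the pipeline's
measurement and statistical machinery on data with known structure, not the
behavioral validity of any particular human dataset.

Two measurement-side caveats are inherent rather than bugs: episode
boundaries contribute one activation and one clearing frame whose SMC
reflects the mass onset/offset of the touch pattern, pulling the measured
trial-mean SMC a few hundredths below the preset at short episode lengths
(the effect vanishes as episodes lengthen, and is common to all groups);
and zero-order-hold resampling of a ~5 Hz stream onto the 0.2 s grid leaves
repeated grid frames that fragment episodes, inflating the returns count
relative to the scripted sequence under irregular sampling (exact recovery
holds under regular sampling).

## Problem sizes

The test suite and acceptance run use deliberately scaled problem sizes
chosen to keep Monte-Carlo error well inside the asserted tolerances:
parameter recovery uses single 900 s trials (≈ 3,500 explored frames per
preset, giving standard errors several times smaller than the ±0.15-cell /
±0.02-SMC bands); cohort checks use the study-sized default cohort (32
participants × 6 trial phases of 60 s); the correlation check uses 100
cohorts of 96 trials of 30 s; the null-calibration check uses 2,000
simulated three-group tables of 60 observations.
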