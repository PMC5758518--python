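# Methods

## Body model

The body is a kinematic chain of 14 rigid segments — head (He), trunk (Tr),
left/right upper arms (LUA/RUA), forearms (LFA/RFA), hands (LA/RA), thighs
(LT/RT), shanks (LS/RS), feet (LF/RF) — each defined by a proximal and a
distal endpoint in the lab frame (x along the beam, y leftward, z up).
Endpoint trajectories are low-pass filtered with a 4th-order Butterworth at
20 Hz applied forward–backward (zero phase, so the timing of momentum
fluctuations is not distorted), then projected onto the medio-lateral plane
by zeroing the x coordinate.

Inertial properties come from a bundled Winter-style anthropometric table
(mass fraction, COM position along the segment, radius of gyration about
the transverse axis, and segment length as a fraction of stature; the trunk
gyration ratio follows de Leva-style values). Any table with the same
schema can be substituted via `AnthropometricTable.from_yaml`. Mass
fractions of the bundled table sum to 1.000; a residual up to ±0.02 is
tolerated for user tables and reported.

Per frame and segment the model computes the COM (at `com_fraction` of the
endpoint line), COM velocity and angular velocity by central finite
differences (one-sided at the trial boundaries, which the analysis windows
never include), the absolute orientation, and the planar moment of inertia
`I = m (gyration_fraction × length)²` evaluated per frame.

### Sign conventions

Orientation angles are measured from +z toward +y (leftward positive), the
convention in which the trunk angle reads directly as lateral lean; relative
orientations are differences child − parent along the chain (the trunk is
referenced to the lab z-axis). The angular velocity is reported about +x
with the right-hand rule, which in this plane equals *minus* the derivative
of the reporting angle. This keeps the spin term `I·ω` consistent with the
x-component of the moment-arm term `m[(y−y_P)v_z − (z−z_P)v_y]`; the
free-flight and point-mass oracles close the loop on this convention.

Unwrapping the orientation time series leaves a per-trial arbitrary 2π
branch for segments whose mean orientation sits near ±π (the legs point
down). Relative-angle channels are therefore canonicalized by wrapping each
channel's trial mean into (−π, π] before trials are pooled; this only
shifts constants and cannot affect covariances.

### Trial windows

Successful trials keep the central 15–85% of their duration; unsuccessful
trials keep the last 3 s before balance loss; unsuccessful trials shorter
than 2.5 s are excluded. Trials between 2.5 and 3 s are analysed whole and
the shortfall is logged (the exclusion rule, not the tail rule, governs
their fate).

## Angular momentum

Per segment, the x-component of `L_i(r_P) = (r_COM,i − r_P) × m_i v_COM,i +
I_i ω_i` is computed about three axes parallel to the beam: a fixed point at
the participant's mean head position (the distal head endpoint averaged over
every windowed frame of all their trials), the per-frame whole-body COM
(mass-weighted mean of segment COMs — the pipeline is self-contained and
does not rely on a proprietary COM estimate), and a fixed beam point,
default (y, z) = (0, 0) at floor level. The beam height is configurable
(e.g. z = 0.034 m for the beam top); the choice moves moment arms by at
most the beam height and is recorded in the config. The total is the exact
row sum over the 14 contributions.

"Walking speed" for the dimensionless normalization (mass × speed × height)
is the mean forward (x) velocity of the whole-body COM over the analysis
window, computed before projection — the only forward-speed quantity
available per trial.

## Dimensionality analysis

PCA is applied to the covariance matrix (not the correlation matrix — no
per-channel amplitude normalization) of the pooled windowed frames of one
condition, per participant: all successful trials, or all valid
unsuccessful trials, or one block of a block split. The smallest K with
cumulative VAF ≥ 95% is retained. VARIMAX rotates the covariance loadings
(eigenvectors scaled by √eigenvalue) with no Kaiser row normalization,
convergence at a relative criterion gain below 1e-8 or 1000 sweeps. The
classic SVD iteration can stall on saddle points (perfectly mixed
loadings), so it restarts from the identity plus three seeded random
orthogonal rotations and keeps the best criterion value — fully
deterministic. Rotated components are re-ordered by descending VAF
(recomputed from column norms; the rotation conserves the retained total),
and each column's largest-magnitude element is made positive.

Component weights (score time series) are least-squares projections of
centered data onto the rotated loadings; new trials are centered with the
fit means so score amplitudes remain comparable within a participant.
Similarity uses |S| with post-hoc sign alignment, greedy best-pair matching
with ties broken on the lowest index pair. Cross-validated VAF centers the
target data with its own means and reconstructs it by least squares from
the loading span; with a set's own retained components this reproduces the
cumulative eigenvalue VAF exactly (a numerical-consistency identity the
tests assert at 1e-9).

Body-part group VAF is reported under two definitions, because they answer
different questions: (1) least-squares reconstruction of the full centered
matrix from the group's channels alone (the default; groups need not sum to
100%, and on strongly rank-1 data *any* correlated group scores high), and
(2) the group's share of summed channel variances (sums to 100% and
reflects where the variance physically sits). The pipeline reports the
first in its summaries and exposes the second via
`group_vaf(..., method="variance_share")`.

## Balance statistics

`VCOM_RMS` is the plain RMS (no mean removal — it is an amplitude, not a
dispersion; a demeaned variant is available via a flag) of the ML COM
velocity over the analysis window. Successful and unsuccessful trials are
compared with a two-sided Welch t-test. The per-trial RMS of the first
beam-axis component's weight is regressed on trial type (successful = 1,
unsuccessful = 0, so the interaction coefficient is the successful-slope
increment), `VCOM_RMS`, and their interaction, by ordinary least squares
pooled over participants. Pooling ignores the repeated-measures structure
(no participant random effect); this mirrors the analysis the package
reproduces and is noted as a statistical caveat rather than altered. The
regression axis defaults to the beam (the axis whose PC1 dominates); it is
a parameter.

## Synthetic data generator

Real beam-walking recordings are not redistributable, so the generator
produces planar kinematics with the structure the analysis assumes:
relative segment orientations composed of K orthonormal synergy vectors
weighted by sinusoids of distinct amplitude and frequency plus white
Gaussian noise, forward kinematics through the 14-segment chain standing on
a virtual beam, and constant forward progression.

Default conditions (chosen once, to match the recording setup and observed
magnitudes of the task): 100 Hz sampling, ~10 s successful trials at
0.5 m/s (a 4.75 m beam), participants 70 ± 11 kg and 1.76 ± 0.09 m, beam
top at z = 0.034 m. Three default synergies mirror the strategies the task
elicits: mirror-symmetric flapping of the horizontally extended arms (the
"T-bar"), a whole-body lean whose pelvis counter-translation keeps the COM
over the beam (hip strategy; amplitude 0.30 rad at 0.5 Hz on the trunk
channel), and antisymmetric leg ab/adduction. Amplitudes (0.35, 0.30,
0.12 rad) are strictly decreasing for identifiability; frequencies (0.9,
0.5, 1.4 Hz) are distinct and far below Nyquist. Measurement noise defaults
to 0.002 rad (≈ millimetre-level marker noise over half-metre segments). A
residual uncompensated pelvis sway of 0.012 m produces successful-trial
`VCOM_RMS` ≈ 0.03 m/s; unsuccessful trials append an exponential ML drift
(scale 6 mm, time constant 0.8 s) over the final 3 s, reaching ≈ 0.12 m/s.

Trunk dominance of the beam-axis AM *emerges* from the trunk's mass
(≈ 50% of body mass) and its moment arm about the beam — the generator
plants synergies in angle space, never in momentum space. With the default
conditions the pipeline retains one beam-axis component (PC1 ≈ 96%,
trunk-loaded), more components about the head and COM axes, and K = 3
trunk-excluded or kinematic components — the structural pattern the
analysis is designed to detect.

What the generator does **not** emulate: stepping (no gait cycle, no
foot–beam contact or ground-reaction forces — the chain is kinematic, not
dynamic), sagittal-plane motion, marker dropout or soft-tissue artefact,
inter-participant differences in strategy (participants share synergy
shapes by default, which is what makes cross-participant similarity ≈ 1 an
expected outcome rather than a finding), and autocorrelated measurement
noise. Passing tests therefore validate the *machinery* — momentum
computation, decomposition, statistics — on data with known structure; they
do not certify numerical agreement with any particular human cohort.

## Numerical choices and problem sizes

Finite differences: `np.gradient` (central interior, one-sided edges);
velocities of quadratic trajectories are exact at interior frames.
Eigendecomposition via `eigh` on the symmetric covariance; eigenvalues
clipped at zero. Degenerate inputs raise typed errors naming the offending
segment/frame/field (zero-length segments, zero vectors in similarity or
sparsity, constant series in correlations — reported as missing, not 0 —
rank-deficient regression designs). Report JSON is deterministic (sorted
keys, repr floats) and embeds the resolved config and its hash.

Test problem sizes: oracle scenes run at 200 Hz for ≤ 0.6 s; property
suites use 1.5–4 k frame matrices; the recovery cohort uses 4 participants
× 100 successful trials (~10 s each) at 10% noise; the directional and
statistics cohorts use 2–4 participants × 8–14 trials. The full suite runs
in well under a minute on one core.

## Known limitations

- Planar only; the sagittal plane is out of scope.
- The head-axis point is an average over windowed frames of the head
  segment's distal endpoint; other head-marker conventions shift it by a
  few centimetres.
- Cross-participant component averaging is done on sign-aligned matched
  components with equal participant weights; other weightings are
  defensible.
- The anthropometric table is a published average; analyses needing
  participant-specific inertia should supply their own table.
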