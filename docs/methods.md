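# Methods

This note documents the models and procedures implemented in `gaitsm`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic world does and does not establish.

## Study design

All scores compare a participant to a normative reference built from
able-bodied controls.  Per participant, gait cycles are delimited by
consecutive ipsilateral foot contacts within a walking pass; the first and
last cycle of every pass are discarded as acceleration/deceleration.  The
segmenting side is the prosthetic side for unilateral users and a
configurable default (left) otherwise; for bilateral users, side-dependent
*parameter* values are averaged over left and right.  Signals are analysed
at a 40 Hz working rate (downsampled from 100 Hz); 100 cycles are sampled
per patient and 10 cycles per control, the control cycles aggregated into
the normative set.  Scores are computed per cycle where the measure is
cycle-wise (GPS, MDP, INI) and averaged; the statistics layer then relates
the 11 inertial-sensor scores (HMM-SM, MDP, DTW for each of three sensor
configurations, plus INI and MGS) to the GPS across the patients.

Sensor configurations: `pelvis` (one 6-channel block), `upper_legs` and
`lower_legs` (left+right blocks stacked to 12 channels).

## Downsampling

100 -> 40 Hz is the rational ratio 2/5, handled by zero-phase polyphase
resampling (`scipy.signal.resample_poly`, per-channel mean removed and
restored so constants pass exactly).  An earlier candidate — zero-phase
Butterworth at 0.45 x target rate plus linear interpolation — attenuated
band-limited content near 11 Hz by ~8%, which would have distorted the
signal-based scores; the polyphase filter keeps content below ~15 Hz within
1% of its energy.  Content between 15 Hz and the 20 Hz Nyquist is still
attenuated by the anti-alias rolloff; gait signal energy lives well below
that.

## Gaussian-HMM fitting

Ergodic 5-state HMMs with full covariances, fitted by EM (hmmlearn) on
multi-cycle sequences: a sliding window concatenates groups of 10 cycles
(stride 1 by default), which stabilises training relative to single-cycle
sequences.  Channels are z-normalized by the normative set's per-channel
statistics before any model is fitted, so participant and control models
live on one scale.

Initialisation matters more than restarts here.  Each seeded restart starts
from a k-means partition of the frames: cluster centroids as means,
*per-cluster* covariances, and a transition matrix estimated from the
k-means label sequence (add-one smoothing, sequence joins skipped).
Initialising every state at the global data covariance — a common default —
drowns the cluster structure and reliably merges well-separated states into
wrong local optima.  Five restarts, 200 iterations, log-likelihood tolerance
1e-4; the best final log-likelihood wins.  A diagonal covariance floor
(1e-6) is enforced on the returned model, and the EM covariance prior is an
identity matrix (a scalar prior would be added to every matrix entry,
which is singular for degenerate input).  Constant input therefore returns
a floored model instead of crashing.

## The similarity score

Between two fitted models, every emission pair gets the closed-form
symmetric Kullback-Leibler divergence (sum of both directions).  The
correspondence matrix is the kernel `q_ij = exp(-D_sym/tau)`; the score is
the mean normalized Gini sparsity of its rows and columns (see README for
the formula).  The Gini index uses the sorted-sum formula with the
`N/(N-1)` normalisation so a one-hot vector scores exactly 1.  Because the
Gini index is scale-invariant, each row/column is evaluated with its
exponent shifted by its smallest divergence — mathematically identical to
the raw kernel but immune to underflow when divergences are large.

**Kernel scale.**  Symmetric-KL values scale with dimension, normalisation
and within-state variance, so a fixed `tau` is meaningless across data
sets.  By default the study pipeline self-calibrates: `tau` is chosen so
that a typical pair of *distinct* normative states (the median off-diagonal
divergence of the control model) maps to a correspondence of 1/100.  States
as separable as the normative states then contribute nothing to a row's
mass — self-similarity stays near 1 — while deviated states whose best and
second-best matches begin to blur on the scale of normative state
separations visibly reduce the sparsity of Q.  `tau` can be fixed
explicitly via `StudyConfig.tau`; the low-level operations default to
`tau = 1`.  Stationary-distribution weighting of Q is available behind a
flag but off by default: the score is defined on the emissions alone.

## Comparator measures

- **MDP**: online Kohonen SOM (10 x 10 grid, 50 epochs, learning rate 0.5
  -> 0.01, Gaussian neighborhood width max(grid)/2 -> 0.5, both decaying
  linearly) trained on the z-normalized normative frames; a cycle's score
  is the mean Euclidean distance of its frames to their best-matching
  units, a participant's score the mean over sampled cycles.
- **DTW**: classic dynamic-programming DTW, Euclidean frame distance,
  symmetric steps, unconstrained warping window, cycles at native length;
  participant score is the mean over the full participant x normative cycle
  cross product.  Frames are z-normalized by the same normative statistics
  as for the HMM-SM and MDP so the three signal-based scores are
  comparable.
- **INI**: 9 parameters per cycle — cycle duration, stride length, swing
  percentage, and six kinematic/positional parameters of the ankle and
  shank — z-scored by the normative per-cycle statistics, projected onto
  the normative PCA basis and whitened by 1/sqrt(eigenvalue); the score is
  the Euclidean norm (equivalently the Mahalanobis distance to the
  normative distribution; whitening can be disabled).  Participant score:
  mean over cycles.
- **MGS**: a configurable registry maps the six gait aspects (amplitude,
  temporal, distribution, complexity, symmetry, regularity) to candidate
  parameters; the default inventory (signal RMS and range; cadence and
  swing percentage; skew and kurtosis; sample entropy m=2, r=0.2 SD;
  left/right step-time ratio; stride autocorrelation) is this package's
  documented approximation of the published aspect structure, not a
  reproduction of the original inventory.  Correlation-matrix PCA on the
  normative rows retains components with eigenvalue >= 1; per aspect the
  parameter with the highest |correlation| with any retained component is
  kept; deviations are `min(|z|, 3)/3` so the score lives in [0, 1] (the
  source's exact 0-1 standardisation is not published; the cap of 3 SDs is
  this package's choice).

## Statistics

Spearman rho with tie-corrected ranks; p-values by the t approximation for
n > 10 and by permutation for n <= 10 (exhaustive for n <= 8, 100,000
seeded permutations for n = 9-10).  One BH family per reported table,
step-up adjusted p-values, significance at alpha = 0.05 on the adjusted p.
Subgroup testing: per-group Shapiro-Wilk, a Welch one-way ANOVA omnibus
(closed form, tested against the squared two-sample Welch t), and all
pairwise Welch t-tests with Welch-Satterthwaite degrees of freedom.  The
omnibus is Welch's one-way ANOVA rather than a repeated-measures ANOVA:
the subgroups are independent samples, so a repeated-measures structure
does not apply.

## Synthetic cohort generator

The generator is a statistical stand-in for walking trials, not a
biomechanical model.  Per sensor location and channel it holds fixed
5-harmonic Fourier templates (frozen seed, so the synthetic world is stable
across releases); kinematic variables hold 3-harmonic templates with
typical amplitude scales (e.g. ~55 deg knee flexion range, ~5 deg pelvic
obliquity).  A subject has a base cadence (~1.1 s cycles, 5% between-subject
SD), per-cycle duration jitter (CV 2% at severity 0), and a severity
parameter d in [0, 1] that jointly deforms signals and kinematics:
channel-wise amplitude scaling (fixed direction plus subject random
effect), channel-wise phase shifts, alternating-cycle asymmetry (15% at
d = 1), kinematic offsets of 2-5 degrees at d = 1, reduced stride length
and swing apex, slower cadence, and inflated noise.  Controls are d = 0.

Two noise processes exist besides sensor noise: per-cycle amplitude
variability (CV 6%) and per-cycle phase jitter (SD 1% of the cycle) on the
signals.  Without this stride-to-stride waveform variability consecutive
cycles are near-identical template copies — unlike any real gait recording —
and HMM emission covariances collapse to the sensor-noise floor, making
every state pair appear infinitely separable.  Kinematic curves stay
exactly template-plus-noise at d = 0 (their per-cycle amplitude variability
is proportional to d), so at severity 0 the expected per-variable GVS is
the kinematic noise SD (1 degree).

Default cohort: 30 controls plus patient subgroups of 10/7/6/3 (the four
prosthetic-user types), three bilateral users, severity ranges per subgroup
chosen so the rotationplasty group is most affected and the transtibial
group least (TT 0.15-0.45, TF 0.25-0.60, VN 0.50-0.90, LS 0.35-0.75);
patients get >= 100 segmentable cycles, controls >= 50.  Foot-contact and
toe-off events are emitted by construction (stance fraction 60% at d = 0),
so event detection is out of scope.

**What a green synthetic test establishes** — that the implementations are
internally correct and that the measures respond to a known severity signal
with the expected sign and ordering.  It does not establish clinical
validity: the generator has no musculoskeletal constraints, its severity
axis is one-dimensional, its deformations are smooth and global, and the
published cohort's effect sizes cannot be reproduced because the original
recordings are not available.

## Scaled validation runs

`gaitsm.validation.run_scaled_study` runs the complete design at reduced
size (10 controls x 10 normative cycles, 16 patients x 50 cycles with
severities on an even grid over [0, 1]) with one sensor configuration (the
lower legs, the best-performing location), window stride 5, two EM restarts
and 100 iterations so it fits a single CPU in minutes; `deviation_sweep`
scores 5 fresh subjects per severity level against one normative model.
These back `scripts/acceptance.py` and the acceptance tests; the full-size
defaults remain in `StudyConfig`.

## Known limitations

- The HMM-SM depends on EM training consistency; with few cycles or states
  the score can vary between seeds (the window/restart machinery mitigates
  but does not remove this).
- The MGS parameter inventory is an approximation; its published behaviour
  (including the inverted correlation with GPS reported for real cohorts)
  should not be expected to transfer to the synthetic world.
- Bilateral users' INI/MGS parameters are averaged over sides on all
  segmentable cycles rather than a sampled subset.
- Sample entropy is computed on a length-capped series (1200 frames) for
  tractability.
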