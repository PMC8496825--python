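# Methods

`albring` simulates a two-stage model of head-direction (HD) stabilization:
a subcortical ring attractor integrates angular velocity, and a cortical
pathway learns a sparse code for the egocentric bearing of the whole
landmark array ("abstract landmark bearing", aLB) that is fed back through
retrosplenial layers to correct path-integration drift. This note documents
the model equations as implemented, the calibrated defaults, the synthetic
inputs, and the numerical and design choices that were genuinely open.

## Rate neurons

Every layer is a population of rate units. Rates follow a thresholded
hyperbolic tangent of the activation, f = tanh(beta (a - alpha)) for
a >= alpha and 0 otherwise, clipped to [0, 1]. Activations obey leaky
integrator dynamics tau da/dt = -a + sum_j g_j W_j f_j, integrated with
explicit Euler at a global step dt = 5 ms (configurable; all time constants
are 20 ms, so dt/tau = 0.25). Explicit Euler is first-order: the relative
error of free decay at dt = tau/100 is ~2% over four time constants and
halves with dt; none of the model's conclusions depend on integrator
accuracy at that level, and the acceptance suite checks dt-robustness by
halving dt.

Within-layer inhibition is fixed: *global* inhibition is the rank-one matrix
J/N (every neuron, itself included), *lateral* inhibition is (J - I)/(N-1)
(zero diagonal). Both are row-stochastic, so the inhibition a single active
neuron exerts on another scales like 1/N; gains on these matrices therefore
have magnitude of order N where winner-take-all behavior is required.

## Visual world

An environment is a set of distal cues, each owned by one feature channel
(color-like identity). A channel holds `n_per_channel` = 360 neurons with
egocentric preferred directions tiling [-180, 180) at 1 degree (0 = ahead;
anticlockwise positive). Cue shapes:

- unimodal: scaled von Mises f(theta) = fmax exp(kappa (cos(theta-phi)-1)),
  default kappa = 20;
- broad: von Mises bumps tiled across `width` (default 90 deg) and rescaled
  to fmax — a plateau whose shoulders follow the von Mises CDF;
- bimodal: two summed unimodal bumps (an ambiguous, 180-degree-symmetric
  landmark when the centers are antipodal);
- constant: direction-independent rate, used for odors.

Cues may be static, rotate at fixed speed, teleport to a seeded uniform
random direction at a fixed period, or exist only inside a time window.
Because all cues are distal, a cue's egocentric bearing is
wrap(center - HD), independent of location.

Each channel sums its cues' profiles at their current bearings, optionally
adds background noise (a low-amplitude broad von Mises bump at a random
center, amplitude `noise_amp`, default off), and is then rescaled so that
every channel containing an active cue has the same mean rate
(`target_mean` = 0.08). This mean normalization emulates upstream
adaptation; it is what makes narrow cues more salient (higher peaks) than
broad ones and what makes a newly appearing cue "count" as much as familiar
ones. Channels with no active cue are not rescaled, so silent channels stay
silent. A separate noise mode adds uniform positive noise with 1-norm equal
to a fraction (e.g. 5%) of the channel's 1-norm, redrawn every step, used by
the noisy capacity protocol. For speed, cue profiles are rendered from
cached templates shifted circularly (linear interpolation between
whole-degree rolls); integer-degree geometry is exact, which preserves the
shift-equivariance property on the grid.

## aLB layer and the modified Oja Subspace Algorithm

N_aLB = 360 cells receive every visual channel through non-negative plastic
weights and inhibit each other laterally (gain g_lat = -0.75 (N-1), i.e.
0.75 per cell pair) — winner-take-all competition. Activations are floored
at a_min = -1 so that losing cells can re-enter competition quickly. The
feed-forward gain g_vis = 0.45 is divided equally among channels currently
carrying signal (divisive input normalization); with it, sceneries with two
or five active features drive the layer on the same scale, which keeps one
set of thresholds valid across all protocols.

Weights evolve by the modified Oja Subspace Algorithm, applied once per
integration step with the current rates:

W_j <- [ W_j + eta f_aLB (f_vis_j - zeta W_j^T f_aLB)^T ]_+

The feedback term W^T f_aLB is the visual input the current aLB activity
"expects"; the update moves weights in proportion to the prediction error,
which depresses connections from absent features (this is how cells
disconnect from moved, teleported or removed cues) and acts as a
potentiation threshold that keeps the code sparse. [.]_+ clips negative
entries to zero (synapses do not change sign); a prefactor zeta > 1 on the
feedback term is exactly compensated by eta -> eta/zeta with the input gain
scaled up by zeta (the package tests this equivalence to machine precision).
eta = 0.001 per step: slow enough that a cell transiently co-active in a
foreign environment is not re-trained away from its own (this is what
preserves early environments in long multi-environment runs), fast enough
that weights converge well within one 20-minute session.

Initial weights are i.i.d. uniform on [0, 0.55]. This scale is a calibrated
compromise with a real trade-off behind it: untrained cells must be drivable
enough that a novel scene recruits fresh cells instead of re-using partially
matching trained ones, but quiet enough that they stay below the recruitment
threshold whenever a trained winner is active. With the activation threshold
alpha = 2.4 and slope beta = 2.0, a fully matching trained cell (drive ~5)
saturates, a 2-of-3-cue partial match (drive ~3.0) stays below rate 0.5
under winner inhibition, and the untrained reservoir (drive ~3.6 +/- 0.14)
fires only where no trained cell covers — which is also how coverage gaps
self-fill during learning.

Alternative rules (for the comparison study) share the interface: plain
Hebbian (the outer-product term alone), Hebbian covariance (running-mean
centered, EMA time constant 200 steps), Intrator-style BCM (sliding
threshold = EMA of f^2), and the original OSA (no clipping, no sign
constraint). Under the ambiguous two-cue scenery only the clipped,
laterally-inhibited subspace rule yields all-unimodal recruited cells; plain
Hebbian cells inherit the bimodal ambiguity of the red channel.

## Ring attractor

N_HD = 360 neurons; symmetric kernel amp * exp(kappa_a (cos d - 1)) -
inhibition/N with kappa_a = 12, amp = 0.05, inhibition = 3.2 — a stable
bump ~55 deg wide at half max that holds direction indefinitely at rest.
The velocity input multiplies the antisymmetric kernel, which is the exact
angular derivative of the symmetric one. For that kernel pair the continuum
traveling-bump solution moves at exactly gain*omega/tau, independent of bump
shape, so the analytic gain tau*pi/180 is already correct to ~1% and a
one-off simulate-and-decode calibration (cached per attractor spec) brings
tracking error below 0.4% for |omega| <= 400 deg/s. Fast rotations are
sub-stepped so the bump moves at most ~0.5 deg per substep. Path-integration
drift (the phenomenon the feedback must fix) is emulated by a gain mismatch
(pi_gain, e.g. 1.05) since a noiseless attractor cannot drift by itself; a
noise mode is a trivial variant.

## Retrosplenial loop and feedback

gRSC receives the attractor 1-to-1 (gain 1.5) under mild global
self-inhibition — a relay of the unimodal HD signal. dRSC receives gRSC
through the plastic matrix W_g2d and the landmark input (aLB rates, or
stacked visual channels in the direct variant) through W_in2d, under strong
global self-inhibition (gain 8) so only the best-matched cells stay active.
Both afferents are classic Hebbian (dW = eta f_post f_pre^T, learning frozen
in test phases) with per-row two-norm capping. The row cap is implemented as
a cap — rows are scaled *down* when they exceed w_max — although the printed
form of the normalization (max{w_max/||w||, 1}) would instead raise every
sub-cap row to exactly w_max; both behaviors are selectable
(`norm_mode="cap"|"grow"`), the cap being the default because w_max is
described as the *maximum* total connection strength.

Two structural choices make the feedback loop well-posed:

- **dRSC cells have initial preferred directions.** Each cell's initially
  random gRSC afferent carries a weak von Mises bias (amplitude 0.05, kappa
  8) toward one HD, and the fixed 1-to-1 feedback connects the cell to the
  attractor neuron with that direction (cells are labelled by their initial
  preferred direction). Without the bias, the direction a cell happens to
  learn is uncorrelated with the attractor neuron its feedback targets, and
  the loop scrambles the estimate it is meant to correct.
- **dRSC is landmark-dominant.** The gRSC afferent cap is low
  (w_max_g2d = 0.3, gain 0.3) while the landmark afferent is strong
  (w_max = 1, gain 4): a dRSC cell barely fires from the internal estimate
  alone, and fires hard when the learned landmark input arrives. The dRSC
  bump is therefore pinned to what the scene says rather than tracking the
  (possibly drifting, and always slightly lagging) internal state — feedback
  corrects rather than drags. Early in learning, before associations exist,
  dRSC is nearly silent and the attractor path-integrates undisturbed, which
  is what lets the associations form against a correct internal signal.

Feedback enters the attractor as g_fb (P f_dRSC - mean), i.e. 1-to-1
excitation plus global inhibition. g_fb = 0.5 in the full model: strong
enough to ignite a new bump at a remote scene-consistent direction (a 120
degree correction is a jump, not a slide). The direct variant uses
g_fb = 0.15, *below* the remote-ignition threshold, together with its own
input gain (0.5), initialization (0.01) and Hebbian rate (5e-5) for the
dense visual afferent — the alternative network has its own hyperparameter
set, as in the reference study. At sub-ignition feedback the attractor can
only be captured by the nearest feedback peak, which is exactly why the
direct model follows the ambiguous narrow cue 60 degrees clockwise after a
120-degree anticlockwise scene rotation while the full model, whose
conjunctive aLB code offers no 60-degree interpretation, follows the true
rotation.

Heterogeneous dRSC learning (het_eta) sets the Hebbian rate of a random
half of the population to ~0: those cells keep their initial unimodal
preference per compartment, reproducing between-compartment bidirectional
cells next to the within-compartment bidirectional cells the trained half
develops in mirrored environments.

## Trajectories

Learning phases run on a 20-minute HD trajectory. The recorded-data reader
accepts MAT files (HD series plus optional dt/fs; angular velocity derived
by wrapped finite differences when absent). Since no recording ships with
the package, the seeded synthetic generator is the default input: angular
velocity is an Ornstein-Uhlenbeck process with 0.5 s correlation time
(naturalistic head turns, symmetric zero-mean velocity), rescaled exactly so
the realized mean |omega| equals the target 72.88 deg/s; HD is the wrapped
integral. Test phases freeze all plasticity and rotate uniformly at 60 deg/s
for 60 s starting from the last learning HD, sampling every 1-degree HD bin
10 times.

## Quantification

Internal HD is decoded by the population vector (rate-weighted circular mean
of preferred directions; undefined for a zero resultant, e.g. a perfectly
antipodal pattern, and raised as an error rather than guessed). Tuning
curves are mean rates per 1-degree true-HD bin from test-phase logs. A cell
is *recruited* if its peak test rate reaches epsilon_aLB = 0.5; unimodality
is the number of contiguous circular runs of supra-threshold bins.
Similarity of recruited sets is the Jaccard index (IoU); the IoU of two
empty sets is defined as 0 so silent populations never count as similar.
Heading errors are circular means with circular-SD-based standard errors;
signed errors here are small so circular vs arithmetic aggregation is
benign.

## Protocols and scaling

The scenario library parameterizes every study condition: the two-cue
ambiguous scenery; moving (90 deg/s) and teleporting (10 s period) cue
variants; the novel-cue appearance (due West between 400 s and 800 s); the
sequential 10-environment capacity protocol (shared red/blue, green rotated
36 deg anticlockwise per environment, 120 s dwell, HD continuous across
transitions); the 180-degree mirrored pair (60 s alternation); the
120-degree scene rotation; the multi-environment retrieval comparison; a
20-environment rich-capacity protocol (3 cues drawn seeded from 6 features,
uniform random directions); the 5% uniform-noise capacity variant; and
darkness (no visual input, pi_gain mismatch). `duration_scale` shrinks all
dwell times proportionally while layer sizes, gains and dt stay fixed, so
each scenario has a fast miniature twin in the same dynamical regime; the
shipped tests and the acceptance script run at scales between 0.1 and 0.5
(dwell times of 60-240 s rather than the full 20 minutes), which the
convergence diagnostics show is comfortably past weight convergence for the
default learning rates. The miniature fixtures additionally shrink the grid
to 36 neurons per channel and 72 aLB cells, rescaling g_vis by 360/n_vis and
g_lat by (n_alb - 1) to preserve drive scales.

## What the synthetic world does and does not show

The generator reproduces the statistics the model is sensitive to: mean
angular speed and smoothness of head turns, cue geometry, saliency ordering
imposed by mean normalization, and cue instability (motion, teleportation,
appearance). It does not emulate parallax or proximal cues (all cues are
distal by assumption), retinal preprocessing, attention, location-modulated
firing, or realistic sensory noise spectra. Passing tests therefore show
that the algorithms have the claimed computational properties under the
stated model of the world, not that the parameters fit any particular
animal's data.

## Known limitations

- Hyperparameters are calibrated to the qualitative target behaviors, not
  fitted to recordings; other parameter sets may work as well.
- The full model's distant correction is an ignition event with a gain
  threshold; very close to that threshold the corrected direction can
  undershoot by a few degrees (re-association during the post-rotation
  period pulls slightly back).
- Learning-phase tracking with immature associations can transiently wander
  by tens of degrees for unlucky seeds before the feedback locks in; the
  associations then stabilize the offset the moment it locks.
- At miniature scale (36-neuron channels), tuning lobes can be split by
  single-bin sampling gaps; the unimodality statistics are meaningful at
  the default 360-neuron scale.
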