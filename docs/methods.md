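# Methods

`hemisim` simulates post-stroke hemiparesis and rehabilitation in a
bilaterally symmetric convolutional network that performs stereo-guided
reaching with two muscle-actuated arms.  This note records the model, its
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## Arm model

Each arm is a two-link kinematic chain with three degrees of freedom —
shoulder flexion, shoulder rotation, elbow flexion — each driven by an
agonist/antagonist muscle pair, six muscles per arm.  Joint angles follow

    theta = (MN_ag - MN_an) * pi/2 + pi/2,

so activations in [0, 1] give angles in [0, pi], and co-activation at 0.5
gives the neutral pi/2.  Upper arm and forearm are 0.3 workspace units each
(arm length 0.6); shoulders sit at x = +/-0.15 with the workspace origin at
the hollow of the neck.  The hand position composes shoulder-relatively in
row-vector order:

    H = [(H_o - E_o) R_E + (E_o - S_o)] R_S1 R_S2 + S_o

with R_E and R_S1 rotating about the y-axis and R_S2 about the z-axis, so
zero angles reproduce the rest configuration (hand at (+/-0.15, 0, 0.6)).

**Sign convention for shoulder flexion.**  Each rotation admits two sign
conventions.  With flexion signed the other way, R_S1 points the flexed arm
*away* from the front workspace: the reachable set then lies almost entirely
at y <= 0 while every target box has y > 0, and fewer than 3% of workspace
targets can be reached at all.  We therefore measure shoulder flexion toward
the front (+y) — the unique choice under which 99.7% of the
within-arm-length workspace is reachable and the neutral pose (all
activations 0.5) lands at (+/-0.15, 0.3, 0.3), in the middle of the front
workspace.  This neutral pose is the home position used for resting arms.

The kinematics are closed-form and differentiable; an analytic Jacobian
(`hand_jacobian`) carries endpoint-error gradients into the network.
Numerical tolerance for the kinematic invariants (segment lengths, mirror
symmetry, reachability bound) is 1e-9 absolute.  The model is deliberately
static: no muscle dynamics, forces, or trajectories — reaching is one-shot.

## Visual input

Scenes are rendered analytically rather than with an external 3D tool: one
shaded sphere in front of a blank wall, viewed by two pinhole cameras at
x = +/-0.03 (interocular stand-in), placed at y = -0.5, z = 0.2 and looking
along +y.  The renderer preserves the cues that carry target position:

* image-plane location = pinhole projection of the sphere centre,
* apparent radius scaling with 1/depth (perspective size cue),
* horizontal disparity between the views, strictly decreasing with depth,
* a Lambertian shading gradient standing in for glare/shadow,
* an antialiased rim so sub-pixel position shifts survive discretisation.

Colour is a per-variant grey intensity; a dataset uses 3 joint
(colour, size) variants — radii (0.06, 0.08, 0.10), levels (1.0, 0.75, 0.5)
— so the network cannot key on appearance.  Resolution, camera geometry and
palette are configurable; the focal length is 0.375x the image width so the
full workspace projects inside the frame.

Datasets combine a target grid with the four hand-selection parameter (HSP)
modes — rest [0 0], unimanual right [0 1], unimanual left [1 0],
bimanual-joint [1 1] — and the variants: |positions| x 3 x 4 samples.  The
default grids hold 1174 training and 450 test positions drawn uniformly over
the union of the left and right workspaces (x in (-0.6, 0.6),
y in (0, 0.6), z in (-0.1, 0.5)).  An active arm's required endpoint is the
target; an inactive arm's is its home pose.  Because an arm is a 0.6-long
chain anchored at x = +/-0.15, the far contralateral workspace is physically
out of reach; unimanual samples therefore present the sphere on the active
arm's side (x-mirror of the grid position when needed — the two side
boxes are exact mirror images), while bimanual-joint samples keep one
shared target for both arms.  Two-object (bimanual-independent) scenes are
available
but excluded from the default grids, which use the single-target joint task.

## Network

Two vertical halves, each: five 5x5 stride-1 same-padded convolutional
layers with 2, 4, 8, 4, 2 feature maps (ReLU; one 2x2 max-pool after
layer 1) and three fully connected layers of 50, 30, 6 sigmoid units.  Both
halves receive the full two-channel stereo stack; the two HSP bits join the
input of fc6 on both halves (hand selection is a motor-side signal; the
convolutional stack stays purely visual).  Cross-connections exist at
exactly two levels — conv1 -> conv2 and fc6 -> fc7 — as dedicated weight
blocks mixing the contralateral layer into the ipsilateral next layer, so
they can be ablated individually.  Each half's six outputs drive the
ipsilateral arm.

Training minimises the summed squared endpoint error of both hands, with
gradients flowing through the arm kinematics, plus an L2 penalty (1e-4) on
all weight matrices.  The optimiser is Adam (the study's learning rate of
1e-4 at full scale), minibatch 32, Glorot-initialised weights, all seeded
and bit-reproducible per seed.  No deep-learning framework is used: the
forward/backward passes are written directly on numpy (im2col convolutions)
and validated against central finite differences at 1e-4 relative tolerance.

## Stroke induction

* **Acute lesion:** the activations of nodes 1..n (n in {5, 10, 15, 20}) of
  the *left* half's 30-node penultimate layer are clamped to zero on every
  forward pass, permanently.  Because those nodes feed only the left output
  layer, right-arm behaviour is bit-identical pre/post lesion — the model's
  hemiparesis is exact.  The same site is lesioned in every model.
* **Chronic stage (learned non-use):** the lesioned model trains for 10
  further epochs on right-arm-only samples (HSP [0 1]; the [0 1] subset of
  the training grid).  All unclamped weights may drift — this phase models
  everyday use, not therapy.  10 non-use vs 30 healthy epochs keeps the 1/3
  chronic/healthy budget ratio.
* **Callosal integrity:** a fraction (1 - p), p in {0.5, 0.7, 0.9}, of the
  motor-side cross-connection weights (both fc6 -> fc7 blocks pooled) is
  chosen at random, set to zero, and excluded from all later training —
  structural loss, not retrainable.  Visual-side cross-connections are never
  degraded.

## Rehabilitation

Therapy retrains the impaired model on 300 rendered target presentations:

* **Complexity.**  *Stereotypic*: M = 30 unique targets in the small
  box (left arm: -0.3 < x < -0.2, 0.25 < y < 0.35, 0.05 < z < 0.15), each
  presented N = 10 times (M x N = 300; the M/N split is our choice — few
  points, many repetitions, as in task-oriented practice).  *Exploratory*:
  300 distinct targets over the paretic arm's full workspace.
* **Hand mode.**  CIMT fixes HSP [1 0] (only the paretic left arm moves; the
  resting right arm's home-endpoint term stays in the loss); BMT fixes
  HSP [1 1] (both arms to the same target in the paretic workspace).
* **Plasticity.**  *Local* retrains only the lesioned layer's afferents —
  the lesioned (left) half's ipsilateral and cross fc6 -> fc7 blocks and
  fc7 bias; *global* retrains everything.  The lesion clamp and ablated
  callosal weights are preserved in either case.

Rehab runs 10 epochs over the 300 presentations (configurable; the same
order as the non-use phase).  Colour/size variants cycle over presentations.

## Evaluation and statistics

Performance is the Reaching Error, RE = ||x_target - x_hand||_2, averaged
over the test grid; rest-mode samples are excluded from all stroke analyses.
Targets with RE > 0.06 (one tenth of the arm length) count as inaccessible.
Each arm's mean is taken over the samples in which it is active.

Group comparisons use per-seed mean paretic-arm RE (5 independently
initialised models per group) as the statistical unit.  A Levene test
(centred on the mean) gates the branch: homogeneous variances -> one-way
ANOVA with Tukey HSD post-hoc; heterogeneous -> Welch ANOVA with Dunn's
rank-based pairwise tests under Bonferroni correction.  Significance is
p = 0.05 throughout.  The protocol recommendation rule: global plasticity is
recommended for a (stage, lesion size, integrity) condition only when it is
significantly better than local under at least one hand mode of exploratory
therapy; ties go to local, the cheaper protocol.

## Scaled-down (desk) profile

The full profile (64x64 views, 1174/450 positions, 30 epochs, Adam 1e-4) is
the study condition but costs hours of CPU per model.  Experiments, tests
and the acceptance script run a documented scaled-down replica: 16x16 views,
150-position grids, identical epoch budgets and ratios (30/10/10), Adam step
1e-3.  The larger step compensates for having roughly one eighth of the
gradient steps per training run; at 1e-4 the desk-scale healthy model stays
grossly underfit (mean RE ~0.26 against a 0.039 reachability floor), which
was diagnosed from training curves before any acceptance quantity was
measured.  Relative effects — lesion-size monotonicity, exact right-arm
containment, chronic-worse-than-acute, therapy orderings — are the
quantities expected to transfer across scales; absolute REs are not.

Two irreducible error floors are worth keeping in mind when reading desk-
scale numbers: ~17% of each side's workspace box lies beyond the 0.6
arm length (box corners), and bimanual-joint samples keep the shared
target, unreachable by the contralateral arm in its far half.  A perfect
controller still scores mean left RE ~0.039 on the desk test grid.

Two full-scale phenomena do *not* survive the scale-down, and the
corresponding acceptance tests fail by design rather than being weakened:

* **Accessibility maps.**  At 16x16 the focal length is 6 px, so one pixel
  of image position spans ~0.13 workspace units and the sphere is
  sub-pixel; the healthy model plateaus around mean left RE 0.13, leaving
  most targets above the 0.06 threshold with no peripheral structure.  The
  "few inaccessible targets, at the workspace edges" picture needs a
  visual resolution and data scale beyond desk cost.
* **Small-lesion plasticity equivalence.**  Because the desk-scale healthy
  baseline is still on its learning curve, global retraining during
  therapy continues general learning and beats local plasticity even for a
  5-node lesion (its post-rehab error undercuts the healthy baseline
  itself, showing the gain is not lesion compensation).  The large-lesion
  and chronic preferences for global plasticity, which rest on relative
  comparisons, do reproduce.

## What the generator does and does not emulate

The synthetic scenes carry position, perspective size, disparity, and a
shading gradient, but not the photorealistic wall/shadow/glare of a real
render, nor occlusion or texture.  Passing tests therefore show that the
*mechanisms* — bilateral convolutional control, lesion-induced impairment,
therapy-dependent recovery — behave as claimed under clean visual input;
they do not certify performance on natural images, nor clinical validity of
any protocol recommendation.

## Known limitations

* One-shot reaching: no trajectories, velocities, forces, or feedback.
* Lesions only in the penultimate motor layer; no visual-pathway lesions.
* Muscle deterioration in chronic stroke is not modelled.
* The ipsilateral-control convention (each half drives its own-side arm) is
  a simplification of contralateral cortical control.
* Desk-scale absolute REs are optimisation-limited; only orderings and
  interaction patterns are interpreted.
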