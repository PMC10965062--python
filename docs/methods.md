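# Methods

This note documents the models, conventions, numerical choices, and known
limitations of `videogait`: what each pipeline computes, what the synthetic
walker does and does not emulate, and which design decisions were genuinely
open.

## Measurement model

### Coordinates and events

OpenPose BODY_25 JSON stores raw image pixels (origin top-left, y down).
Analysis coordinates flip the vertical axis (positive up) and orient the
horizontal axis per view: frontal — positive toward the participant's left
(seen from behind while walking away, the participant's left is image-left,
so x is negated; walking toward the camera it is image-right); sagittal —
positive in the direction of travel. The transform is affine and
invertible; confidences are untouched. Keypoints with confidence below 0.1
are treated as absent (OpenPose writes exact zeros for non-detections; 0.1
discards only those and near-garbage).

Heel-strikes and toe-offs are extrema of relative trajectories:

* **sagittal video** — per side, positive/negative peaks of
  `ankle_x − midhip_x` after zero-lag 4th-order Butterworth filtering at
  5 Hz;
* **frontal video** — extrema of `left_ankle_y − right_ankle_y`. Walking
  away, positive peaks are left heel-strikes and negative peaks right
  heel-strikes; the mapping reverses walking toward the camera. Only
  heel-strikes are emitted from the frontal view;
* **marker data** — per side, peaks of the anterior-posterior ankle marker
  relative to the torso, filtered at 7 Hz.

Peak-picking parameters are scale-free: the minimum separation between
same-sign peaks is 0.4× the stride period implied by the dominant frequency
of the signal (estimated above max(0.35 Hz, 3/duration) so the bout
envelope of short walkway trials cannot masquerade as the stride), and the
minimum prominence is 20% of the signal's interquartile range. Detected
peaks are refined to sub-frame precision by parabolic interpolation through
the sample maximum and its neighbours; event times are therefore real
numbers, not frame indices. The frontal difference signal is additionally
smoothed at 6 Hz (zero-lag) before peak picking: the gait content sits
below ~2 Hz and the far-range peaks are small enough that pixel noise
otherwise scatters their location by several frames.

### Frontal depth and spatiotemporal parameters

Torso pixel size is measured as torso height (neck–mid-hip vertical
distance, the default), shoulder width, or the square root of their product
(so that every representation scales linearly with inverse depth). The size
series is divided by its median over a reference window — trial start until
0.3 s before the first heel-strike, minimum 5 frames, when the person
stands at the known reference depth — and the ratio is low-pass filtered at
0.4 Hz (zero-lag). Depth-change then follows from the pinhole inversion
`Δd = d_ref/s_ratio − d_ref`; neither the focal length nor the subject's
size enters. Walking direction is auto-inferred from the ratio trend
(shrinking torso = walking away) and can be overridden. Step time is the
interval between consecutive bilateral heel-strikes, step length the
absolute depth travelled over it, speed their quotient; each step carries
the side of its terminating heel-strike (a left step ends at a left
heel-strike — the paretic/left convention for hemiparetic gait). Depth is
read at event frames (nearest frame); linear sub-frame interpolation is
available behind a flag.

The 0.4 Hz smoothing needs time to settle: on short bouts its transient
from the standing-to-walking onset leaks into the first and last steps.
Pipelines therefore trim two steps per end by default (gait initiation and
termination are transient anyway), and validation compares cycles matched
against reference events — the same same-cycles principle used when
comparing two real measurement systems.

### Sagittal parameters, kinematics, and trunk lean

A single scale factor (known distance along the line of progression over
its pixel length) converts pixels to meters. Two step-length definitions
are implemented: the horizontal ankle-to-ankle distance at the instant of
the terminating heel-strike (the definition comparable to motion capture),
and the torso (mid-hip) travel between heel-strikes (the definition shared
with the frontal workflow). Torso travel is systematically longer than the
ankle distance because the trailing ankle has already rolled forward over
the forefoot at the contralateral strike; the package reproduces the sign
of this difference and treats its magnitude as walker-dependent.

Step *positions* are sampled, at the sub-frame event times, from the
gap-filled **unfiltered** trajectories. Zero-phase smoothing clips
trajectory extrema exactly where the heel-strike positions are read — on
synthetic data the 5 Hz filter shortens ankle-distance step lengths by
3–7% — so the filter is reserved for event detection and angle curves,
where it belongs.

Joint angle conventions (the keypoint triplets define the segments; the
sign conventions are this package's choice and are anchored by tests):

* hip — thigh segment (hip→knee) angle from the downward vertical, flexion
  (knee forward) positive;
* knee — angle between thigh and shank; 0 at full extension, flexion
  positive, hyperextension negative;
* ankle — angle between shank (knee→ankle) and foot (ankle→hallux) minus
  90°, dorsiflexion positive (computed as an unsigned deviation, hence
  mirror-invariant);
* trunk inclination — mid-hip→neck angle from vertical at heel-strikes,
  forward lean positive, minus a configurable 12° offset that aligns
  video keypoints with marker-based trunk definitions (keypoints and
  markers track similar but not identical anatomy).

### Aggregation and agreement

Session summaries average trial means (each walking bout weighted equally,
as in a clinical session of repeated bouts); a pooled-step mode exists for
step-level comparisons. Asymmetry indices are (side A − side B)/(A + B)
with side A the paretic/left side, computed per trial and averaged.
Speed-change deltas are fast-minus-preferred elementwise. Agreement between
systems reports mean difference ± SD, mean absolute error ± SD, 95% limits
of agreement (mean ± 1.96 SD), and Pearson r, on pairs matched by greedy
nearest-time heel-strike correspondence (default window 0.25 s). Kinematic
waveforms are compared as MAE over gait cycles resampled to 101 phase
points (0–100%) by linear interpolation.

## The synthetic walker

The generator is kinematic — prescribed trajectories, not locomotor
dynamics — because the artifact under test is the *measurement* chain, not
gait physics. It emulates the features the pipelines are sensitive to:

* footfalls spaced by commanded per-side step lengths and times, with
  left/right asymmetry as (L−R)/(L+R) indices and scaled initiation and
  termination steps (0.45 and 0.8 of the commanded length) at both ends of
  the bout, preceded/followed by quiet standing;
* a pelvis that advances through mid-stance knots on a monotone spline,
  with vertical vaulting over the planted foot (inverted-pendulum-like)
  and legs posed by two-link inverse kinematics (infeasible commands —
  step length beyond leg geometry — raise an error);
* a stance-to-swing sequence per foot: heel-off roll (the ankle shifts
  ~5 cm forward, completing exactly at the contralateral strike, so the
  ankle-to-ankle distance at a strike equals the commanded step length),
  push-off over the forefoot starting half a frame after the contralateral
  strike and faster than the pelvis advances, swing with ground-skimming
  terminal approach, and a constant-deceleration heel-rocker landing that
  crosses the pelvis speed exactly at contact — which makes the
  ankle-forward-of-pelvis curve peak smoothly *at* the strike, i.e. the
  walker realizes the event definition the detectors use;
* pinhole projection into frontal (camera 1.52 m behind the start, or
  beyond the far end for toward-walking) and sagittal (6 m to the side,
  aimed at the middle of the steady-state volume) cameras, with a step
  width of 0.12 m by default (set 0 for a strictly in-plane walker);
* a corruption model: Gaussian pixel noise, confidence-zero dropout, and
  left/right label exchanges on logged frames — all seeded and
  reproducible bit-exactly.

`WalkerSpec.from_speed` solves the step length from a commanded gait speed
(accounting for heel-off roll and rocker travel) and sizes the bout to a
fixed walkway with a minimum walking time so the 0.4 Hz size-ratio
smoothing settles; fast walkers get a proportionally longer capture volume,
as they would in an overground protocol.

What the walker does **not** emulate, and therefore what passing tests do
not show about real data: soft-tissue and clothing artifact, pose-estimator
bias (its errors are modeled as unbiased Gaussian noise plus label swaps),
out-of-sagittal-plane trunk or pelvis rotation, double-support force
dynamics, camera distortion and rolling shutter, and pathological gait
patterns beyond parametric asymmetry and trunk lean. Real-data errors
reported in the literature for comparable workflows are larger than the
synthetic recovery errors here, and should be expected to be.

## Numerical choices

* Zero-lag filtering uses `scipy.signal.filtfilt` with its default
  odd-reflection padding (length ≈ 3× the filter order). Odd reflection
  extends ramp-like signals linearly, which matters for the 0.4 Hz stream;
  even reflection would fold the depth ramp into a V at the edges.
* Gap filling linearly interpolates interior missing runs of duration
  ≤ 0.12 s (inclusive boundary, run length/fps); longer and edge runs stay
  missing, and leading/trailing gaps are never extrapolated.
* The left/right corrector keeps, per frame, the labeling that minimizes
  summed displacement from the last corrected positions over the paired
  lower-limb keypoints, with two safeguards: a hysteresis margin (a swap
  must beat keeping labels by 20%) so near-ambiguous leg-crossing frames do
  not flip-flop, and a majority pass — if more than half the frames would
  be "corrected", the anchor frame itself was mislabeled and the decision
  set is inverted.
* Participant tracking anchors on the mid-hip keypoint (fallback:
  confidence-weighted centroid), with a jump threshold of 25% of the image
  diagonal per frame; near-ties are resolved by higher mean confidence and
  logged. A CSV override can pin identities on specific frames, and a
  frame-list override reproduces manual left/right edits.
* Degenerate inputs: flat signals yield no events (IQR-based prominence);
  fewer than two heel-strikes yield an empty step table; consecutive
  same-side strikes produce steps flagged invalid rather than silently
  dropped; zero-variance inputs make Pearson r NaN.

## Validation design

Recovery is always assessed on gait cycles cross-referenced with the
generator's steady-state events (matched-cycle comparison), because count-
based alignment breaks when initiation produces small extra extrema — the
same reason real studies cross-reference events between systems before
comparing parameters. Problem sizes in the acceptance script — 100 seeded
bouts per frontal condition, single bouts for the sagittal and event
checks, 10⁵ samples for the limits-of-agreement coverage — were chosen to
keep the full run under a minute while leaving the statistical checks
well-powered.

## Known limitations

* Frontal event detection degrades beyond ~8 m of subject depth when steps
  are short: the depth signature of a strike shrinks as 1/d² while the
  swing-lift signature shrinks as 1/d, so mid-swing bumps eventually rival
  strike peaks. Keep the subject within the validated range (reference
  depths up to ~7 m) or supply events externally.
* Sagittal step lengths use one scale factor at the plane of progression;
  with a realistic step width the two legs sit at slightly different
  depths, leaving a per-step out-of-plane error that grows toward the
  image edges (percent-level at a 6 m camera distance). Averaging bouts
  recorded from both sides cancels the side-specific component; the
  asymmetry metrics do exactly that.
* Frontal toe-offs are not emitted; sagittal toe-off timing is less
  accurate than heel-strike timing (push-off motion flattens the relative
  minimum) and is not used by the spatiotemporal parameters.
* The 12° trunk offset is dataset-derived, not anatomical; it is a
  configuration default, not a constant.
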