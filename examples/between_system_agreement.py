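"""Validate one measurement system against another with Bland–Altman
agreement statistics on matched gait cycles.

Here the frontal workflow plays the "new" system and the generator's
ground truth plays motion capture: heel-strikes are cross-referenced so
both systems score the same cycles, then differences, absolute errors, 95%
limits of agreement, and the Pearson correlation are reported per
parameter.
"""

import numpy as np

import videogait as vg
from videogait.agreement import agreement
from videogait.events import cross_reference_events
from videogait.pipeline import analyze_frontal_track

spec = vg.WalkerSpec()
points3d, truth = vg.simulate_walk(spec)
camera, setup = vg.frontal_camera(spec, truth)
trial = vg.project(points3d, camera, spec.fps)
trial, _ = vg.corrupt(trial, sigma_px=2.0, seed=11)  # realistic pixel noise
track = vg.to_gait_coordinates(trial, setup)
result = analyze_frontal_track(track, setup, trim_steps=0)

matched = cross_reference_events(result.events, truth.events, tol_s=0.25)
print(f"Matched heel-strikes: {matched.n_matched} "
      f"({len(matched.unmatched_a)} video-only, "
      f"{len(matched.unmatched_b)} truth-only; unmatched events are "
      "spurious noise detections that matching excludes)")

# build per-cycle pairs of (video, truth) step parameters
pairs = sorted(matched.pairs_left + matched.pairs_right)
video_steps = result.steps[result.steps["valid"]]
truth_steps = truth.steps
video, ref = {"step_time_s": [], "step_length_m": []}, {"step_time_s": [], "step_length_m": []}
for (va, ta), (vb, tb) in zip(pairs, pairs[1:]):
    if vb - va > 1.0:   # not a consecutive-step pair
        continue
    v_row = video_steps[np.isclose(video_steps["t_end_s"], vb)]
    t_row = truth_steps[np.isclose(truth_steps["t_end_s"], tb, atol=1e-6)]
    if len(v_row) and len(t_row):
        video["step_time_s"].append(float(v_row.iloc[0]["step_time_s"]))
        ref["step_time_s"].append(float(t_row.iloc[0]["step_time_s"]))
        video["step_length_m"].append(float(v_row.iloc[0]["step_length_m"]))
        ref["step_length_m"].append(float(t_row.iloc[0]["torso_travel_m"]))

for name, unit in (("step_time_s", "s"), ("step_length_m", "m")):
    rep = agreement(video[name], ref[name])
    print(f"\n{name} (video vs truth, n={rep.n}):")
    print(f"  mean difference {rep.mean_diff:+.3f} ± {rep.sd_diff:.3f} {unit}")
    print(f"  mean absolute error {rep.mean_abs_error:.3f} {unit}")
    print(f"  95% limits of agreement [{rep.loa_low:+.3f}, {rep.loa_high:+.3f}] {unit}")
    print(f"  Pearson r = {rep.pearson_r:.3f}" if np.isfinite(rep.pearson_r)
          else "  Pearson r undefined (zero variance)")
print("\nThe limits of agreement bracket ~95% of between-system differences; "
      "narrow limits mean the video system can replace the reference for "
      "that parameter.")
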