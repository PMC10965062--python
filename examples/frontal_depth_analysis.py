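"""Frontal-plane gait analysis: depth from torso pixel size.

A person walking away from a single frontal camera shrinks on the image
plane; under the pinhole model the torso size ratio equals
d_ref / (d_ref + Δd), so the depth-change Δd — and from it step lengths and
gait speed — follows from pixel sizes alone, with the focal length and the
person's physical size cancelling out.
"""

import videogait as vg
from videogait.pipeline import analyze_frontal_track

spec = vg.WalkerSpec()
points3d, truth = vg.simulate_walk(spec)
camera, setup = vg.frontal_camera(spec, truth)          # 1.52 m behind start
track = vg.to_gait_coordinates(vg.project(points3d, camera, spec.fps), setup)

result = analyze_frontal_track(track, setup)
steps = result.steps[result.steps["valid"]]

print(f"Walking direction (auto-inferred from size-ratio trend): {result.direction}")
print(f"Reference torso size s_ref = {result.size.s_ref:.1f} px at "
      f"d_ref = {setup.d_ref_m:.2f} m")
print(f"Detected heel-strikes: {result.events.heel_strikes_left.size} left, "
      f"{result.events.heel_strikes_right.size} right")
print("\nSteps from the depth-change series (torso travel between "
      "consecutive bilateral heel-strikes):")
print(steps[["side", "step_time_s", "step_length_m", "speed_mps"]]
      .round(3).to_string(index=False))
print(f"\nMean recovered gait speed: {steps['speed_mps'].mean():.3f} m/s")
print(f"Ground-truth steady speed:  {truth.gait_speed_mps:.3f} m/s")
print("The difference is the frontal workflow's measurement error on this "
      "noiseless bout (percent-level; pixel noise adds more).")
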