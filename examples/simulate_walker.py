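"""Generate a ground-truthed synthetic walking trial and inspect it.

The kinematic walker advances with commanded step length and step time,
including gait initiation/termination steps, and is projected by a pinhole
camera into OpenPose-format pixel keypoints. Everything a measurement
pipeline should recover is known exactly.
"""

from pathlib import Path

import videogait as vg

spec = vg.WalkerSpec(step_length_m=0.65, step_time_s=0.55, duration_s=7.5)
points3d, truth = vg.simulate_walk(spec)

print(f"Simulated {points3d.shape[0]} frames at {spec.fps:g} Hz "
      f"({points3d.shape[1]} keypoints).")
print(f"Steady-state gait speed: {truth.gait_speed_mps:.3f} m/s "
      "(torso advance per step / step time).")
print("\nGround-truth steps (side, interval, ankle step length, torso travel):")
print(truth.steps.round(3).to_string(index=False))

# project into a frontal camera 1.52 m behind the start and write OpenPose JSON
camera, setup = vg.frontal_camera(spec, truth)
trial = vg.project(points3d, camera, spec.fps)
out = Path("scratch/example_frontal_json")
vg.write_openpose_json(trial, out)
print(f"\nWrote {trial.n_frames} OpenPose JSON frames to {out}/ "
      f"(frontal view, reference depth {setup.d_ref_m:.2f} m).")
print("Transient rows mark gait initiation/termination; analyses usually "
      "work on the steady steps between them.")
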