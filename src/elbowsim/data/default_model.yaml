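# Default planar elbow + cable exosuit model.
# Units are SI throughout (kg, m, s, rad, N).
#
# Geometry convention: elbow at the origin; the upper arm is vertical
# (shoulder locked); the elbow angle theta is measured between the
# forearm and the downward vertical, theta = 0 with the arm hanging,
# increasing toward flexion.  Anchor coordinates: first component is the
# anterior offset, second the along-segment coordinate (up the humerus
# for the arm strap, out along the forearm for the forearm strap).
segment:
  forearm_mass: 1.53          # kg
  com_distance: 0.18          # m, elbow -> forearm COM
  inertia_about_elbow: 0.02   # kg m^2, sagittal-plane component
  upper_arm_orientation: 0.0  # rad, fixed (shoulder locked, arm vertical)
load:
  external_mass: 0.0          # kg; task sweep uses 0, 2, 5
  load_distance: 0.35         # m, elbow -> hand-held load
exosuit:
  # Anchor pair for the flexor cable.  The extensor cable
  # gets its own low posterior routing near the olecranon: a straight
  # segment mirroring the flexor anchors crosses to the flexion side of
  # the joint beyond ~25 degrees of flexion and would lose its extension
  # moment arm, so the posterior routing hugs the elbow instead.
  arm_anchor: [0.04, 0.14]      # m, upper-arm strap, upper-arm frame
  forearm_anchor: [0.02, 0.15]  # m, forearm strap, forearm frame
  extensor_arm_anchor: [-0.04, 0.06]
  extensor_forearm_anchor: [-0.04, 0.02]
gravity: 9.81                   # m/s^2, downward
gains:
  kp: 900.0   # 1/s^2, position-error feedback
  kv: 60.0    # 1/s,   velocity-error feedback
settings:
  sample_rate: 121.0        # Hz, control/reporting grid
  integrator_max_step: 0.008
  integrator_min_step: 0.0
  optimizer_tolerance: 1.0e-6
  rng_seed: 0               # reserved; the pipeline is deterministic
  inertia_about: elbow      # elbow | com (adds m*lc^2 if 'com')
  literal_dynamics_sign: false
muscle_file: arm26_muscles.yaml
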