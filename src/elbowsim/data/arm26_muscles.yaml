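# Six-muscle elbow set patterned on the publicly documented arm26 / Thelen
# planar upper-limb model.
#
# Provenance of each field:
#   max_isometric_force, optimal_fiber_length, tendon_slack_length,
#   pennation_at_optimal: transcribed from the openly published arm26
#   model parameters (OpenSim distribution; Thelen-type muscles).
#   max_contraction_velocity (10 optimal lengths/s) and the activation /
#   deactivation time constants (0.010 s / 0.040 s) are the standard
#   Thelen-muscle defaults.
#   moment_arm_coeffs: quadratic fits (ascending powers of elbow flexion
#   angle, radians; metres) to published elbow flexion moment-arm curves:
#   biceps peaking near 4-4.5 cm at mid/late flexion, brachialis near
#   2.5-3 cm, triceps near-constant 2.1-2.4 cm (extension).
#   mtu_length_coeffs: exact polynomial antiderivative of the (negated,
#   signed) moment arm, anchored so each fiber sits at its optimal length
#   at a 45-degree elbow angle (mid-range) under the rigid-tendon,
#   constant-thickness pennation model.  This enforces the geometric
#   identity d(MTU length)/d(angle) = -(signed moment arm) analytically.
#   origin / insertion: effective straight-line attachment points used
#   only for joint-reaction bookkeeping (force directions), in metres.
#   origin is in the (vertical) upper-arm frame, insertion in the forearm
#   frame; both frames share the elbow as origin, first coordinate is the
#   anterior offset, second the along-segment coordinate (up the humerus /
#   out along the forearm).
#
# Sign convention: +1 flexor, -1 extensor; flexor moment arms positive
# over the working range [0, pi/2] (0 = arm hanging fully extended).
muscles:
  - name: biceps_long
    sign: 1
    max_isometric_force: 624.3
    optimal_fiber_length: 0.1157
    tendon_slack_length: 0.2723
    pennation_at_optimal: 0.0
    max_contraction_velocity: 10.0
    act_time_constant: 0.010
    deact_time_constant: 0.040
    moment_arm_coeffs: [0.020, 0.030, -0.010]
    mtu_length_coeffs: [0.411346, -0.02, -0.015, 0.003333]
    origin: [0.010, 0.320]
    insertion: [0.005, 0.045]
  - name: biceps_short
    sign: 1
    max_isometric_force: 435.56
    optimal_fiber_length: 0.1321
    tendon_slack_length: 0.1923
    pennation_at_optimal: 0.0
    max_contraction_velocity: 10.0
    act_time_constant: 0.010
    deact_time_constant: 0.040
    moment_arm_coeffs: [0.018, 0.032, -0.011]
    mtu_length_coeffs: [0.34663, -0.018, -0.016, 0.003667]
    origin: [0.012, 0.290]
    insertion: [0.005, 0.042]
  - name: brachialis
    sign: 1
    max_isometric_force: 987.26
    optimal_fiber_length: 0.0858
    tendon_slack_length: 0.0535
    pennation_at_optimal: 0.0
    max_contraction_velocity: 10.0
    act_time_constant: 0.010
    deact_time_constant: 0.040
    moment_arm_coeffs: [0.015, 0.020, -0.008]
    mtu_length_coeffs: [0.155958, -0.015, -0.01, 0.002667]
    origin: [0.008, 0.120]
    insertion: [0.004, 0.030]
  - name: triceps_long
    sign: -1
    max_isometric_force: 798.52
    optimal_fiber_length: 0.1340
    tendon_slack_length: 0.1430
    pennation_at_optimal: 0.2094
    max_contraction_velocity: 10.0
    act_time_constant: 0.010
    deact_time_constant: 0.040
    moment_arm_coeffs: [-0.023, -0.004, 0.002]
    mtu_length_coeffs: [0.255098, 0.023, 0.002, -0.000667]
    origin: [-0.012, 0.300]
    insertion: [-0.010, -0.020]
  - name: triceps_medial
    sign: -1
    max_isometric_force: 624.3
    optimal_fiber_length: 0.1138
    tendon_slack_length: 0.0908
    pennation_at_optimal: 0.1571
    max_contraction_velocity: 10.0
    act_time_constant: 0.010
    deact_time_constant: 0.040
    moment_arm_coeffs: [-0.021, -0.004, 0.002]
    mtu_length_coeffs: [0.185794, 0.021, 0.002, -0.000667]
    origin: [-0.010, 0.140]
    insertion: [-0.010, -0.020]
  - name: triceps_lateral
    sign: -1
    max_isometric_force: 624.3
    optimal_fiber_length: 0.1138
    tendon_slack_length: 0.0980
    pennation_at_optimal: 0.1571
    max_contraction_velocity: 10.0
    act_time_constant: 0.010
    deact_time_constant: 0.040
    moment_arm_coeffs: [-0.022, -0.004, 0.002]
    mtu_length_coeffs: [0.192209, 0.022, 0.002, -0.000667]
    origin: [-0.010, 0.160]
    insertion: [-0.010, -0.020]
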