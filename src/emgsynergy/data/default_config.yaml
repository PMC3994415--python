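# Default closed-loop simulation configuration.
#
# The synergy block is the shipped sinusoid family for the two-digit
# unscrewing synergy (radians); the remaining blocks are simulator
# constants (see docs/methods.md for units and rationale).

synergy:
  omega: 3.0
  joints:
    - {joint: x_F1, amplitude_rad: 0.635, phase_rad: -0.9425, offset_rad: 0.975}
    - {joint: x_F2, amplitude_rad: 0.319, phase_rad: 1.571, offset_rad: 0.900}
    - {joint: x_T1, amplitude_rad: 0.490, phase_rad: 1.971, offset_rad: 0.350}
    - {joint: x_T2, amplitude_rad: 0.400, phase_rad: 1.856, offset_rad: 0.000}
    - {joint: x_T3, amplitude_rad: 0.000, phase_rad: 0.000, offset_rad: 1.257}
    - {joint: x_T4, amplitude_rad: 0.000, phase_rad: 0.000, offset_rad: 0.450}

controller:
  K: 0.02        # tendon-force feedback gain, rad/N
  K_I: 2.0
  K_P: 8.0
  K_D: 0.2
  C: 12.0        # voltage bound, V
  epsilon: 0.05  # boundary-layer width
  deriv_tau_s: 0.02

plant:
  inertia: 1.0           # kg*mm^2 per joint
  damping: 20.0          # 1/s
  motor_gain: 40.0       # rad/s^2 per volt
  voltage_limit: 12.0
  cylinder_radius_mm: 17.5
  engagement_band_mm: 3.0
  contact_stiffness_n_per_mm: 0.1
  tendon_moment_arm_mm: 10.0

finger:
  link_lengths_mm: [45.0, 25.0]
  base_position_mm: [0.0, 0.0]
  base_orientation_rad: 0.0
  flexion_sign: -1
  joint_names: [x_F2, x_F1]

mapping:
  gamma: 0.1
  reference_joint: x_F2
  switch_tolerance_rad: null   # null -> 2% of the joint's peak-to-peak range

task:
  target_rad: 6.0
  timeout_s: 60.0
  backward_tolerance_rad: 0.02

cylinder:
  bite_mm: 2.5            # max nominal path/surface interference (grip depth)
  anchor_phase_rad: 1.5707963267948966

baselines:
  open_loop: {C_IL: 10.0}
  mc: {C_MC: 10.0, weights: [-1.0, 0.0, 0.05, 0.02], epsilon_MC: 0.2}
  arm_rate_rad_s: 1.0
  wrist_excursion_rad: 1.0
  grip_threshold: 1.0
  closure_max: 1.2
  grip_stiffness_n: 20.0
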