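# Default four-arm coronary plaque study.
#
# Geometry is in millimetres; the solver works in SI internally.

vessel:
  lms_diameter: 4.5        # left main stem diameter, mm
  lad_diameter: 3.5        # left anterior descending, mm
  lcx_diameter: 3.0        # left circumflex, mm
  lms_length: 10.0
  lad_length: 25.0
  lcx_length: 25.0
  bifurcation_angle: 80.0  # degrees between LAD and LCx
  fillet_radius: 1.0       # junction smoothing radius, mm

plaques:
  # raised-cosine intrusions; stenosis_fraction is the fractional diameter
  # reduction (0.6 -> 60% diameter stenosis)
  - {branch: LMS, center_s: 5.0, length: 4.0, stenosis_fraction: 0.6, eccentric: false}
  - {branch: LAD, center_s: 6.0, length: 4.0, stenosis_fraction: 0.6, eccentric: false}

mesh:
  h: 0.25                  # target element size, mm (h/2 around plaques)
  seed: 0                  # jitter seed; fixed for reproducible meshes

waveform:
  source: default          # or a CSV path with (t_seconds, velocity_m_per_s)
  harmonics: 8
  amplitude_scale: 1.0

solver:
  dt: 0.0125               # s per timestep
  steps_per_cycle: 80      # 80 x 0.0125 s = 1.0 s cardiac cycle
  cycles: 2                # first cycle discarded as start-up transient
  residual_target: 1.0e-4
  max_inner_iterations: 100
  rho: 1060.0              # blood density, kg/m^3

rheology:
  newtonian_viscosity: 0.0035   # Pa.s

# which of the four study arms to run
arms: [newtonian_plaque, newtonian_noplaque, gpl_plaque, gpl_noplaque]

sections:
  lcx_group_center: 3.5    # mm: center of the K-O group on the proximal LCx
  samples: 51
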