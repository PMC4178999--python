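# Default synthetic middle-ear + transducer configuration.
# Electromechanical couplings and the noise floor are produced by the
# scripted calibration procedure (python -m earloop.calibrate).
middle_ear:
  eardrum_area: 6.0e-5
  eardrum_mass: 1.0e-5
  eardrum_stiffness: 3560.0
  eardrum_damping: 0.15
  malleus_coupling_stiffness: 1890.0
  malleus_coupling_damping: 0.08
  malleus_incus_mass: 5.5e-5
  ligament_stiffness: 70.0
  ligament_damping: 0.05
  isj_stiffness: 12000.0
  isj_damping: 0.1
  stapes_mass: 3.5e-6
  annular_stiffness: 2160.0
  annular_damping: 0.15
  cochlea_mass: 1.0e-5
  cochlea_stiffness: 650.0
  cochlea_damping: 0.8
  loss_factor: 0.0
  contact_diameter_mm: 1.0
  state: intact
transducer:
  frame_mass: 3.5e-5
  sensor_coupling: 8.1534706052e+01
  actuator_coupling: 4.2292024467e-04
  sensor_plate_stiffness: 5.0e4
  sensor_plate_damping: 0.3
  actuator_plate_stiffness: 5.0e4
  actuator_plate_damping: 0.3
  max_drive_voltage: 1.0
  length_mm: 4.0
  width_mm: 2.5
  thickness_mm: 1.0
signal_chain:
  preamp_gain: 1000.0
  adc_bits: 16
  adc_range: 10.0
  antialias_order: 4
  antialias_cutoff: 4000.0
  sample_rate: 10000.0
noise:
  rms_volts: 2.7287164880e-07
  shape: white
control:
  forward:
    gain_db: 0.0
    lowpass_order: 4
    lowpass_cutoff: 4000.0
    delay_samples: 1
  lms_taps: 100
  lms_step: 0.05
  lms_eps: 1.0e-8
  lms_leakage: 0.0
  normalized: true
  msg_ceiling_db: 60.0
  seed: 20140807
experiment:
  multisine_points: 2048
  stimulus_f_min: 100.0
  stimulus_f_max: 2500.0
  stimulus_spl: 50.0
  calibrated_band: [250.0, 2500.0]
  grid_points: 128
  grid_f_min: 100.0
  grid_f_max: 5000.0
  sweep_step_db: 0.5
  sweep_start_db: -20.0
  mic_gain_pa_per_mm_s: 50.0
  mic_corner_hz: 150.0
fitting:
  berger_coefficients: {}
  default_coefficient: 0.5
seed: 20140807
output_dir: results
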