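# kV CBCT acquisition protocols for the linac-mounted on-board imager.
# total mAs per acquisition = tube_current_ma * acquisition_time_s
#                             * frame_rate_fps * pulse_duration_s
# (thorax 360 mAs, pelvis 1440 mAs, fourd 672 mAs).
thorax:
  n_acquisitions: 1
  tube_current_ma: 20.0
  acquisition_time_s: 60.0
  frame_rate_fps: 15.0
  pulse_duration_s: 0.020
  tube_voltage_kv: 125.0
  gantry_start_deg: -180.0
  gantry_stop_deg: 180.0
  gantry_step_deg: 2.0
pelvis:
  n_acquisitions: 1
  tube_current_ma: 80.0
  acquisition_time_s: 60.0
  frame_rate_fps: 15.0
  pulse_duration_s: 0.020
  tube_voltage_kv: 125.0
  gantry_start_deg: -180.0
  gantry_stop_deg: 180.0
  gantry_step_deg: 2.0
fourd:
  n_acquisitions: 1
  tube_current_ma: 40.0
  acquisition_time_s: 120.0
  frame_rate_fps: 7.0
  pulse_duration_s: 0.020
  tube_voltage_kv: 125.0
  gantry_start_deg: -180.0
  gantry_stop_deg: 180.0
  gantry_step_deg: 2.0
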