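# Default parameter set of the myocardial-bridge / mural-coronary rig emulation:
# silicone-tube geometry, fitted compliance coefficients, the physiological
# operating point (120/80 mmHg, 60 bpm, 205 ml/min, viscosity 3.8e-3 Pa.s) and
# the standard sweep grids.

[geometry]
R0_mm = 2.465
Ri_mm = 2.165
lambda_z = 1.2

[fit]
a = 4.91
b = 3.17e-3
c = 1.18e-5
d = 4.81e-7
e = 2.39e-9
pressure_unit = "mmHg"
validity_range = [-20.0, 160.0]

[cardiac]
systolic = 120.0
diastolic = 80.0
heart_rate = 60.0
mean_flow_ml_min = 205.0
viscosity_pa_s = 3.8e-3
systole_fraction = 0.35

[schedule]
level = 1.0
onset_phase = 0.0
duration_phase = 0.35
overshoot_gain = 35.0
overshoot_damping = 12.0
overshoot_freq = 8.0

[sweep]
compression_levels = [0.0, 0.5, 0.8, 1.0]
q2_grid_mmHg = [0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0]
q2_setpoint_mmHg = 0.0
sweep_level = 0.0

[run]
duration_s = 5.0
sample_rate_hz = 1000.0
noise_sd_mmHg = 0.0
seed = 0
out_dir = "results"
log_level = "INFO"
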