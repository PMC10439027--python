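# Eccentricity experiment: circular dynamic pink-noise field, cued vs uncued
# orientation discrimination at four retinal eccentricities.
#
# Geometry is in degrees of visual angle. ppd is the nominal pixels-per-degree
# of a 1024x768 display viewed so the 14.32 deg field radius spans half the
# screen height (384 px / 14.32 deg ~= 26.8 px/deg); set it to the calibrated
# value of your display.
schema_version: 1
ppd: 26.8
refresh_rate_hz: 120.0       # display refresh; each noise frame is shown twice
update_rate_hz: 60.0         # noise update rate
n_steps: 4                   # hybrid steps per keyframe transition
field_shape: circular
field_radius_deg: 14.32
field_ramp_deg: 2.39         # soft field boundary (cosine ramp, inside the radius)
mean_luminance: 0.5
contrast: 0.2
window_r_deg: 1.75           # signal plateau radius
window_w_deg: 0.875          # signal cosine ramp width
fixation_range_ms: [400.0, 800.0]
cue_frames: 4                # 66.7 ms; the nearest frame count to a 75 ms cue
cue_delay_ms: 100.0
signal_ms: 50.0              # 3 frames at 60 Hz
mask_range_ms: [500.0, 500.0]
sigmas: [30.0, 35.0, 40.0, 45.0, 50.0, 55.0, 60.0, 65.0, 70.0]
tilts: [40.0, -40.0]
conditions: [cued, uncued]
eccentricities: [0.0, 3.5, 7.0, 10.5]
trials_per_cell: 1           # 144 cells; repeat blocks to taste
master_seed: 20220801
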