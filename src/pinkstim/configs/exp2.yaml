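# Items experiment: rectangular dynamic pink-noise strip with five
# task-irrelevant ring outlines; the orientation signal appears at one of nine
# horizontal positions, inside or between the rings.
#
# The per-observer filter width for the main task is picked from the sigmas
# ladder via the preceding cued threshold task (90% accuracy criterion); the
# ladder below is that threshold-task ladder (narrower than the eccentricity
# experiment because the signal is smaller and briefer).
schema_version: 1
ppd: 26.8
refresh_rate_hz: 120.0
update_rate_hz: 120.0        # signal duration of 5 frames = 41.7 ms needs the full rate
n_steps: 8                   # keeps the background transition pace of 4 steps at 60 Hz
field_shape: rectangular
field_height_deg: 2.5
field_width_deg: 20.0
mean_luminance: 0.5
contrast: 0.2
window_r_deg: 1.0
window_w_deg: 0.875          # the vertical ramp is clipped by the 2.5 deg field height
fixation_range_ms: [300.0, 1000.0]
cue_frames: 0                # no cue in the main task
cue_delay_ms: 0.0
signal_frames: 5             # ~42 ms at 120 Hz
mask_range_ms: [300.0, 650.0]
sigmas: [10.0, 20.0, 30.0, 40.0, 50.0]
tilts: [40.0, -40.0]
conditions: [uncued]
positions: [-8.0, -6.0, -4.0, -2.0, 0.0, 2.0, 4.0, 6.0, 8.0]
trials_per_cell: 4           # 360 trials, the scale of one observer's session
master_seed: 20220802
frames_overlay:
  positions: [-8.0, -4.0, 0.0, 4.0, 8.0]
  radius_deg: 1.0
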