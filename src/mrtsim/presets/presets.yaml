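# Bundled beamline presets: wiggler field x beam-defining aperture x mesh.
# Loaded by mrtsim.config.RunConfig.from_preset.
machine:
  ring_current: 200.1   # mA
  ring_energy: 3.032    # GeV
wiggler:
  period: 52.0          # mm
  n_periods: 30
  magnetic_length: 1.56 # m
  min_photon_energy: 40.0  # keV
defaults:
  mask_width: 20.0      # mm
  scan_speed: 10.0      # mm/s
  field_height: 20.0    # mm
  field_width: 20.0     # mm
  k_w: 1.0
  n_primaries: 100000
  n_jobs: 1
  seed: 1
presets:
  3T_bda0.532_bb: {field: 3.0, bda_height: 0.532, mesh: bb, msc: false}
  3T_bda1.053_bb: {field: 3.0, bda_height: 1.053, mesh: bb, msc: false}
  3T_bda2.014_bb: {field: 3.0, bda_height: 2.014, mesh: bb, msc: false}
  3T_bda0.532_mb: {field: 3.0, bda_height: 0.532, mesh: mb, msc: true}
  3T_bda1.053_mb: {field: 3.0, bda_height: 1.053, mesh: mb, msc: true}
  3T_bda2.014_mb: {field: 3.0, bda_height: 2.014, mesh: mb, msc: true}
  2T_bda0.532_bb: {field: 2.0, bda_height: 0.532, mesh: bb, msc: false}
  2T_bda1.053_bb: {field: 2.0, bda_height: 1.053, mesh: bb, msc: false}
  2T_bda2.014_bb: {field: 2.0, bda_height: 2.014, mesh: bb, msc: false}
  2T_bda0.532_mb: {field: 2.0, bda_height: 0.532, mesh: mb, msc: true}
  2T_bda1.053_mb: {field: 2.0, bda_height: 1.053, mesh: mb, msc: true}
  2T_bda2.014_mb: {field: 2.0, bda_height: 2.014, mesh: mb, msc: true}
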