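# Example input configuration for polarsim.config.input_process_from_config.
#
# The yeast ligand-noise estimate for these discretization defaults is
# sigma ~ 1.3 to 4.1 nM (external diffusive noise per receptor-sized
# surface patch); sigma is tied to the k_x = 200, dt = 0.01 s defaults
# and is NOT rescaled if the discretization changes.
grid:
  kind: circle          # or axisymmetric_sphere
  n: 200                # spatial nodes (k_x)
  radius_um: 2.0
gradient:
  L_mid: 10.0           # concentration at the cell midpoint (nM)
  L_slp: 0.01           # slope, nM per um
  direction_deg: 0.0
  switches: []          # e.g. [[300.0, 180.0]] for a reversal at t=300 s
noise:
  sigma: 3.0
  distribution: normal  # lognormal recommended when sigma ~ L_mid
  dt: 0.01              # noise refresh step k_t (s)
  seed: 0
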