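# Default three-pool Bloch-McConnell parameterization at 9.4 T.
#
# Plausible defaults, not measured values: the relaxation times and pool
# sizes are representative literature-scale numbers for mouse brain at
# 9.4 T. The hydroxyl pool sits at +0.6 ppm and exchanges at 600 1/s
# (slow-to-intermediate regime of myoinositol -OH protons); its fraction is
# calibrated so that the simulated MTR asymmetry at 0.6 ppm under the
# standard saturation schedule (1.6 s, 0.9 uT, steady-state mode) is 8.2%,
# the scale of the in vivo contralateral-control contrast. A broad
# macromolecular pool at -2.4 ppm provides a small negative-offset
# background.
scanner:
  field_strength: 9.4
  gamma_bar: 42.577
pulse:
  cest: {b1: 0.9, duration: 1.6}
  wassr: {b1: 0.1, duration: 0.5}
pools:
  - {name: water, t1: 1.8, t2: 0.040, shift: 0.0, fraction: 1.0, k_exchange: 0.0}
  - {name: hydroxyl, t1: 1.0, t2: 0.010, shift: 0.6, fraction: 0.0037324, k_exchange: 600.0}
  - {name: macromolecular, t1: 1.0, t2: 0.0005, shift: -2.4, fraction: 0.001, k_exchange: 40.0}
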