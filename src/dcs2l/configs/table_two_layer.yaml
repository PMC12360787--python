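# Baseline two-layer medium (785 nm): extracerebral slab over brain.
rho: 35.0
beta: 0.5
wavelength: 785.0
n0: 1.4
extracerebral:
  mua: 0.019
  musp: 0.86
  Db: 1.05e-6
  thickness: 10.0
brain:
  mua: 0.020
  musp: 1.210
  Db: 6.0e-6
  thickness: inf
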