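# Baseline four-layer slab head model at 785 nm (scalp, skull, CSF, brain).
n_tissue: 1.4
wavelength: 785.0
z_max: 100.0
r_max: 100.0
layers:
  - {name: scalp, mua: 0.019, musp: 0.726, thickness: 3.0, Db: 1.0e-6, g: 0.89}
  - {name: skull, mua: 0.014, musp: 0.946, thickness: 7.0, Db: 8.0e-8, g: 0.89}
  - {name: csf,   mua: 0.001, musp: 0.002, thickness: 2.0, Db: 1.0e-8, g: 0.89}
  - {name: brain, mua: 0.020, musp: 1.210, thickness: inf, Db: 6.0e-6, g: 0.89}
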