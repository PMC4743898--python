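# Two-layer folds in a pressure-driven air channel (mIFEM), desk scale:
# resolves the pressure-driven closing phase of the glottal cycle.
case: fold
params:
  scale: 1.0
  n_steps: 120
  output_every: 40
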