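# Red blood cell in an asymmetric bifurcation (w1/w2 = 1.44) with equal
# outlet flow rates: the cell selects the narrower branch.
case: bifurcation
params:
  r_d: 1.44
  flow_ratio: 1.0
  n_steps: 200
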