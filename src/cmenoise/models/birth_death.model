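# Constitutive expression: birth-death process with Poisson steady state.
species: [n]
parameters:
  k_s: 20.0
  k_d: 1.0
bounds: {n: 60}
reactions:
  - name: synthesis
    propensity: k_s
    change: {n: 1}
  - name: degradation
    propensity: k_d * n
    change: {n: -1}
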