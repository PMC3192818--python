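# Genetic toggle switch: mutual Hill repression, linear degradation.
species: [u, v]
parameters:
  K_u: 1.0
  K_v: 1.0
  r_u: 10.0
  r_v: 10.0
  beta: 2.0
  gamma: 2.0
  d_u: 1.0
  d_v: 1.0
bounds: {u: 60, v: 60}
reactions:
  - name: synth_u
    propensity: r_u / (1 + (v / K_v)**beta)
    change: {u: 1}
  - name: deg_u
    propensity: d_u * u
    change: {u: -1}
  - name: synth_v
    propensity: r_v / (1 + (u / K_u)**gamma)
    change: {v: 1}
  - name: deg_v
    propensity: d_v * v
    change: {v: -1}
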