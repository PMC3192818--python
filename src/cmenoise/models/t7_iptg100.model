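# T7 RNAP growth-modulating positive-feedback circuit (pseudo-steady state).
species: [t7, o0]
parameters:
  M: 10
  k_0: 0.0008
  k_1: 0.0065
  k_f: 0.01
  k_b: 0.11
  d_x0: 0.003
  mu: 0.007
  theta: 1.0
bounds: {t7: 60, o0: 10}
reactions:
  - name: synth_basal
    propensity: k_0 * o0
    change: {t7: 1}
  - name: synth_active
    propensity: k_1 * (M - o0)
    change: {t7: 1}
  - name: activation
    propensity: k_f * o0 * t7
    change: {t7: -1, o0: -1}
  - name: deactivation
    propensity: k_b * (M - o0)
    change: {t7: 1, o0: 1}
  - name: degradation
    propensity: d_x0 * t7
    change: {t7: -1}
  - name: division
    propensity: mu / (1 + t7 / theta)
    kernel:
      name: binomial_division
      molecules: t7
      inactive_promoters: o0
      promoters: 10
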