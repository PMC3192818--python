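"""T7 RNAP positive feedback with growth retardation: ON-cell fractions.

T7 RNA polymerase activates its own promoters; its expression slows cell
division, and division dilutes it (binomial partitioning, promoters
reset).  The pseudo-steady state during log-phase growth is bimodal, and
the valley rule splits the T7 marginal into OFF (low) and ON (high)
populations.  Raising the effective growth rate mu shifts cells to OFF.
"""

import cmenoise as cn

for name, label in [
    ("t7_base", "base (mu=0.007)"),
    ("t7_mu013", "faster growth (mu=0.013)"),
    ("t7_iptg100", "lower induction (k_0, k_1 -26%)"),
]:
    network, space = cn.load_builtin_model(name)
    dist = cn.solve_steady_state(cn.build_generator(network, space), space)
    marginal = cn.DistributionGrid(cn.StateSpace([space.upper[0]]), dist.marginal(0))
    frac, border = cn.on_fraction_valley(marginal)
    print(f"{label:34s} ON = {100 * frac:5.1f}%  (ON/OFF border at n = {border})")
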