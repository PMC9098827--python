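"""Sample a stability ensemble and correlate parameters with stability.

For the one-variable gain/loss system the steady state is stable exactly
when the loss elasticity exceeds the gain elasticity, so with both drawn
from U(0, 2) half of all sampled steady states are stable, the gain
elasticity is destabilizing (negative correlation) and the loss
elasticity stabilizing (positive correlation).
"""

from genmod import (
    ParameterRanges,
    build_jacobian,
    fixture,
    proportion_stable_sweep,
    sample_ensemble,
    stability_correlation,
)

jac = build_jacobian(fixture("one_d_gain_loss"), timescale_reference="X")
ranges = ParameterRanges({"g_x": (0, 2), "l_x": (0, 2)})

ens = sample_ensemble(jac, ranges, m=50_000, seed=1)
print(f"proportion of stable steady states: {ens.psw:.3f}  (analytic: 0.500)")

corr = stability_correlation(ens)
for name, value in corr.items():
    tag = "stabilizing" if value > 0 else "destabilizing"
    print(f"  {name}: {value:+.3f}  ({tag})")

# Proportion of stable webs: clamp the loss elasticity, randomize the rest.
sweep = proportion_stable_sweep(
    jac, ParameterRanges({"g_x": (0, 2)}), {"l_x": [0.5, 1.0, 1.5, 2.0]},
    m_per_cell=10_000, seed=2,
)
print("\nPSW along the loss elasticity (analytic: l_x / 2):")
print(sweep.table.to_string(index=False))
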