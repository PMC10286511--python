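"""Uniform flux allocation maximizes the rate of entropy production.

Builds an ensemble of three phosphorylation switches plus one GTPase cycle,
divides a fixed chemical flux uniformly across them, evaluates the entropy
production rate, and confirms by random constrained search that no other
allocation does better.
"""

import numpy as np

from bois import mrep

spec = mrep.SwitchEnsembleSpec(
    n_pdpc=3,
    has_gtpc=True,
    return_rates=np.array([1.0, 1.0, 2.0, 0.5]),
    mu=np.array([-2.0, -2.0, -2.0, -2.0]),  # free-energy drop per cycle
)
J = 1.0

alloc = mrep.allocate_flux(J, spec.n_switches)
print(f"total flux J = {J}, {spec.n_switches} switches -> J0 = {alloc.per_switch[0]:.3f} each")

p_on = [mrep.on_probability(alloc.per_switch[i], spec.return_rates[i])
        for i in range(spec.n_switches)]
print("ON probabilities (J0 / k-):", [f"{p:.3f}" for p in p_on])
print("  -> the rigid return rates (phosphatase / GTP hydrolysis) set the switch states")

ts = mrep.entropy_production_rate(spec, alloc)
print(f"entropy production T*sigma = {ts:.3f} energy/time")

report = mrep.verify_uniform_flux_optimality(spec, J, n_trials=1000, rng=0)
print(f"best of {report['n_trials']} random constrained allocations: "
      f"{report['best_perturbed_entropy_production']:.6f} "
      f"(advantage over uniform: {report['max_advantage']:.2e})")
print("  -> the uniform allocation is never beaten")

pools = mrep.ReceptorPools(total=2.5, unattached=0.5, n_switch_sites=2)
print(f"\nreceptor bookkeeping: R_T={pools.total}, unattached={pools.unattached}, "
      f"{pools.n_switch_sites} sites -> R_ref = {mrep.reference_concentration(pools):.2f}")
print("  every ON switch saturates at exactly 1 R_ref unit")
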