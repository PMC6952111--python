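"""Small simulation study: recall and reduction rate of the meta approach.

Simulates 50 block-LD loci with one causal variant at 50%-power effect size,
fine-maps each with and without AIM information, and reports the recall
(fraction of loci whose causal variant is inside the 95%-causal set) and the
median reduction rate r = (N_eQTL - N_Meta) / N_eQTL.
"""

from aimfine import CausalPrior, SimScenario
from aimfine.experiments import run_scenario

scenario = SimScenario(
    n_causal=1, ncp_eqtl=5.2, ncp_aim=5.2, n_variants=50, rho=0.95, seed=21, n_loci=50
)
result = run_scenario(scenario, CausalPrior(k_max=3))

print(f"loci simulated:        {result.n_loci}")
print(f"recall (meta sets):    {result.recall_meta:.3f}")
print(f"recall (eQTL sets):    {result.recall_eqtl:.3f}")
print(f"median reduction rate: {result.median_reduction:.3f}")
sizes = [(r.n_eqtl, r.n_meta) for r in result.loci[:10]]
print(f"first 10 set-size pairs (eQTL, meta): {sizes}")
# Recall near 0.95 (here usually higher, since the greedy set overshoots rho)
# shows the 95% coverage contract holds; a positive median reduction shows
# the AIM statistic is pruning linked non-causal variants, not the signal.
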