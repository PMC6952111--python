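"""Simulate one eQTL locus and fine-map it with and without allelic imbalance.

Builds a 50-variant block-LD locus with one causal variant, draws eQTL and
AIM z-scores from their sampling distributions, and compares the 95%-causal
set from the eQTL statistics alone with the set from the meta statistics.
"""

import numpy as np

from aimfine import CausalPrior, SimScenario, SummaryStatVector, finemap, finemap_meta
from aimfine.experiments import simulate_locus
from aimfine.meta import meta_correlation, meta_statistics
from aimfine.stats import regularize

scenario = SimScenario(n_causal=1, ncp_eqtl=5.2, ncp_aim=5.2, n_variants=50, seed=7, n_loci=1)
locus = simulate_locus(scenario, 0)
print(f"implanted causal variant: {locus.causal[0]}")
print(f"z-score at causal variant: eQTL {locus.s_e[locus.causal[0]]:.2f}, AIM {locus.s_a[locus.causal[0]]:.2f}")

prior = CausalPrior(sigma=5.2, pi_causal=0.01, k_max=3)
se = SummaryStatVector(z=locus.s_e, kind="eqtl")
sa = SummaryStatVector(z=locus.s_a, kind="aim")
sm1, sm2 = meta_statistics(sa, se)

eqtl_set, _ = finemap(se, regularize(locus.sigma_e), prior, rho=0.95)
sigma_m = regularize(meta_correlation(locus.sigma_e, locus.sigma_a))
meta_set = finemap_meta(sm1, sm2, sigma_m, prior, rho=0.95)

print(f"eQTL-only causal set: {eqtl_set.size} variants (mass {eqtl_set.mass:.3f})")
print(f"meta causal set ({meta_set.kind}): {meta_set.size} variants (mass {meta_set.mass:.3f})")
r = (eqtl_set.size - meta_set.size) / eqtl_set.size
print(f"reduction rate: {r:.2f}")
print(f"causal variant captured by meta set: {locus.causal[0] in meta_set.variants}")
# Both sets are guaranteed to hold >= 95% posterior mass; adding the AIM
# statistic typically shrinks the set because its LD pattern (heterozygosity
# correlation) differs from genotype LD and breaks ties among linked variants.
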