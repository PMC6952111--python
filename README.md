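# aimfine

Fine-mapping of cis-regulatory variants in eQTL studies, refined with
allelic imbalance.

## The problem

eQTL studies find variants associated with a gene's total expression, but
linkage disequilibrium (LD) makes it hard to tell which variant in an
associated locus is actually causal. Bayesian fine-mapping methods report a
*ρ-causal set* — the smallest set of variants containing all causal variants
with posterior probability at least ρ — yet in high-LD regions these sets
can stay large.

RNA-seq offers a second, orthogonal readout of cis-regulation: **allelic
imbalance (AIM)**, unequal expression of a gene from the two chromosomes of
a diploid individual. A heterozygous carrier of a causal cis-regulatory
allele expresses the two haplotypes unequally, so the per-individual pattern
of heterozygosity at the causal variant matches the pattern of AIM across
individuals. `aimfine` combines the two signals to produce smaller causal
sets at the same coverage level.

## The model

Per gene, for the top *m* cis variants:

- **eQTL z-scores** `S_E`: marginal OLS of normalized expression on
  standardized dosage, `z_i = (β̂_i/σ̂)·√n` with `σ̂² = RSS/(n−2)`.
- **AIM status** per individual: haplotype-resolved read counts `(c1, c2)`
  at the deepest heterozygous coding SNP (≥ 20 reads) give the allelic
  ratio `AR = c1/(c1+c2)`; AIM is called when `AR < 0.35` or `AR > 0.65`
  (or, more stringently, by an exact two-sided binomial test).
- **AIM z-scores** `S_A`: pooled two-proportion test comparing the
  heterozygote fraction among AIM vs balanced individuals,
  `z = (p̂₁−p̂₂)/√(p̂(1−p̂)(n₁+n₂)/(n₁n₂))`.
- **Fixed-effect meta-analysis**: `S_M1 = (S_A+S_E)/√2` and
  `S_M2 = (S_A−S_E)/√2`, with LD matrix `Σ_M = (Σ_E+Σ_A)/2`, where `Σ_E` is
  genotype LD and `Σ_A` the correlation of heterozygosity indicators. Both
  forms are fine-mapped and the smaller causal set is kept, so the unknown
  sign relation between the two statistics never matters.
- **Fine-mapping**: conditional on a binary causal configuration `C` with
  the effect sizes integrated out under a `N(0, σ²)` prior (σ = 5.2),

      S | C ~ N(0, Σ + σ²·Σ diag(C) Σ).

  The posterior over all configurations with ≤ `k_max` causal variants is
  enumerated exactly (independent Bernoulli(π = 0.01) prior, at least one
  causal variant assumed), and the minimal ρ-causal set is grown greedily
  until its configurations cover ≥ ρ of the posterior mass.

Evaluation uses the *recall* (fraction of simulated loci whose implanted
causal variants all land in the set) and the *reduction rate*
`r = (N_eQTL − N_Meta)/N_eQTL`.

## Worked example

`python examples/01_simulate_and_finemap.py` simulates one 50-variant
block-LD locus with a single causal variant at 50%-power effect size
(non-centrality 5.2) and fine-maps it both ways:

```
implanted causal variant: 34
z-score at causal variant: eQTL 5.73, AIM 6.53
eQTL-only causal set: 36 variants (mass 0.951)
meta causal set (meta1): 33 variants (mass 0.953)
reduction rate: 0.08
causal variant captured by meta set: True
```

Both sets carry ≥ 95% posterior mass, i.e. both honor the coverage
contract; adding AIM removes linked non-causal variants (here 3 of 36,
an 8% reduction) while keeping the causal variant. The other examples
cover AIM calling (`02`), the meta statistic (`03`), a small simulation
study (`04`) and the end-to-end file pipeline (`05`). A thin CLI mirrors
the stages: `aimfine simulate | aim-call | stats | meta | finemap |
evaluate | run`.

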