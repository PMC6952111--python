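"""End-to-end simulation experiments on summary statistics.

Each locus follows the evaluation design used to characterize the method:
a haplotype panel with block LD yields the genotype LD matrix Sigma_E and
the heterozygosity correlation Sigma_A; causal variants are implanted and
eQTL / AIM z-scores are drawn from their multivariate normal sampling
distributions with non-centralities lambda_E and lambda_A; the meta
statistics are formed and both the eQTL-only and the meta fine-mapping are
run, recording causal-set sizes and whether the implanted variants were
captured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CausalConfig, CausalPrior, CorrelationMatrix, DegenerateStatisticError
from .evaluate import EvalResult, LocusResult
from .finemap import finemap, finemap_meta
from .meta import meta_correlation, meta_statistics
from .simulate import (
    SimScenario,
    default_block_structure,
    locus_rng,
    simulate_haplotypes,
    simulate_stats,
)
from .stats import genotype_correlation, heterozygosity_correlation, regularize

__all__ = ["SimulatedLocus", "simulate_locus", "run_locus", "run_scenario", "run_effect_sweep"]


@dataclass
class SimulatedLocus:
    """LD matrices, implanted causal variants and drawn statistics for one locus."""

    sigma_e: CorrelationMatrix
    sigma_a: CorrelationMatrix
    causal: tuple[int, ...]
    s_e: np.ndarray
    s_a: np.ndarray


def _locus_ld(scenario: SimScenario, rng: np.random.Generator):
    """Draw a haplotype panel and return its (Sigma_E, Sigma_A); retry on the
    rare monomorphic / all-het column draw."""
    blocks = default_block_structure(scenario.n_variants, scenario.block_size, scenario.block_r)
    for _ in range(20):
        panel = simulate_haplotypes(
            scenario.n_variants,
            scenario.n_samples,
            block_structure=blocks,
            maf_range=scenario.maf_range,
            seed=rng,
        )
        try:
            sigma_e = genotype_correlation(panel.genotypes)
            sigma_a = heterozygosity_correlation(panel.het)
        except DegenerateStatisticError:
            continue
        return sigma_e, sigma_a
    raise DegenerateStatisticError(
        "could not draw a panel without constant columns; widen maf_range or raise n"
    )


def simulate_locus(scenario: SimScenario, locus: int) -> SimulatedLocus:
    """Simulate LD matrices and summary statistics for one locus of a scenario."""
    rng = locus_rng(scenario.seed, locus)
    sigma_e, sigma_a = _locus_ld(scenario, rng)
    m = scenario.n_variants
    causal = tuple(sorted(rng.choice(m, size=scenario.n_causal, replace=False).tolist()))
    config = CausalConfig(causal, m)
    s_e = simulate_stats(sigma_e, config, scenario.ncp_eqtl, seed=rng, size=1)[0]
    s_a = simulate_stats(sigma_a, config, scenario.ncp_aim, seed=rng, size=1)[0]
    return SimulatedLocus(sigma_e=sigma_e, sigma_a=sigma_a, causal=causal, s_e=s_e, s_a=s_a)


def run_locus(
    locus: SimulatedLocus,
    prior: CausalPrior,
    rho: float = 0.95,
    ridge: float = 1e-3,
) -> LocusResult:
    """Fine-map one simulated locus with and without AIM information."""
    from .core import SummaryStatVector

    se = SummaryStatVector(z=locus.s_e, kind="eqtl")
    sa = SummaryStatVector(z=locus.s_a, kind="aim")
    sm1, sm2 = meta_statistics(sa, se)
    sigma_e_r = regularize(locus.sigma_e, ridge)
    sigma_m_r = regularize(meta_correlation(locus.sigma_e, locus.sigma_a), ridge)
    eqtl_set, _ = finemap(se, sigma_e_r, prior, rho)
    meta_set = finemap_meta(sm1, sm2, sigma_m_r, prior, rho)
    causal = set(locus.causal)
    return LocusResult(
        true_causal=locus.causal,
        n_eqtl=eqtl_set.size,
        n_meta=meta_set.size,
        captured_meta=causal.issubset(meta_set.variants),
        captured_eqtl=causal.issubset(eqtl_set.variants),
    )


def run_scenario(scenario: SimScenario, prior: CausalPrior | None = None, ridge: float = 1e-3) -> EvalResult:
    """Run a full scenario: n_loci independent loci, each fine-mapped with the
    eQTL-only and the meta approach."""
    prior = prior or CausalPrior(k_max=3)
    result = EvalResult()
    for locus_idx in range(scenario.n_loci):
        locus = simulate_locus(scenario, locus_idx)
        result.loci.append(run_locus(locus, prior, scenario.rho, ridge))
    return result


def run_effect_sweep(
    scenario: SimScenario,
    ncp_aim_values: tuple[float, ...] = (2.0, 3.0, 4.0, 5.2),
    prior: CausalPrior | None = None,
    ridge: float = 1e-3,
) -> dict[float, EvalResult]:
    """Sweep the AIM effect size with the eQTL side held fixed.

    Loci (LD, causal variants and the eQTL statistic draw) are shared across
    sweep points; only the AIM statistic is redrawn per lambda_A, so the
    comparison is paired and the eQTL-only causal set is computed once.
    """
    from .core import SummaryStatVector

    prior = prior or CausalPrior(k_max=3)
    results: dict[float, EvalResult] = {lam: EvalResult() for lam in ncp_aim_values}
    for locus_idx in range(scenario.n_loci):
        locus = simulate_locus(scenario, locus_idx)
        config = CausalConfig(locus.causal, scenario.n_variants)
        sigma_e_r = regularize(locus.sigma_e, ridge)
        sigma_m_r = regularize(meta_correlation(locus.sigma_e, locus.sigma_a), ridge)
        se = SummaryStatVector(z=locus.s_e, kind="eqtl")
        eqtl_set, _ = finemap(se, sigma_e_r, prior, scenario.rho)
        rng = locus_rng(scenario.seed, scenario.n_loci + locus_idx)  # AIM redraw stream
        for lam in ncp_aim_values:
            s_a = simulate_stats(locus.sigma_a, config, lam, seed=rng, size=1)[0]
            sa = SummaryStatVector(z=s_a, kind="aim")
            sm1, sm2 = meta_statistics(sa, se)
            meta_set = finemap_meta(sm1, sm2, sigma_m_r, prior, scenario.rho)
            causal = set(locus.causal)
            results[lam].loci.append(
                LocusResult(
                    true_causal=locus.causal,
                    n_eqtl=eqtl_set.size,
                    n_meta=meta_set.size,
                    captured_meta=causal.issubset(meta_set.variants),
                    captured_eqtl=causal.issubset(eqtl_set.variants),
                )
            )
    return results
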