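"""Fixed-effect meta-analysis of eQTL and AIM z-scores.

Total-expression and allelic-imbalance statistics measure cis-regulation on
orthogonal data, so they can be combined like two equally-sized studies:

    S_M1 = (S_A + S_E) / sqrt(2),    S_M2 = (S_A - S_E) / sqrt(2).

Because the dependent variables of the two "studies" differ, the sign
relationship between the statistics is unknown a priori; running downstream
fine-mapping on both forms and keeping the smaller causal set covers both
orientations. The meta statistics are unit-variance under the null, and
their LD matrix is the average Sigma_M = (Sigma_E + Sigma_A) / 2.
"""

from __future__ import annotations

import numpy as np

from .core import CausalConfig, CorrelationMatrix, InputError, SummaryStatVector

__all__ = ["meta_statistics", "meta_correlation", "meta_config_covariance"]

SQRT2 = np.sqrt(2.0)


def meta_statistics(
    sa: SummaryStatVector,
    se: SummaryStatVector,
    weights: tuple[float, float] | None = None,
) -> tuple[SummaryStatVector, SummaryStatVector]:
    """Combine AIM and eQTL z-scores into the two meta forms (M1, M2).

    With the default equal weighting this is ``(S_A ± S_E)/sqrt(2)``; an
    optional ``weights=(w_a, w_e)`` computes the inverse-variance style
    combination ``(w_a S_A ± w_e S_E)/sqrt(w_a² + w_e²)``.
    """
    if len(sa) != len(se):
        raise InputError(f"length mismatch: {len(sa)} AIM vs {len(se)} eQTL statistics")
    if sa.kind != "aim" or se.kind != "eqtl":
        raise InputError(f"expected kinds (aim, eqtl), got ({sa.kind}, {se.kind})")
    if sa.variant_ids != se.variant_ids:
        raise InputError("variant ids of the two statistics do not match")
    if weights is None:
        wa = we = 1.0
    else:
        wa, we = weights
        if wa <= 0 or we <= 0:
            raise InputError("weights must be positive")
    norm = np.sqrt(wa * wa + we * we)
    m1 = (wa * sa.z + we * se.z) / norm
    m2 = (wa * sa.z - we * se.z) / norm
    ids = list(sa.variant_ids)
    return (
        SummaryStatVector(z=m1, kind="meta1", variant_ids=ids),
        SummaryStatVector(z=m2, kind="meta2", variant_ids=ids),
    )


def meta_correlation(sigma_e: CorrelationMatrix, sigma_a: CorrelationMatrix) -> CorrelationMatrix:
    """Meta LD matrix Sigma_M = (Sigma_E + Sigma_A) / 2 (PSD, unit diagonal)."""
    if sigma_e.m != sigma_a.m:
        raise InputError(f"shape mismatch: {sigma_e.m} vs {sigma_a.m}")
    vals = 0.5 * (sigma_e.values + sigma_a.values)
    return CorrelationMatrix(values=vals, kind="meta", variant_ids=sigma_e.variant_ids)


def meta_config_covariance(
    sigma_e: CorrelationMatrix,
    sigma_a: CorrelationMatrix,
    config: CausalConfig,
    sigma_e_prior: float = 5.2,
    sigma_a_prior: float = 5.2,
) -> np.ndarray:
    """Exact covariance of the meta statistic given a causal configuration.

    Summing the two independent Gaussian statistics gives

        Cov(S_M | C) = (Sigma_E + Sigma_A)/2
                     + (sigma_a² Sigma_A Sigma_c Sigma_A
                        + sigma_e² Sigma_E Sigma_c Sigma_E)/2,

    with Sigma_c = diag(C). This is the covariance the Sigma_M-based
    fine-mapping model approximates.
    """
    if sigma_e.m != sigma_a.m:
        raise InputError("shape mismatch between LD matrices")
    if sigma_a_prior <= 0 or sigma_e_prior <= 0:
        raise InputError("prior effect SDs must be positive")
    c = config.c
    E, A = sigma_e.values, sigma_a.values
    Ec = E * c[np.newaxis, :]  # E @ diag(c)
    Ac = A * c[np.newaxis, :]
    return 0.5 * (E + A) + 0.5 * (
        sigma_a_prior**2 * Ac @ A + sigma_e_prior**2 * Ec @ E
    )
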