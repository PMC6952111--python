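"""Bayesian multivariate-normal fine-mapping over causal configurations.

Model. Let S be the m observed z-scores at a locus and Sigma their LD
matrix. Conditional on a binary causal-status vector C, with the true
effects integrated out under a N(0, sigma^2) prior per causal variant,

    S | C  ~  N(0, Sigma + sigma^2 * Sigma diag(C) Sigma).

The posterior over configurations with at most k_max causal variants is
enumerated exactly (independent-Bernoulli prior on C), and the minimal
rho-causal set — the smallest variant set whose configurations jointly
carry posterior mass >= rho — is grown greedily, adding at each step the
variant that raises the covered mass the most.

Numerics. Writing E for the columns of the identity at the causal indices,
Sigma diag(C) Sigma = U U^T with U = Sigma E, and the Woodbury identity
gives, per configuration, only a k x k solve against
M = I_k + sigma^2 Sigma[idx, idx]:

    log|Cov|      = log|Sigma| + log|M|
    S^T Cov^-1 S  = S^T Sigma^-1 S - sigma^2 * t^T M^-1 t,   t = S[idx]

(using Sigma^-1 U = E, so U^T Sigma^-1 S reduces to S at the causal indices).

All configurations of one size are processed with batched linear algebra,
so full enumeration at m = 50, k_max = 3 (~2e4 configurations) takes
milliseconds. A dense-Cholesky evaluation is kept as an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import linalg, special

from .core import (
    BudgetExceededError,
    CausalConfig,
    CausalPrior,
    CausalSet,
    CorrelationMatrix,
    InputError,
    SummaryStatVector,
)

__all__ = [
    "PosteriorTable",
    "config_log_likelihood",
    "dense_config_log_likelihood",
    "joint_log_likelihood",
    "enumerate_posteriors",
    "pip",
    "rho_causal_set",
    "finemap",
    "finemap_meta",
]

LOG2PI = np.log(2.0 * np.pi)


def _as_matrix(sigma: CorrelationMatrix | np.ndarray) -> np.ndarray:
    vals = sigma.values if isinstance(sigma, CorrelationMatrix) else np.asarray(sigma, dtype=float)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise InputError("covariance/correlation matrix must be square")
    return vals


def _base_quantities(s: np.ndarray, sigma: np.ndarray):
    """Cholesky of Sigma, Sigma^-1 s, and the null-configuration log-likelihood."""
    m = s.size
    try:
        cho = linalg.cho_factor(sigma, lower=True)
    except linalg.LinAlgError as err:
        raise InputError(
            "LD matrix is not positive definite; regularize() it first"
        ) from err
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    alpha = linalg.cho_solve(cho, s)
    base_ll = -0.5 * (m * LOG2PI + logdet + s @ alpha)
    return alpha, base_ll


def config_log_likelihood(
    s: SummaryStatVector | np.ndarray,
    sigma_mat: CorrelationMatrix | np.ndarray,
    config: CausalConfig,
    prior: CausalPrior | None = None,
) -> float:
    """log N(s; 0, Sigma + sigma^2 Sigma diag(C) Sigma) via the low-rank update."""
    prior = prior or CausalPrior()
    sv = s.z if isinstance(s, SummaryStatVector) else np.asarray(s, dtype=float).ravel()
    sigma = _as_matrix(sigma_mat)
    alpha, base_ll = _base_quantities(sv, sigma)
    idx = list(config.indices)
    if not idx:
        return float(base_ll)
    s2 = prior.sigma**2
    M = np.eye(len(idx)) + s2 * sigma[np.ix_(idx, idx)]
    t = sv[idx]  # U^T Sigma^-1 s with U = Sigma E collapses to s[idx]
    sign, logdetM = np.linalg.slogdet(M)
    if sign <= 0:
        raise InputError("config covariance not positive definite")
    x = np.linalg.solve(M, t)
    return float(base_ll - 0.5 * logdetM + 0.5 * s2 * (t @ x))


def dense_config_log_likelihood(
    s: SummaryStatVector | np.ndarray,
    sigma_mat: CorrelationMatrix | np.ndarray,
    config: CausalConfig,
    prior: CausalPrior | None = None,
) -> float:
    """Direct dense evaluation of the same density (reference implementation)."""
    prior = prior or CausalPrior()
    sv = s.z if isinstance(s, SummaryStatVector) else np.asarray(s, dtype=float).ravel()
    sigma = _as_matrix(sigma_mat)
    cov = sigma + prior.sigma**2 * sigma @ np.diag(config.c) @ sigma
    m = sv.size
    cho = linalg.cho_factor(cov, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    return float(-0.5 * (m * LOG2PI + logdet + sv @ linalg.cho_solve(cho, sv)))


def joint_log_likelihood(
    sa: SummaryStatVector | np.ndarray,
    se: SummaryStatVector | np.ndarray,
    sigma_a: CorrelationMatrix | np.ndarray,
    sigma_e: CorrelationMatrix | np.ndarray,
    config: CausalConfig,
    prior_a: CausalPrior | None = None,
    prior_e: CausalPrior | None = None,
) -> float:
    """Exact joint model: AIM and eQTL statistics conditionally independent
    given the causal configuration, each with its own CAVIAR-form covariance.
    The meta-statistic model is an approximation of this density."""
    prior_a = prior_a or CausalPrior()
    prior_e = prior_e or prior_a
    return config_log_likelihood(sa, sigma_a, config, prior_a) + config_log_likelihood(
        se, sigma_e, config, prior_e
    )


@dataclass
class PosteriorTable:
    """Exact posterior over all causal configurations with <= k_max causal variants.

    Configurations are stored as bitmasks over variant indices; ``log_post``
    is normalized so that posterior probabilities sum to one over the
    enumerated set.
    """

    m: int
    masks: np.ndarray  # (n_configs,) uint64 support bitmasks
    k: np.ndarray  # (n_configs,) number of causal variants
    log_lik: np.ndarray
    log_prior: np.ndarray
    log_post: np.ndarray
    log_evidence: float
    prior: CausalPrior
    kind: str = "eqtl"
    variant_ids: list[str] | None = None

    @property
    def posterior(self) -> np.ndarray:
        return np.exp(self.log_post)

    def config_at(self, i: int) -> CausalConfig:
        mask = int(self.masks[i])
        idx = tuple(j for j in range(self.m) if mask >> j & 1)
        return CausalConfig(idx, self.m)


def _enumerate_combinations(m: int, k: int) -> np.ndarray:
    return np.array(list(combinations(range(m), k)), dtype=np.int64).reshape(-1, k)


def enumerate_posteriors(
    s: SummaryStatVector | np.ndarray,
    sigma_mat: CorrelationMatrix | np.ndarray,
    prior: CausalPrior | None = None,
    config_budget: int = 10_000_000,
) -> PosteriorTable:
    """Enumerate the posterior over all configurations with k <= k_max.

    The prior over configurations is independent Bernoulli(pi_causal) per
    variant, truncated to k <= k_max and — unless ``prior.include_null`` —
    to k >= 1 (the locus is assumed to harbor at least one causal variant);
    normalization is by log-sum-exp.
    """
    prior = prior or CausalPrior()
    sv = s.z if isinstance(s, SummaryStatVector) else np.asarray(s, dtype=float).ravel()
    sigma = _as_matrix(sigma_mat)
    m = sv.size
    if sigma.shape[0] != m:
        raise InputError("statistic / LD dimension mismatch")
    if m > 63:
        raise BudgetExceededError("more than 63 variants; reduce the locus (top-k selection)")
    k_max = min(prior.k_max, m)
    k_min = 0 if prior.include_null else 1
    n_configs = sum(comb(m, k) for k in range(k_min, k_max + 1))
    if n_configs > config_budget:
        raise BudgetExceededError(
            f"{n_configs} configurations exceed the budget of {config_budget}; "
            "reduce k_max or the number of variants"
        )

    alpha, base_ll = _base_quantities(sv, sigma)
    s2 = prior.sigma**2
    masks_parts, k_parts, ll_parts, lp_parts = [], [], [], []
    for k in range(k_min, k_max + 1):
        if k == 0:
            masks_parts.append(np.zeros(1, dtype=np.uint64))
            k_parts.append(np.zeros(1, dtype=np.int64))
            ll_parts.append(np.array([base_ll]))
            lp_parts.append(np.array([prior.log_prior(0, m)]))
            continue
        combs = _enumerate_combinations(m, k)
        sub = sigma[combs[:, :, None], combs[:, None, :]]  # (ncfg, k, k)
        M = np.eye(k)[None, :, :] + s2 * sub
        sign, logdetM = np.linalg.slogdet(M)
        if np.any(sign <= 0):
            raise InputError("a configuration covariance is not positive definite")
        t = sv[combs]  # (ncfg, k)
        x = np.linalg.solve(M, t[:, :, None])[:, :, 0]
        ll = base_ll - 0.5 * logdetM + 0.5 * s2 * np.einsum("ij,ij->i", t, x)
        masks = np.bitwise_or.reduce(
            np.uint64(1) << combs.astype(np.uint64), axis=1
        )
        masks_parts.append(masks)
        k_parts.append(np.full(combs.shape[0], k, dtype=np.int64))
        ll_parts.append(ll)
        lp_parts.append(np.full(combs.shape[0], prior.log_prior(k, m)))

    masks = np.concatenate(masks_parts)
    ks = np.concatenate(k_parts)
    log_lik = np.concatenate(ll_parts)
    log_prior = np.concatenate(lp_parts)
    log_joint = log_lik + log_prior
    log_evidence = float(special.logsumexp(log_joint))
    log_post = log_joint - log_evidence
    kind = s.kind if isinstance(s, SummaryStatVector) else "eqtl"
    ids = s.variant_ids if isinstance(s, SummaryStatVector) else None
    return PosteriorTable(
        m=m,
        masks=masks,
        k=ks,
        log_lik=log_lik,
        log_prior=log_prior,
        log_post=log_post,
        log_evidence=log_evidence,
        prior=prior,
        kind=kind,
        variant_ids=ids,
    )


def pip(table: PosteriorTable) -> np.ndarray:
    """Posterior inclusion probabilities: PIP_j = sum of P(C|S) over configs with c_j = 1."""
    post = table.posterior
    bits = (table.masks[:, None] >> np.arange(table.m, dtype=np.uint64)[None, :]) & np.uint64(1)
    return post @ bits.astype(float)


def _covered_mass(post: np.ndarray, masks: np.ndarray, set_mask: np.uint64) -> float:
    outside = masks & ~set_mask
    return float(post[outside == 0].sum())


def rho_causal_set(table: PosteriorTable, rho: float = 0.95) -> CausalSet:
    """Greedy minimal rho-causal set.

    Grows a variant set K, at each step adding the variant that maximizes
    the covered posterior mass f(K) = sum over configurations whose support
    lies inside K, until f(K) >= rho. Ties go to the lowest variant index.
    f(all variants) = 1, so termination is guaranteed.
    """
    if not 0 < rho < 1:
        raise InputError("rho must be in (0, 1)")
    post = table.posterior
    masks = table.masks
    # configurations below ~1e-14 relative mass cannot change the greedy path
    keep = post > post.max() * 1e-14
    post, masks = post[keep], masks[keep]

    selected: list[int] = []
    set_mask = np.uint64(0)
    mass = _covered_mass(post, masks, set_mask)
    remaining = set(range(table.m))
    while mass < rho and remaining:
        best_j, best_mass = -1, -np.inf
        for j in sorted(remaining):
            cand = set_mask | (np.uint64(1) << np.uint64(j))
            mj = _covered_mass(post, masks, cand)
            if mj > best_mass + 1e-15:
                best_j, best_mass = j, mj
        selected.append(best_j)
        remaining.discard(best_j)
        set_mask |= np.uint64(1) << np.uint64(best_j)
        mass = best_mass
    ids = table.variant_ids or [f"v{i}" for i in range(table.m)]
    sel = sorted(selected)
    return CausalSet(
        variants=sel,
        mass=float(mass),
        rho=rho,
        kind=table.kind,
        variant_ids=[ids[i] for i in sel],
    )


def finemap(
    s: SummaryStatVector | np.ndarray,
    sigma_mat: CorrelationMatrix | np.ndarray,
    prior: CausalPrior | None = None,
    rho: float = 0.95,
) -> tuple[CausalSet, PosteriorTable]:
    """Enumerate the posterior for one statistic vector and extract its rho-causal set."""
    table = enumerate_posteriors(s, sigma_mat, prior)
    return rho_causal_set(table, rho), table


def finemap_meta(
    sm1: SummaryStatVector | np.ndarray,
    sm2: SummaryStatVector | np.ndarray,
    sigma_m: CorrelationMatrix | np.ndarray,
    prior: CausalPrior | None = None,
    rho: float = 0.95,
) -> CausalSet:
    """Fine-map both meta-statistic forms with the meta LD matrix and keep the
    smaller causal set (ties go to the M1 form)."""
    set1, _ = finemap(sm1, sigma_m, prior, rho)
    set2, _ = finemap(sm2, sigma_m, prior, rho)
    return set1 if set1.size <= set2.size else set2
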