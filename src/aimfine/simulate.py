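"""Synthetic inputs for the fine-mapping pipeline.

Three layers of realism are provided, mirroring how the method is usually
evaluated:

* haplotype panels with block LD (a latent-Gaussian threshold copula), from
  which genotype and heterozygosity correlation matrices are computed exactly
  as for real data;
* direct simulation of marginal association z-scores from their multivariate
  normal sampling distribution ``S ~ N(lambda * Sigma @ C, Sigma)`` given an
  LD matrix, a causal-status vector and a non-centrality parameter;
* read-level allele-specific counts with binomial noise, for exercising the
  AIM-calling stage.

All randomness flows through one seed per scenario; per-locus generators are
derived deterministically from ``(seed, locus_index)``.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core import (
    CausalConfig,
    ConfigurationError,
    CorrelationMatrix,
    InputError,
    SummaryStatVector,
)

__all__ = [
    "SimScenario",
    "HaplotypePanel",
    "simulate_haplotypes",
    "simulate_stats",
    "simulate_allelic_counts",
    "simulate_expression",
    "ncp_for_power",
    "power_for_ncp",
    "locus_rng",
    "default_block_structure",
]

# Two-sided significance level whose critical value is 5.2 — the anchor at
# which a non-centrality of 5.2 corresponds to 50% power.
DEFAULT_ALPHA = float(2.0 * stats.norm.sf(5.2))


@dataclass
class SimScenario:
    """A simulation scenario: locus size, causal architecture and effect scale."""

    n_causal: int = 1
    ncp_eqtl: float = 5.2
    ncp_aim: float = 5.2
    n_variants: int = 50
    rho: float = 0.95
    seed: int = 0
    n_loci: int = 100
    n_samples: int = 325
    maf_range: tuple[float, float] = (0.1, 0.5)
    # one LD block spanning the locus: the top eQTL variants of a gene are
    # selected for association and hence all tag the causal signal
    block_size: int = 50
    block_r: float = 0.8

    def __post_init__(self) -> None:
        if not 1 <= self.n_causal <= self.n_variants:
            raise ConfigurationError("need 1 <= n_causal <= n_variants")
        if self.ncp_eqtl < 0 or self.ncp_aim < 0:
            raise ConfigurationError("non-centrality parameters must be >= 0")
        if not 0 < self.rho < 1:
            raise ConfigurationError("rho must be in (0, 1)")
        if self.n_loci < 1 or self.n_samples < 1:
            raise ConfigurationError("n_loci and n_samples must be >= 1")
        self.maf_range = tuple(self.maf_range)

    @classmethod
    def from_yaml(cls, path: str) -> "SimScenario":
        """Load a scenario from a YAML/JSON-style key-value file."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown scenario fields: {sorted(unknown)}")
        return cls(**data)


@dataclass
class HaplotypePanel:
    """2n phased haplotypes over m biallelic variants."""

    haplotypes: np.ndarray  # (2n, m) 0/1
    maf: np.ndarray  # (m,)
    block_structure: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def m(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def genotypes(self) -> np.ndarray:
        """(n, m) dosage matrix, values in {0, 1, 2}."""
        return self.haplotypes[0::2] + self.haplotypes[1::2]

    @property
    def het(self) -> np.ndarray:
        """(n, m) 0/1 heterozygosity indicator."""
        return (self.haplotypes[0::2] != self.haplotypes[1::2]).astype(np.int8)


def locus_rng(seed: int, locus: int) -> np.random.Generator:
    """Deterministic per-locus random stream derived from (seed, locus)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(locus)]))


def default_block_structure(m: int, block_size: int = 10, r: float = 0.8) -> list[tuple[int, int, float]]:
    """Contiguous LD blocks of `block_size` variants at within-block correlation `r`."""
    blocks = []
    for start in range(0, m, block_size):
        blocks.append((start, min(start + block_size, m), r))
    return blocks


def _bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho
    (Owen's T representation)."""
    rho = min(max(rho, -1 + 1e-12), 1 - 1e-12)
    # nudge away from 0 to dodge the h*k == 0 special case of Owen's formula
    if h == 0.0:
        h = -1e-12
    if k == 0.0:
        k = -1e-12
    denom = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * denom)
    ak = (h - rho * k) / (k * denom)
    c = 0.5 if h * k < 0 else 0.0
    p = (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - special.owens_t(h, ah)
        - special.owens_t(k, ak)
        - c
    )
    return float(min(max(p, 0.0), 1.0))


@functools.lru_cache(maxsize=100_000)
def _latent_rho(p_i: float, p_j: float, target: float) -> float:
    """Latent-Gaussian correlation producing Pearson correlation ``target``
    between threshold-dichotomized indicators with success probabilities
    p_i, p_j (allele frequencies)."""
    if target <= 0.0:
        return 0.0
    h, k = stats.norm.ppf(p_i), stats.norm.ppf(p_j)
    sd = np.sqrt(p_i * (1 - p_i) * p_j * (1 - p_j))

    def gap(r: float) -> float:
        return (_bvn_cdf(h, k, r) - p_i * p_j) / sd - target

    hi = 1.0 - 1e-9
    if gap(hi) < 0:  # target exceeds the maximum correlation for this MAF pair
        return hi
    return float(optimize.brentq(gap, 0.0, hi, xtol=1e-6))


def _validate_blocks(block_structure: list[tuple[int, int, float]], m: int) -> None:
    if not block_structure:
        raise ConfigurationError("block structure must not be empty")
    blocks = sorted(block_structure)
    pos = 0
    for start, end, r in blocks:
        if start != pos or end <= start:
            raise ConfigurationError(
                f"block structure must tile [0, {m}) contiguously; got {block_structure}"
            )
        if r < 0 or r >= 1:
            raise ConfigurationError("within-block correlation must be in [0, 1)")
        pos = end
    if pos != m:
        raise ConfigurationError(f"block structure covers [0, {pos}) but m={m}")


def simulate_haplotypes(
    m: int,
    n: int,
    block_structure: list[tuple[int, int, float]] | None = None,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int | np.random.Generator = 0,
) -> HaplotypePanel:
    """Simulate 2n phased haplotypes over m variants with block-constant LD.

    Each haplotype's allele vector is a thresholded draw from a latent
    Gaussian whose within-block equicorrelation is calibrated (via the
    bivariate normal orthant probability) so that the *binary* allele
    correlation — and hence the genotype correlation — matches the block's
    target level in expectation. Blocks are independent, so cross-block LD
    is zero in expectation. Haplotypes are i.i.d., i.e. Hardy–Weinberg
    genotypes.
    """
    if m < 1 or n < 1:
        raise ConfigurationError("m and n must be >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ConfigurationError("maf_range must be within (0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if block_structure is None:
        block_structure = [(0, m, 0.0)]
    _validate_blocks(block_structure, m)

    # Strongly correlated binary variants must have similar allele
    # frequencies (the attainable Pearson correlation shrinks as MAFs
    # diverge), so MAFs are drawn per block: a base frequency plus a
    # per-variant jitter that narrows as the target correlation grows.
    maf = np.empty(m)
    for start, end, r in block_structure:
        base = rng.uniform(lo, hi)
        jitter = rng.uniform(-1.0, 1.0, size=end - start) * (1.0 - r) * (hi - lo) / 2.0
        maf[start:end] = np.clip(base + jitter, lo, hi)
    haps = np.empty((2 * n, m), dtype=np.int8)
    for start, end, r in block_structure:
        size = end - start
        p = maf[start:end]
        if r > 0 and size > 1:
            # pairwise latent correlations calibrated against the block's MAFs
            R = np.eye(size)
            pr = np.round(p, 2)
            for i in range(size):
                for j in range(i + 1, size):
                    R[i, j] = R[j, i] = _latent_rho(
                        float(pr[i]), float(pr[j]), round(float(r), 4)
                    )
            # pairwise-solved matrices can be slightly indefinite; clip spectrum
            w, V = np.linalg.eigh(R)
            if w[0] < 1e-8:
                R = (V * np.maximum(w, 1e-8)) @ V.T
                d = np.sqrt(np.diag(R))
                R = R / np.outer(d, d)
            L = np.linalg.cholesky(R + 1e-12 * np.eye(size))
            latent = rng.standard_normal((2 * n, size)) @ L.T
        else:
            latent = rng.standard_normal((2 * n, size))
        haps[:, start:end] = (latent < stats.norm.ppf(p)).astype(np.int8)
    return HaplotypePanel(haplotypes=haps, maf=maf, block_structure=list(block_structure))


def simulate_stats(
    corr: CorrelationMatrix | np.ndarray,
    config: CausalConfig,
    ncp: float,
    seed: int | np.random.Generator = 0,
    kind: str = "eqtl",
    size: int | None = None,
) -> SummaryStatVector | np.ndarray:
    """Draw marginal association z-scores ``S ~ N(ncp * Sigma @ C, Sigma)``.

    This is the sampling distribution of z-scores at a locus where the
    variants flagged in ``config`` carry a true (z-scale) effect of size
    ``ncp`` and LD spreads the signal to correlated variants.

    With ``size=None`` one draw is returned as a :class:`SummaryStatVector`;
    with an integer ``size`` an ``(size, m)`` array of draws is returned
    (used for Monte-Carlo checks).
    """
    values = corr.values if isinstance(corr, CorrelationMatrix) else np.asarray(corr, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise InputError("correlation matrix must be square")
    if not np.allclose(values, values.T, atol=1e-10):
        raise InputError("correlation matrix must be symmetric")
    if ncp < 0:
        raise InputError("ncp must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = values.shape[0]
    mean = ncp * values @ config.c
    # tiny jitter so empirical (rank-deficient) correlation matrices factor
    L = np.linalg.cholesky(values + 1e-10 * np.eye(m))
    if size is None:
        draw = mean + L @ rng.standard_normal(m)
        return SummaryStatVector(z=draw, kind=kind)
    draws = mean + rng.standard_normal((size, m)) @ L.T
    return draws


def power_for_ncp(ncp: float, alpha_two_sided: float = DEFAULT_ALPHA) -> float:
    """Two-sided power of a z-test at level alpha for Z ~ N(ncp, 1)."""
    if not 0 < alpha_two_sided < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    crit = stats.norm.isf(alpha_two_sided / 2.0)
    return float(stats.norm.sf(crit - ncp) + stats.norm.cdf(-crit - ncp))


def ncp_for_power(power: float, alpha_two_sided: float = DEFAULT_ALPHA) -> float:
    """Non-centrality parameter giving the requested two-sided power.

    The default significance level is the one whose two-sided critical value
    is 5.2, so that 50% power maps back to a non-centrality of exactly 5.2
    and e.g. 80% power maps to 5.2 + Phi^{-1}(0.8).
    """
    if not 0 < power < 1:
        raise ConfigurationError("power must be in (0, 1)")
    if not 0 < alpha_two_sided < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    crit = stats.norm.isf(alpha_two_sided / 2.0)
    lo, hi = 0.0, crit + 10.0
    if power_for_ncp(lo, alpha_two_sided) >= power:
        # alpha alone already exceeds the requested power
        return 0.0
    return float(optimize.brentq(lambda lam: power_for_ncp(lam, alpha_two_sided) - power, lo, hi, xtol=1e-10))


def simulate_allelic_counts(
    genotypes: np.ndarray,
    causal_effect: float,
    depth_model: int | tuple[str, float] = 20,
    seed: int | np.random.Generator = 0,
    gene_id: str = "gene1",
    snp_id: str = "aisnp1",
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate haplotype-resolved read counts at a single aiSNP.

    Individuals heterozygous for the causal variant (dosage 1 in
    ``genotypes``) draw hap1 counts from Binomial(depth, 0.5 + causal_effect);
    homozygous individuals from Binomial(depth, 0.5). ``depth_model`` is
    either a constant total depth or ``("poisson", mean)``.
    """
    genotypes = np.asarray(genotypes)
    n = genotypes.size
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(depth_model, tuple):
        name, param = depth_model
        if name != "poisson":
            raise InputError(f"unknown depth model {name!r}")
        if param < 0:
            raise InputError("depth must be non-negative")
        depth = rng.poisson(param, size=n)
    else:
        if depth_model < 0:
            raise InputError("depth must be non-negative")
        depth = np.full(n, int(depth_model))
    het = genotypes == 1
    p = np.where(het, np.clip(0.5 + causal_effect, 0.0, 1.0), 0.5)
    c1 = rng.binomial(depth, p)
    c2 = depth - c1
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    return pd.DataFrame(
        {
            "sample": sample_ids,
            "gene": gene_id,
            "snp": snp_id,
            "hap1_count": c1,
            "hap2_count": c2,
        }
    )


def simulate_expression(
    genotypes: np.ndarray,
    causal_indices: list[int],
    beta: float,
    seed: int | np.random.Generator = 0,
    noise_sd: float = 1.0,
) -> np.ndarray:
    """Additive cis-effect expression phenotype: standardized causal dosages
    times ``beta`` plus Gaussian noise."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = np.asarray(genotypes, dtype=float)
    y = rng.normal(0.0, noise_sd, size=g.shape[0])
    for j in causal_indices:
        x = g[:, j]
        sd = x.std()
        if sd == 0:
            raise InputError(f"causal variant {j} is monomorphic in the sample")
        y = y + beta * (x - x.mean()) / sd
    return y
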