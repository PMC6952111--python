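"""Shared domain types and exceptions.

The containers here are deliberately thin wrappers around numpy arrays /
pandas frames: they carry the metadata needed to keep z-score vectors,
correlation matrices and causal configurations aligned, and validate the
invariants that the numerical code relies on (symmetry, unit diagonal,
matching lengths).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STAT_KINDS = ("eqtl", "aim", "meta1", "meta2")
CORR_KINDS = ("genotype_ld", "heterozygosity", "meta")


class AimfineError(Exception):
    """Base class for package errors."""


class ConfigurationError(AimfineError):
    """Invalid scenario / run configuration."""


class InputError(AimfineError):
    """Malformed or inconsistent input data."""


class DegenerateStatisticError(AimfineError):
    """A statistic is undefined for this input (zero variance, p-hat in {0,1}, ...)."""


class NoAIMIndividualsError(AimfineError):
    """No individual shows allelic imbalance for this gene; the AIM statistic
    cannot be computed and the gene must be skipped."""


class UndefinedRatioError(AimfineError):
    """Allelic ratio requested for zero total reads."""


class BudgetExceededError(AimfineError):
    """Causal-configuration enumeration would exceed the compute budget."""


@dataclass
class SummaryStatVector:
    """Per-variant z-scores of a declared kind.

    Parameters
    ----------
    z : array of shape (m,)
        Marginal association z-scores.
    kind : str
        One of ``eqtl``, ``aim``, ``meta1``, ``meta2``.
    variant_ids : list of str, optional
        Identifiers aligned with ``z``; synthesized as ``v0..v{m-1}`` if absent.
    """

    z: np.ndarray
    kind: str
    variant_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).ravel()
        if self.kind not in STAT_KINDS:
            raise InputError(f"unknown statistic kind {self.kind!r}; expected one of {STAT_KINDS}")
        if not np.all(np.isfinite(self.z)):
            raise InputError("summary statistics must be finite")
        if self.variant_ids is None:
            self.variant_ids = [f"v{i}" for i in range(self.z.size)]
        elif len(self.variant_ids) != self.z.size:
            raise InputError("variant_ids length does not match z")

    def __len__(self) -> int:
        return self.z.size


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal correlation matrix between m variants."""

    values: np.ndarray
    kind: str = "genotype_ld"
    ridge: float = 0.0
    variant_ids: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InputError(f"correlation matrix must be square, got shape {v.shape}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise InputError("correlation matrix must be symmetric")
        if self.kind not in CORR_KINDS:
            raise InputError(f"unknown correlation kind {self.kind!r}")
        self.values = v
        if self.variant_ids is None:
            self.variant_ids = [f"v{i}" for i in range(v.shape[0])]
        elif len(self.variant_ids) != v.shape[0]:
            raise InputError("variant_ids length does not match matrix dimension")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    def __len__(self) -> int:
        return self.m


@dataclass(frozen=True)
class CausalConfig:
    """Binary causal-status vector, stored as the sorted index tuple of its support."""

    indices: tuple[int, ...]
    m: int

    def __post_init__(self) -> None:
        idx = tuple(sorted(int(i) for i in self.indices))
        object.__setattr__(self, "indices", idx)
        if len(set(idx)) != len(idx):
            raise InputError("duplicate causal indices")
        if idx and (idx[0] < 0 or idx[-1] >= self.m):
            raise InputError("causal index out of range")

    @property
    def k(self) -> int:
        return len(self.indices)

    @property
    def c(self) -> np.ndarray:
        """Dense 0/1 causal-status vector of length m."""
        c = np.zeros(self.m)
        c[list(self.indices)] = 1.0
        return c

    @classmethod
    def from_vector(cls, c) -> "CausalConfig":
        c = np.asarray(c)
        return cls(tuple(np.flatnonzero(c != 0).tolist()), c.size)


@dataclass(frozen=True)
class CausalPrior:
    """Prior over causal configurations and effect sizes.

    sigma
        Prior standard deviation of the (z-scale) causal effect; 5.2 puts
        half the prior mass beyond genome-wide-scale significance.
    pi_causal
        Independent per-variant prior probability of being causal.
    k_max
        Maximum number of simultaneous causal variants enumerated.
    include_null
        Whether the all-zero configuration (no causal variant) is part of
        the enumerated model space. The framework is applied to loci
        pre-selected for significant association, where at least one causal
        variant is assumed; including the null configuration would let a
        signal-free statistic vector produce a spuriously tiny causal set,
        which breaks the choose-the-smaller-meta-set rule. Off by default.
    """

    sigma: float = 5.2
    pi_causal: float = 0.01
    k_max: int = 6
    include_null: bool = False

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ConfigurationError("sigma must be positive")
        if not 0 < self.pi_causal < 1:
            raise ConfigurationError("pi_causal must be in (0, 1)")
        if self.k_max < 1:
            raise ConfigurationError("k_max must be at least 1")

    def log_prior(self, k: int, m: int) -> float:
        return k * np.log(self.pi_causal) + (m - k) * np.log1p(-self.pi_causal)


@dataclass
class CausalSet:
    """A rho-causal set: variant indices whose configurations jointly carry
    posterior mass >= rho."""

    variants: list[int]
    mass: float
    rho: float
    kind: str
    variant_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.variants)

    def __contains__(self, idx: int) -> bool:
        return idx in set(self.variants)
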