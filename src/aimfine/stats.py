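"""Per-variant association statistics and correlation matrices.

Two marginal statistics are computed per cis variant:

* an eQTL z-score from ordinary least squares of normalized total
  expression on the (standardized) variant dosage,
  ``z_i = (beta_hat_i / sigma_hat) * sqrt(n)``;
* an AIM z-score from a pooled two-proportion test comparing the
  heterozygote fraction among AIM individuals with that among
  balanced individuals (the case/control form used in GWAS).

Alongside, three correlation matrices describe how those statistics
co-vary across variants: the genotype LD matrix Sigma_E, the
heterozygosity-indicator correlation Sigma_A, and (in `meta`) their
average Sigma_M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    CorrelationMatrix,
    DegenerateStatisticError,
    InputError,
    NoAIMIndividualsError,
    SummaryStatVector,
)

__all__ = [
    "ExpressionPhenotype",
    "AIMContingency",
    "eqtl_zscores",
    "aim_zscore",
    "aim_zscores",
    "genotype_correlation",
    "heterozygosity_correlation",
    "select_top_variants",
    "regularize",
]


@dataclass
class ExpressionPhenotype:
    """Normalized total-expression values for one gene, with optional covariates."""

    Y: np.ndarray
    Z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        if self.Y.size < 3:
            raise InputError("need at least 3 samples for a defined residual SD")
        if not np.all(np.isfinite(self.Y)):
            raise InputError("expression values must be finite")
        if self.Z is not None:
            self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
            if self.Z.shape[0] != self.Y.size:
                self.Z = self.Z.T
            if self.Z.shape[0] != self.Y.size:
                raise InputError("covariate rows must match sample count")

    @property
    def n(self) -> int:
        return self.Y.size


@dataclass
class AIMContingency:
    """2x2 summary for one variant: heterozygosity split by AIM status."""

    n1: int  # individuals with AIM
    n2: int  # individuals with balanced expression
    p1_hat: float  # het fraction among AIM
    p2_hat: float  # het fraction among balanced

    @property
    def p_hat(self) -> float:
        return (self.n1 * self.p1_hat + self.n2 * self.p2_hat) / (self.n1 + self.n2)

    @classmethod
    def from_indicators(cls, het: np.ndarray, status: np.ndarray) -> "AIMContingency":
        """Build from per-individual het (0/1) and AIM status (0/1) vectors."""
        het = np.asarray(het, dtype=float)
        status = np.asarray(status, dtype=float)
        aim = status == 1
        bal = status == 0
        n1, n2 = int(aim.sum()), int(bal.sum())
        p1 = float(het[aim].mean()) if n1 else np.nan
        p2 = float(het[bal].mean()) if n2 else np.nan
        return cls(n1=n1, n2=n2, p1_hat=p1, p2_hat=p2)


def eqtl_zscores(
    pheno: ExpressionPhenotype | np.ndarray,
    genotypes: np.ndarray,
    variant_ids: list[str] | None = None,
) -> SummaryStatVector:
    """Marginal OLS eQTL z-scores for every variant.

    Fits ``Y = mu + beta_i X_i + gamma Z + eps`` one variant at a time with
    standardized dosages, and returns ``z_i = (beta_hat_i / sigma_hat_i) *
    sqrt(n)`` with ``sigma_hat = sqrt(rss / (n - 2))``. Covariates, when
    present, are residualized out of Y once before the per-variant fits.

    Constant dosage columns carry no association information; they are
    dropped with a warning and omitted from the returned vector.
    """
    if not isinstance(pheno, ExpressionPhenotype):
        pheno = ExpressionPhenotype(Y=pheno)
    X = np.asarray(genotypes, dtype=float)
    if X.ndim != 2 or X.shape[0] != pheno.n:
        raise InputError("genotypes must be (n_samples, m_variants)")
    n, m = X.shape
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(m)]

    y = pheno.Y - pheno.Y.mean()
    if pheno.Z is not None:
        Z = np.column_stack([np.ones(n), pheno.Z])
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        y = y - Z @ coef

    sd = X.std(axis=0)
    keep = sd > 0
    if not np.all(keep):
        dropped = [variant_ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping constant genotype columns: {dropped}")
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    xty = Xs.T @ y
    xtx = np.einsum("ij,ij->j", Xs, Xs)
    beta = xty / xtx
    rss = y @ y - xty**2 / xtx
    rss = np.maximum(rss, 0.0)
    sigma = np.sqrt(rss / (n - 2))
    if np.any(sigma == 0):
        raise DegenerateStatisticError(
            "residual SD is zero for at least one variant (perfect fit)"
        )
    z = beta / sigma * np.sqrt(n)
    return SummaryStatVector(z=z, kind="eqtl", variant_ids=[v for v, k in zip(variant_ids, keep) if k])


def aim_zscore(contingency: AIMContingency) -> float:
    """Pooled two-proportion z comparing het fractions of AIM vs balanced groups.

    ``z = (p1_hat - p2_hat) / sqrt(p_hat (1 - p_hat) (n1 + n2) / (n1 n2))``,
    standard normal under the null of equal heterozygote fractions.
    """
    if contingency.n1 < 1:
        raise NoAIMIndividualsError(
            "no individuals with AIM; the AIM statistic is undefined for this gene"
        )
    if contingency.n2 < 1:
        raise DegenerateStatisticError("no balanced individuals; statistic undefined")
    p = contingency.p_hat
    if not 0.0 < p < 1.0:
        raise DegenerateStatisticError(
            f"pooled het fraction {p} leaves no variance; statistic undefined"
        )
    n1, n2 = contingency.n1, contingency.n2
    se = np.sqrt(p * (1.0 - p) * (n1 + n2) / (n1 * n2))
    return float((contingency.p1_hat - contingency.p2_hat) / se)


def aim_zscores(
    het: np.ndarray,
    status: np.ndarray,
    variant_ids: list[str] | None = None,
) -> tuple[SummaryStatVector, list[int]]:
    """Per-variant AIM z-scores from an (n, m) het-indicator matrix and a
    per-individual AIM status vector (entries 0/1; NaN = missing, excluded).

    Variants whose pooled het fraction is 0 or 1 among status-called
    individuals are undefined; their indices are returned in the second
    element and their z set to 0 is *not* attempted — callers must drop them.
    """
    het = np.asarray(het, dtype=float)
    status = np.asarray(status, dtype=float)
    called = ~np.isnan(status)
    het_c, status_c = het[called], status[called]
    if not np.any(status_c == 1):
        raise NoAIMIndividualsError("no individuals with AIM for this gene")
    m = het.shape[1]
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(m)]
    zs, undefined = [], []
    for j in range(m):
        cont = AIMContingency.from_indicators(het_c[:, j], status_c)
        try:
            zs.append(aim_zscore(cont))
        except DegenerateStatisticError:
            undefined.append(j)
            zs.append(np.nan)
    z = np.asarray(zs)
    kept = [i for i in range(m) if i not in set(undefined)]
    vec = SummaryStatVector(
        z=z[kept], kind="aim", variant_ids=[variant_ids[i] for i in kept]
    )
    return vec, undefined


def _pearson_matrix(X: np.ndarray, kind: str, variant_ids: list[str] | None) -> CorrelationMatrix:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise InputError("need an (n, m) matrix with m >= 1")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise DegenerateStatisticError(f"constant columns at indices {bad}; correlation undefined")
    if X.shape[1] == 1:
        vals = np.ones((1, 1))
    else:
        vals = np.corrcoef(X, rowvar=False)
    vals = np.clip((vals + vals.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(vals, 1.0)
    return CorrelationMatrix(values=vals, kind=kind, variant_ids=variant_ids)


def genotype_correlation(genotypes: np.ndarray, variant_ids: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise Pearson correlation of dosage columns (the LD matrix Sigma_E)."""
    return _pearson_matrix(genotypes, "genotype_ld", variant_ids)


def heterozygosity_correlation(het: np.ndarray, variant_ids: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise Pearson correlation of 0/1 heterozygosity indicators (Sigma_A)."""
    return _pearson_matrix(het, "heterozygosity", variant_ids)


def select_top_variants(z: SummaryStatVector | np.ndarray, k: int = 50) -> np.ndarray:
    """Indices of the k variants with largest |z|, descending, ties by lower index."""
    zv = z.z if isinstance(z, SummaryStatVector) else np.asarray(z, dtype=float)
    if zv.size < 1:
        raise InputError("need at least one variant")
    order = np.argsort(-np.abs(zv), kind="stable")
    return order[: min(k, zv.size)]


def regularize(corr: CorrelationMatrix, ridge: float = 1e-3) -> CorrelationMatrix:
    """Ridge-regularize a correlation matrix and restore the unit diagonal.

    ``(Sigma + ridge*I) / (1 + ridge)`` is positive definite whenever Sigma
    is positive semi-definite, changes no entry by more than ``ridge``, and
    keeps the diagonal exactly 1, so downstream Cholesky factorizations are
    safe on rank-deficient empirical LD.
    """
    if ridge < 0:
        raise InputError("ridge must be non-negative")
    vals = (corr.values + ridge * np.eye(corr.m)) / (1.0 + ridge)
    return CorrelationMatrix(values=vals, kind=corr.kind, ridge=corr.ridge + ridge, variant_ids=corr.variant_ids)
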