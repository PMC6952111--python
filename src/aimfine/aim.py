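"""Allelic-imbalance (AIM) calling from haplotype-resolved read counts.

For each gene in each individual, phased heterozygous coding SNPs (aiSNPs)
provide hap1/hap2 read counts (c1, c2). The allelic ratio AR = c1/(c1+c2)
deviates from 0.5 when the two chromosomes express the gene unequally. A
sample-gene is called AIM either by an empirical threshold on AR (default
AR < 0.35 or AR > 0.65, i.e. two empirical standard deviations from the
null) or by an exact two-sided binomial test against p = 0.5.

To avoid double counting reads that overlap multiple aiSNPs, only the SNP
with the most reads is used per sample-gene; a minimum total read count
(default 20) filters noisy calls.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import InputError, UndefinedRatioError

__all__ = [
    "allelic_ratio",
    "select_aisnp",
    "read_filter",
    "binarize_empirical",
    "binom_test_pvalue",
    "binarize_binomial",
    "empirical_thresholds",
    "call_aim",
    "concordance_diagnostic",
]

COUNT_COLUMNS = ["sample", "gene", "snp", "hap1_count", "hap2_count"]


def allelic_ratio(c1: int, c2: int) -> float:
    """Fraction of allele-informative reads on haplotype 1."""
    if c1 < 0 or c2 < 0:
        raise InputError("read counts must be non-negative")
    total = c1 + c2
    if total == 0:
        raise UndefinedRatioError("allelic ratio undefined for zero total reads")
    return c1 / total


def select_aisnp(records: pd.DataFrame) -> pd.Series:
    """The aiSNP for one sample-gene: the record with the most total reads.

    Ties are broken by the lexicographically smallest snp id, making the
    choice deterministic.
    """
    if len(records) == 0:
        raise InputError("no candidate aiSNP records for this sample-gene")
    totals = records["hap1_count"] + records["hap2_count"]
    best = records.assign(_total=totals).sort_values(
        ["_total", "snp"], ascending=[False, True], kind="stable"
    )
    return best.iloc[0].drop("_total")


def read_filter(c1: int, c2: int, min_reads: int = 20) -> bool:
    """True iff the total read count reaches the minimum (default 20)."""
    return (c1 + c2) >= min_reads


def binarize_empirical(ar: float, lo: float = 0.35, hi: float = 0.65) -> int:
    """AIM (1) iff AR < lo or AR > hi, strictly; boundary values are balanced (0)."""
    if not 0.0 <= ar <= 1.0:
        raise InputError("allelic ratio must be in [0, 1]")
    return int(ar < lo or ar > hi)


def binom_test_pvalue(c1: int, c2: int) -> float:
    """Exact two-sided binomial test of c1 successes in c1+c2 trials vs p = 0.5."""
    total = c1 + c2
    if total == 0:
        raise UndefinedRatioError("binomial test undefined for zero total reads")
    return float(stats.binomtest(c1, total, 0.5).pvalue)


def binarize_binomial(c1: int, c2: int, alpha: float = 0.05) -> int:
    """AIM (1) iff the exact two-sided binomial p-value is below alpha."""
    return int(binom_test_pvalue(c1, c2) < alpha)


def empirical_thresholds(ars: np.ndarray, n_sd: float = 2.0) -> tuple[float, float]:
    """Derive (lo, hi) AR thresholds as ``0.5 -/+ n_sd * sd`` from an observed
    allelic-ratio distribution (the construction behind the 0.35/0.65 default)."""
    ars = np.asarray(ars, dtype=float)
    if ars.size < 2:
        raise InputError("need at least 2 allelic ratios to estimate a spread")
    sd = float(ars.std(ddof=1))
    return 0.5 - n_sd * sd, 0.5 + n_sd * sd


def _validate_counts(counts: pd.DataFrame) -> None:
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise InputError(f"count table is missing columns {missing}")
    if len(counts) and (counts["hap1_count"].min() < 0 or counts["hap2_count"].min() < 0):
        raise InputError("negative read counts")


def call_aim(
    counts: pd.DataFrame,
    method: str = "empirical",
    min_reads: int = 20,
    ar_lo: float = 0.35,
    ar_hi: float = 0.65,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per sample-gene AIM status from an allelic count table.

    For every (gene, sample) the aiSNP is chosen (most reads, ties by snp
    id), the read filter is applied, and the surviving allelic ratio is
    binarized by the requested method. Samples failing the filter get a
    missing status (NaN).

    Returns a frame with columns gene, sample, snp, ar, status, method.
    """
    if method not in ("empirical", "binomial"):
        raise InputError(f"unknown binarization method {method!r}")
    _validate_counts(counts)
    rows = []
    for (gene, sample), grp in counts.groupby(["gene", "sample"], sort=True):
        rec = select_aisnp(grp)
        c1, c2 = int(rec["hap1_count"]), int(rec["hap2_count"])
        if not read_filter(c1, c2, min_reads):
            rows.append((gene, sample, rec["snp"], np.nan, np.nan))
            continue
        ar = allelic_ratio(c1, c2)
        if method == "empirical":
            status = binarize_empirical(ar, ar_lo, ar_hi)
        else:
            status = binarize_binomial(c1, c2, alpha)
        rows.append((gene, sample, rec["snp"], ar, float(status)))
    out = pd.DataFrame(rows, columns=["gene", "sample", "snp", "ar", "status"])
    out["method"] = method
    return out


def concordance_diagnostic(
    counts: pd.DataFrame,
    thresholds: tuple[int, ...] = (0, 10, 20, 30),
) -> pd.DataFrame:
    """Concordance of allelic ratios between aiSNP pairs within sample-genes.

    For each read threshold, every (gene, sample) with at least two SNPs
    passing the filter contributes the allelic-ratio pair of its two
    deepest SNPs; the Pearson correlation over those pairs is reported.
    Deeper thresholds should give higher concordance because binomial noise
    shrinks with read depth.
    """
    _validate_counts(counts)
    totals = counts["hap1_count"] + counts["hap2_count"]
    counts = counts.assign(_total=totals)
    rows = []
    for t in thresholds:
        kept = counts[counts["_total"] >= max(t, 1)]
        xs, ys = [], []
        for (_gene, _sample), grp in kept.groupby(["gene", "sample"], sort=True):
            if len(grp) < 2:
                continue
            top2 = grp.sort_values(["_total", "snp"], ascending=[False, True]).iloc[:2]
            ars = [
                allelic_ratio(int(r["hap1_count"]), int(r["hap2_count"]))
                for _, r in top2.iterrows()
            ]
            xs.append(ars[0])
            ys.append(ars[1])
        if len(xs) < 2:
            warnings.warn(f"fewer than 2 aiSNP pairs at read threshold {t}; skipping")
            rows.append((t, np.nan, len(xs)))
            continue
        r = float(np.corrcoef(xs, ys)[0, 1])
        rows.append((t, r, len(xs)))
    return pd.DataFrame(rows, columns=["read_threshold", "pearson_r", "n_pairs"])
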