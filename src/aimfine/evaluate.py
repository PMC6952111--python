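"""Scoring fine-mapping runs and validating causal sets against annotations.

Two families of checks live here:

* simulation metrics — recall (fraction of loci whose implanted causal
  variants are all inside the reported set) and the reduction rate
  r = (N_eQTL - N_Meta) / N_eQTL comparing causal-set sizes with and
  without allelic-imbalance information;
* annotation-based validation on real data, where truth is unknown —
  a Mann-Whitney test on TSS distances and a Fisher exact test for
  enrichment of causal-set variants in active genomic intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import CausalSet, InputError, SummaryStatVector

__all__ = [
    "LocusResult",
    "EvalResult",
    "reduction_rate",
    "recall_rate",
    "topn_comparison",
    "annotation_enrichment",
    "tss_distance_test",
]


@dataclass
class LocusResult:
    """Fine-mapping outcome at one simulated locus."""

    true_causal: tuple[int, ...]
    n_eqtl: int
    n_meta: int
    captured_meta: bool
    captured_eqtl: bool

    @property
    def reduction(self) -> float:
        return reduction_rate(self.n_eqtl, self.n_meta)


@dataclass
class EvalResult:
    """Aggregate over simulated loci."""

    loci: list[LocusResult] = field(default_factory=list)

    @property
    def recall_meta(self) -> float:
        return recall_rate([r.captured_meta for r in self.loci])

    @property
    def recall_eqtl(self) -> float:
        return recall_rate([r.captured_eqtl for r in self.loci])

    @property
    def median_reduction(self) -> float:
        return float(np.median([r.reduction for r in self.loci]))

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def reduction_rate(n_eqtl: int, n_meta: int) -> float:
    """Relative shrinkage of the causal set when AIM is added; negative when
    the meta set is larger."""
    if n_eqtl < 1:
        raise InputError("reduction rate undefined for an empty eQTL causal set")
    return (n_eqtl - n_meta) / n_eqtl


def recall_rate(captured: list[bool]) -> float:
    """Fraction of loci in which all true causal variants were captured."""
    if not captured:
        raise InputError("recall undefined on an empty result list")
    return float(np.mean([bool(c) for c in captured]))


def topn_comparison(causal_set: CausalSet | list[int], eqtl_z: SummaryStatVector | np.ndarray) -> int:
    """How many causal-set variants are absent from the same-size top-|z| eQTL set.

    A value of 0 would mean the causal set is just the strongest eQTLs; larger
    values show the set is not a mere effect-size ranking.
    """
    members = causal_set.variants if isinstance(causal_set, CausalSet) else list(causal_set)
    zv = eqtl_z.z if isinstance(eqtl_z, SummaryStatVector) else np.asarray(eqtl_z, dtype=float)
    n = len(members)
    order = np.argsort(-np.abs(zv), kind="stable")
    topn = set(order[:n].tolist())
    return len(set(members) - topn)


def _in_intervals(positions: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """0/1 overlap of positions with 0-based half-open [start, end) intervals."""
    positions = np.asarray(positions, dtype=np.int64)
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    hit = np.zeros(positions.size, dtype=bool)
    for start, end in iv:
        hit |= (positions >= start) & (positions < end)
    return hit


def annotation_enrichment(
    set_a_positions: np.ndarray,
    set_b_positions: np.ndarray,
    active_intervals: np.ndarray,
) -> tuple[float, float]:
    """Fisher exact test: are set-A variants more often inside active intervals
    than set-B variants?

    Intervals follow the BED convention (0-based, half-open): a variant at an
    interval's start is inside; one at its end is outside. Returns
    (odds ratio, two-sided p).
    """
    a_in = _in_intervals(set_a_positions, active_intervals)
    b_in = _in_intervals(set_b_positions, active_intervals)
    table = np.array(
        [
            [int(a_in.sum()), int((~a_in).sum())],
            [int(b_in.sum()), int((~b_in).sum())],
        ]
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise InputError(f"degenerate 2x2 table (zero margin): {table.tolist()}")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def tss_distance_test(set_a_distances: np.ndarray, set_b_distances: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value on absolute TSS distances of two
    variant sets (rank-based, hence invariant to monotone transforms)."""
    a = np.abs(np.asarray(set_a_distances, dtype=float))
    b = np.abs(np.asarray(set_b_distances, dtype=float))
    if a.size == 0 or b.size == 0:
        raise InputError("both distance samples must be non-empty")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
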