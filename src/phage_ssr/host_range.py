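"""Motif composition by host-range group, with Pearson chi-square.

Broad- vs restricted-host-range phage groups are compared on the rotation-
class composition of their mono- (or longer) nucleotide repeats. Counts are
pooled within each group; the test always runs on counts, never on the
percentages shown in composition plots (a chi-square on percentages is
invalid).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ComputationError
from .ssr_engine import SSRRecord, canonical_motif_class


@dataclass(frozen=True)
class GroupComposition:
    group_id: str
    k: int
    counts: Mapping[str, int]       # motif class -> pooled count
    percents: Mapping[str, float]   # sums to 100 when total > 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def group_composition(
    ssrs_by_genome: Mapping[str, Sequence[SSRRecord]],
    groups: Mapping[str, str],
    k: int,
) -> list[GroupComposition]:
    """Pool motif-class counts of length-k repeats within each group."""
    unassigned = set(ssrs_by_genome) - set(groups)
    if unassigned:
        raise ValueError(f"genomes without a group assignment: {sorted(unassigned)}")
    pooled: dict[str, dict[str, int]] = {g: {} for g in dict.fromkeys(groups.values())}
    for genome, ssrs in ssrs_by_genome.items():
        bucket = pooled[groups[genome]]
        for ssr in ssrs:
            if ssr.motif_len != k:
                continue
            cls = canonical_motif_class(ssr.motif)
            bucket[cls] = bucket.get(cls, 0) + 1
    out = []
    for group_id, counts in pooled.items():
        total = sum(counts.values())
        percents = {c: 100.0 * n / total for c, n in counts.items()} if total else {}
        out.append(GroupComposition(group_id=group_id, k=k, counts=counts, percents=percents))
    return out


def pearson_chi_square(
    table: Sequence[Sequence[int]] | np.ndarray, yates: bool = False
) -> ChiSquareResult:
    """Pearson chi-square of independence on an r x m count table.

    statistic = sum (O - E)^2 / E with E from the row/column margins;
    df = (r-1)(m-1). No continuity correction by default (set ``yates``
    for a 2x2 table). A zero margin makes an expected cell 0 and is an
    error naming the offending row/column.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any():
        raise ComputationError(f"zero row margin at row {int(np.argmax(row == 0))}")
    if (col == 0).any():
        raise ComputationError(f"zero column margin at column {int(np.argmax(col == 0))}")
    exp = np.outer(row, col) / obs.sum()
    dev = np.abs(obs - exp)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float((dev ** 2 / exp).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return ChiSquareResult(statistic=statistic, df=df, p_value=float(stats.chi2.sf(statistic, df)))


def compare_groups(
    comp_a: GroupComposition, comp_b: GroupComposition, yates: bool = False
) -> tuple[ChiSquareResult, list[str]]:
    """Chi-square between two pooled compositions.

    Motif classes absent from both groups are dropped; returns the result
    and the ordered class list actually tested.
    """
    classes = sorted(set(comp_a.counts) | set(comp_b.counts))
    classes = [c for c in classes if comp_a.counts.get(c, 0) + comp_b.counts.get(c, 0) > 0]
    if len(classes) < 2:
        raise ComputationError("fewer than 2 motif classes with nonzero counts")
    table = [
        [comp_a.counts.get(c, 0) for c in classes],
        [comp_b.counts.get(c, 0) for c in classes],
    ]
    return pearson_chi_square(table, yates=yates), classes
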