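"""Coding vs non-coding placement of SSRs.

Each SSR is labeled against the genome's coding intervals: by default a
tract is *coding* when it overlaps any CDS by at least 1 bp (boundary
spanning tracts count as coding); the alternative rule assigns by the
position of the tract's first base. When several CDS overlap a tract the
one with the largest overlap wins, ties broken by smallest start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .errors import ComputationError
from .sequence_io import AnnotationTable
from .ssr_engine import SSRRecord


@dataclass(frozen=True)
class RegionLabel:
    ssr: SSRRecord
    label: Literal["coding", "non-coding"]
    cds_label: str      # empty iff non-coding
    overlap_bp: int


def classify_ssrs(
    ssrs: Sequence[SSRRecord],
    annotation: AnnotationTable,
    genome_len: int | None = None,
    rule: Literal["overlap", "start"] = "overlap",
) -> list[RegionLabel]:
    """Label every SSR as coding or non-coding (exactly once each)."""
    labels: list[RegionLabel] = []
    for ssr in ssrs:
        if genome_len is not None and ssr.end > genome_len:
            raise ValueError(
                f"SSR at {ssr.start}..{ssr.end} exceeds genome length {genome_len}"
            )
        best_label, best_ov, best_start = "", 0, None
        for cds in annotation.intervals:
            if cds.start > ssr.end:
                break
            ov = min(ssr.end, cds.end) - max(ssr.start, cds.start) + 1
            if rule == "start":
                ov = ov if cds.start <= ssr.start <= cds.end else 0
            if ov > best_ov or (ov == best_ov and ov > 0 and cds.start < best_start):
                best_label, best_ov, best_start = cds.label, ov, cds.start
        if best_ov >= 1:
            labels.append(RegionLabel(ssr, "coding", best_label, best_ov))
        else:
            labels.append(RegionLabel(ssr, "non-coding", "", 0))
    return labels


def coding_fraction(labels: Sequence[RegionLabel]) -> tuple[float, float]:
    """(% coding, % non-coding); the two sum to 100."""
    if not labels:
        raise ComputationError("no labeled SSRs")
    n_coding = sum(1 for l in labels if l.label == "coding")
    pct = 100.0 * n_coding / len(labels)
    return pct, 100.0 - pct


def per_cds_distribution(labels: Sequence[RegionLabel], top_k: int = 15) -> pd.DataFrame:
    """Share of all SSRs attributable to each of the top_k most SSR-rich CDS.

    Remaining coding SSRs pool into "Others"; non-coding into "NC".
    Percentages sum to 100.
    """
    total = len(labels)
    counts: dict[str, int] = {}
    n_nc = 0
    for l in labels:
        if l.label == "coding":
            counts[l.cds_label] = counts.get(l.cds_label, 0) + 1
        else:
            n_nc += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = [
        {"cds_label": name, "n_ssr": n, "pct_of_all_ssrs": 100.0 * n / total}
        for name, n in ranked[:top_k]
    ]
    n_others = sum(n for _, n in ranked[top_k:])
    rows.append(
        {"cds_label": "Others", "n_ssr": n_others, "pct_of_all_ssrs": 100.0 * n_others / total if total else 0.0}
    )
    rows.append({"cds_label": "NC", "n_ssr": n_nc, "pct_of_all_ssrs": 100.0 * n_nc / total if total else 0.0})
    return pd.DataFrame(rows, columns=["cds_label", "n_ssr", "pct_of_all_ssrs"])


def motif_len_by_region(labels: Sequence[RegionLabel]) -> pd.DataFrame:
    """Per motif length 1-6: the percentage of that class's SSRs in coding
    regions. Lengths with no SSRs at all are flagged absent (NaN), never 0."""
    rows = []
    for k in range(1, 7):
        klabels = [l for l in labels if l.ssr.motif_len == k]
        n = len(klabels)
        if n == 0:
            rows.append({"motif_len": k, "n_ssr": 0, "pct_coding": float("nan")})
        else:
            n_coding = sum(1 for l in klabels if l.label == "coding")
            rows.append({"motif_len": k, "n_ssr": n, "pct_coding": 100.0 * n_coding / n})
    return pd.DataFrame(rows, columns=["motif_len", "n_ssr", "pct_coding"])
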