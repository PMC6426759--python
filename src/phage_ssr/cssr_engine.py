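"""Compound microsatellite (cSSR) construction and classification.

Two SSRs whose intervening distance is at most dMAX bases belong to the same
compound locus. Chaining sweeps left to right over the start-sorted SSR
list and joins the next tract whenever start_next - max_end_so_far - 1 <=
dMAX, which is exactly the connected components of the pairwise gap graph.
Chains of length >= 2 become CompoundSSRs; singletons stay standalone.

Classes follow the field's structure nomenclature: two tracts of different
rotation classes at zero gap form a *compound* locus; with an interruption,
an *interrupted compound* (or *interrupted pure* when both tracts share a
rotation class); three or more tracts with any interruption form a
*complex* locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .ssr_engine import SSRRecord, canonical_motif_class

DMAX_MIN, DMAX_MAX = 0, 50


@dataclass(frozen=True)
class CssrParams:
    """dMAX: largest permitted distance (bp) between chained SSRs, 0-50."""

    dmax: int = 10

    def __post_init__(self) -> None:
        if not (DMAX_MIN <= self.dmax <= DMAX_MAX):
            raise ValueError(f"dmax must be in [{DMAX_MIN}, {DMAX_MAX}], got {self.dmax}")


@dataclass(frozen=True)
class CompoundSSR:
    """An ordered chain of >=2 SSRs merged under dMAX."""

    genome_id: str
    members: tuple[SSRRecord, ...]
    start: int = field(init=False)
    end: int = field(init=False)
    span_len: int = field(init=False)
    n_members: int = field(init=False)
    cssr_class: str = field(init=False)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a compound SSR needs at least 2 members")
        object.__setattr__(self, "n_members", len(self.members))
        object.__setattr__(self, "start", self.members[0].start)
        object.__setattr__(self, "end", max(m.end for m in self.members))
        object.__setattr__(self, "span_len", self.end - self.start + 1)
        object.__setattr__(self, "cssr_class", classify_cssr(self))

    @property
    def gaps(self) -> tuple[int, ...]:
        """Intervening bases between consecutive members (negative = overlap)."""
        return tuple(
            b.start - a.end - 1 for a, b in zip(self.members, self.members[1:])
        )


def classify_cssr(c: CompoundSSR) -> str:
    """Structure class of a compound locus (see module docstring)."""
    if len(c.members) < 2:
        raise ValueError("classification needs >= 2 members")
    gaps = tuple(b.start - a.end - 1 for a, b in zip(c.members, c.members[1:]))
    interrupted = any(g >= 1 for g in gaps)
    if len(c.members) == 2:
        same_class = canonical_motif_class(c.members[0].motif) == canonical_motif_class(
            c.members[1].motif
        )
        if same_class:
            # gap 0 between same-class tracts occurs only at a rotation
            # phase break (e.g. ACACAC|CACACA); treated as compound.
            return "interrupted-pure" if interrupted else "compound"
        return "interrupted-compound" if interrupted else "compound"
    return "complex" if interrupted else "compound"


def build_cssrs(
    ssrs: Sequence[SSRRecord], params: CssrParams | None = None
) -> tuple[list[CompoundSSR], list[SSRRecord]]:
    """Chain start-sorted SSRs of one genome into compound loci.

    Returns (compound loci, standalone SSRs); every input SSR appears in
    exactly one of the two. Input must be sorted by start (overlapping
    tracts, gap < 0, always chain).
    """
    params = params or CssrParams()
    if any(b.start < a.start for a, b in zip(ssrs, ssrs[1:])):
        raise ValueError("SSR list must be sorted by start")
    cssrs: list[CompoundSSR] = []
    standalone: list[SSRRecord] = []
    chain: list[SSRRecord] = []
    max_end = None
    for ssr in ssrs:
        if chain and ssr.start - max_end - 1 <= params.dmax:
            chain.append(ssr)
            max_end = max(max_end, ssr.end)
            continue
        if len(chain) >= 2:
            cssrs.append(CompoundSSR(genome_id=chain[0].genome_id, members=tuple(chain)))
        elif chain:
            standalone.append(chain[0])
        chain = [ssr]
        max_end = ssr.end
    if len(chain) >= 2:
        cssrs.append(CompoundSSR(genome_id=chain[0].genome_id, members=tuple(chain)))
    elif chain:
        standalone.append(chain[0])
    return cssrs, standalone


def ccssr_count(cssrs: Iterable[CompoundSSR]) -> int:
    """Total number of individual SSRs that are members of compound loci."""
    return sum(c.n_members for c in cssrs)


def dmax_sweep(ssrs: Sequence[SSRRecord], dmax_values: Iterable[int]) -> pd.DataFrame:
    """cSSR incidence as a function of dMAX: (dmax, n_cssr, cssr_percent).

    n_cssr is non-decreasing in dMAX (merging can only grow); cssr_percent
    is 100 * n_cssr / n_ssr.
    """
    n_ssr = len(ssrs)
    rows = []
    for d in dmax_values:
        cssrs, _ = build_cssrs(ssrs, CssrParams(dmax=int(d)))
        rows.append(
            {
                "dmax": int(d),
                "n_cssr": len(cssrs),
                "cssr_percent": 100.0 * len(cssrs) / n_ssr if n_ssr else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["dmax", "n_cssr", "cssr_percent"])
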