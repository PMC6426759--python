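"""Per-genome and cohort-level SSR statistics.

Relative abundance (RA) is the number of SSRs per kb of genome; relative
density (RD) is the SSR sequence space (tract bp) per kb; cRA/cRD are the
same quantities for compound loci, with cRD counting the full compound
span including interruptions. Two distinct "compound percentage" readings
are kept apart: ``cssr_percent`` = 100 * n_cssr / n_ssr (how many compound
loci relative to SSRs) and ``ssr_in_cssr_percent`` = 100 * CcSSR / n_ssr
(what fraction of SSRs sit inside compound loci).

Compound incidence is tested against a cohort expectation: with
c' the mean members-per-compound across the cohort, a genome carrying
CcSSR member SSRs is expected to show E = CcSSR / c' compound loci, and
z = (O - E) / sqrt(E) measures the departure of the observed count O.
All values are kept at full precision internally; rounding to 2 decimals
happens only at serialization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from scipy import stats

from .cssr_engine import CompoundSSR, ccssr_count
from .errors import ComputationError
from .sequence_io import SequenceRecord
from .ssr_engine import SSRRecord


@dataclass(frozen=True)
class GenomeSummary:
    genome_id: str
    genome_len: int
    gc_fraction: float
    n_ssr: int
    n_cssr: int          # cSSR_obs, the "O" of the z-score
    ccssr: int           # SSRs participating in compound loci
    ssr_bp: int
    cssr_bp: int
    ra: float = field(init=False)
    rd: float = field(init=False)
    cra: float = field(init=False)
    crd: float = field(init=False)
    cssr_percent: float = field(init=False)
    ssr_in_cssr_percent: float = field(init=False)

    def __post_init__(self) -> None:
        if self.genome_len <= 0:
            raise ValueError("genome length must be positive")
        kb = self.genome_len / 1000.0
        object.__setattr__(self, "ra", self.n_ssr / kb)
        object.__setattr__(self, "rd", self.ssr_bp / kb)
        object.__setattr__(self, "cra", self.n_cssr / kb)
        object.__setattr__(self, "crd", self.cssr_bp / kb)
        object.__setattr__(
            self, "cssr_percent", 100.0 * self.n_cssr / self.n_ssr if self.n_ssr else 0.0
        )
        object.__setattr__(
            self,
            "ssr_in_cssr_percent",
            100.0 * self.ccssr / self.n_ssr if self.n_ssr else 0.0,
        )


@dataclass(frozen=True)
class StudyConstants:
    """c' = mean members-per-compound, over genomes with >= 1 compound locus."""

    n_genomes: int
    c_prime: float


@dataclass(frozen=True)
class ZScoreResult:
    genome_id: str
    cssr_obs: int
    cssr_exp: float
    z: float | None     # None when E = 0 (flagged, not zero)


def summarize_genome(
    seq: SequenceRecord,
    ssrs: Sequence[SSRRecord],
    cssrs: Sequence[CompoundSSR],
) -> GenomeSummary:
    return GenomeSummary(
        genome_id=seq.id,
        genome_len=seq.length,
        gc_fraction=seq.gc_fraction,
        n_ssr=len(ssrs),
        n_cssr=len(cssrs),
        ccssr=ccssr_count(cssrs),
        ssr_bp=sum(s.tract_len for s in ssrs),
        cssr_bp=sum(c.span_len for c in cssrs),
    )


def study_constants(summaries: Sequence[GenomeSummary]) -> StudyConstants:
    """Cohort constant c'; genomes without compound loci are excluded."""
    ratios = [s.ccssr / s.n_cssr for s in summaries if s.n_cssr > 0]
    if not ratios:
        raise ComputationError("no genome in the cohort has a compound SSR")
    return StudyConstants(n_genomes=len(ratios), c_prime=sum(ratios) / len(ratios))


def zscores(
    summaries: Sequence[GenomeSummary], constants: StudyConstants
) -> list[ZScoreResult]:
    """Observed-vs-expected compound incidence per genome.

    E = CcSSR / c'; z = (O - E)/sqrt(E). Genomes with CcSSR = 0 get a
    flagged result (z = None) rather than a number.
    """
    out = []
    for s in summaries:
        exp = s.ccssr / constants.c_prime
        z = (s.n_cssr - exp) / math.sqrt(exp) if exp > 0 else None
        out.append(ZScoreResult(genome_id=s.genome_id, cssr_obs=s.n_cssr, cssr_exp=exp, z=z))
    return out


def regress(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """OLS of y on x: (R^2, slope, p-value of the slope)."""
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("regress needs equal-length vectors with n >= 3")
    if len(set(map(float, x))) == 1:
        raise ComputationError("zero variance in x")
    res = stats.linregress(x, y)
    return res.rvalue ** 2, res.slope, res.pvalue
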