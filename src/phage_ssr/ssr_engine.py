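"""Perfect microsatellite (SSR) detection.

A simple sequence repeat here is a maximal perfect tandem tract of an
aperiodic motif of 1-6 bp carrying at least a threshold number of whole
copies: 6 for mononucleotides and 3 for di- through hexanucleotides by
default (the standard perfect-mode mining thresholds for small viral
genomes). Partial trailing copies never count, tracts never contain N, and
a tract is reported only at its minimal period (ATATAT is (AT)3, never
(ATAT)1.5 nor (ATAT)2 of a periodic motif).

Motifs are grouped into rotation classes for composition summaries: the
class representative is the lexicographically smallest cyclic rotation
(GC -> CG, GGC -> CGG). Reverse complements are deliberately NOT merged,
so C and G mononucleotide runs stay distinct classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .sequence_io import SequenceRecord

DEFAULT_MIN_ITERATIONS: Mapping[int, int] = {1: 6, 2: 3, 3: 3, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class SSRParams:
    """Detection thresholds: minimum whole-copy count per motif length."""

    min_iterations: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_ITERATIONS)
    )
    max_motif_len: int = 6

    def __post_init__(self) -> None:
        ks = sorted(self.min_iterations)
        if ks != list(range(1, self.max_motif_len + 1)):
            raise ValueError("min_iterations must cover motif lengths 1..max_motif_len")
        if any(v < 2 for v in self.min_iterations.values()):
            raise ValueError("every minimum iteration count must be >= 2")


@dataclass(frozen=True)
class SSRRecord:
    """One perfect repeat tract; coordinates are 1-based inclusive."""

    genome_id: str
    motif: str
    motif_len: int
    iterations: int
    start: int
    end: int
    tract_len: int

    def __post_init__(self) -> None:
        assert self.tract_len == self.iterations * self.motif_len
        assert self.end - self.start + 1 == self.tract_len


def is_aperiodic(motif: str) -> bool:
    """True iff the motif is not a whole-number repetition of a shorter string."""
    k = len(motif)
    for p in range(1, k):
        if k % p == 0 and motif == motif[:p] * (k // p):
            return False
    return True


def canonical_motif_class(motif: str) -> str:
    """Lexicographically smallest cyclic rotation of an aperiodic 1-6 bp motif."""
    if not 1 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 1-6, got {motif!r}")
    if not is_aperiodic(motif):
        raise ValueError(f"motif {motif!r} is periodic")
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def find_ssrs(seq: SequenceRecord, params: SSRParams | None = None) -> list[SSRRecord]:
    """Return every maximal perfect tandem tract meeting the thresholds.

    For each period k the sequence is compared against itself shifted by k;
    a maximal run of m matches certifies a perfect region of m + k bases.
    Whole copies = (m + k) // k; the motif is the region's first k bases and
    must be aperiodic (otherwise the same tract is found at its minimal
    period). N never matches anything, so N both breaks runs and is excluded
    from tracts. Output is sorted by start, then motif length.
    """
    params = params or SSRParams()
    s = seq.seq
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    not_n = arr != ord("N")
    records: list[SSRRecord] = []
    for k in range(1, params.max_motif_len + 1):
        thr = params.min_iterations[k]
        if len(arr) < k * thr:
            continue
        eq = (arr[k:] == arr[:-k]) & not_n[k:] & not_n[:-k]
        if not eq.any():
            continue
        # run-length encode the boolean match vector
        padded = np.concatenate(([False], eq, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        starts, ends = edges[::2], edges[1::2]  # eq[a:b] all True
        keep = ends - starts >= k * (thr - 1)  # (m + k) // k >= thr
        for a, b in zip(starts[keep].tolist(), ends[keep].tolist()):
            m = b - a
            iterations = (m + k) // k
            motif = s[a : a + k]
            if not is_aperiodic(motif):
                continue
            records.append(
                SSRRecord(
                    genome_id=seq.id,
                    motif=motif,
                    motif_len=k,
                    iterations=iterations,
                    start=a + 1,
                    end=a + iterations * k,
                    tract_len=iterations * k,
                )
            )
    records.sort(key=lambda r: (r.start, r.motif_len))
    return records


def motif_summary(ssrs: Iterable[SSRRecord]) -> pd.DataFrame:
    """Per-class census: (motif_len, motif_class, count, max_iterations).

    Counts partition the input; max_iterations is the longest run observed
    for any rotation in the class.
    """
    rows: dict[tuple[int, str], list[int]] = {}
    for ssr in ssrs:
        key = (ssr.motif_len, canonical_motif_class(ssr.motif))
        entry = rows.setdefault(key, [0, 0])
        entry[0] += 1
        entry[1] = max(entry[1], ssr.iterations)
    df = pd.DataFrame(
        [
            {"motif_len": k, "motif_class": cls, "count": c, "max_iterations": mx}
            for (k, cls), (c, mx) in sorted(rows.items())
        ],
        columns=["motif_len", "motif_class", "count", "max_iterations"],
    )
    return df
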