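"""Synthetic phage genomes with planted, exhaustively known repeat content.

The generator emulates the cohort this pipeline targets: 40-112 kb genomes
with GC content 0.50-0.70, an iid per-base background, non-overlapping CDS
intervals covering a target coding fraction, and planted perfect repeats of
chosen motif, copy number and region. With ``scrub=True`` the background is
resampled wherever it spontaneously contains a qualifying repeat, so the
planted list is the *exhaustive* ground truth and detector recovery can be
asserted exactly rather than probabilistically.

``brute_force_ssr_oracle`` is an independent naive reference detector
(every start, every period, O(L * k * run)) used to verify the production
scanner; it shares no code path with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import GenerationError
from .sequence_io import AnnotationTable, CdsInterval, SequenceRecord
from .ssr_engine import SSRParams, SSRRecord, find_ssrs, is_aperiodic

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantSpec:
    """One repeat to plant: motif, copies, position (1-based or "auto"),
    and the region constraint (coding / non-coding / any)."""

    motif: str
    iterations: int
    position: int | str = "auto"
    region: str = "any"

    def __post_init__(self) -> None:
        if not (1 <= len(self.motif) <= 6) or not is_aperiodic(self.motif):
            raise GenerationError(f"motif {self.motif!r} must be aperiodic, 1-6 bp")
        if set(self.motif) - set("ACGT"):
            raise GenerationError(f"motif {self.motif!r} has non-ACGT residues")
        if self.region not in {"coding", "non-coding", "any"}:
            raise GenerationError(f"unknown region {self.region!r}")

    @property
    def tract_len(self) -> int:
        return len(self.motif) * self.iterations


@dataclass(frozen=True)
class SyntheticTruth:
    genome: SequenceRecord
    annotation: AnnotationTable | None
    planted: tuple[SSRRecord, ...]
    expected_cssrs_at_dmax: dict[int, int] = field(default_factory=dict)


def generate_genome(
    length: int, gc: float, seed: int, genome_id: str = "synthetic"
) -> SequenceRecord:
    """iid background genome with P(G) = P(C) = gc/2."""
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not 0 < gc < 1:
        raise ValueError("gc must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(_BASES, size=length, p=p)
    return SequenceRecord(id=genome_id, seq=draws.tobytes().decode("ascii"))


def expected_compound_counts(
    planted: Sequence[SSRRecord], dmax_values: Iterable[int]
) -> dict[int, int]:
    """Number of compound loci implied by planted coordinates under the
    gap <= dmax chaining rule, for each dmax. Generator-side arithmetic,
    independent of the cssr engine."""
    tracts = sorted(((p.start, p.end) for p in planted))
    out = {}
    for d in dmax_values:
        n, size, max_end = 0, 0, None
        for s, e in tracts:
            if max_end is not None and s - max_end - 1 <= d:
                size += 1
                max_end = max(max_end, e)
            else:
                if size >= 2:
                    n += 1
                size, max_end = 1, e
        if size >= 2:
            n += 1
        out[int(d)] = n
    return out


def _free_intervals(length: int, annotation: AnnotationTable | None, region: str):
    """0-based half-open intervals where a tract with the given region
    constraint may be placed."""
    if region == "any" or annotation is None:
        return [(0, length)]
    coding = [(c.start - 1, c.end) for c in annotation.intervals]
    if region == "coding":
        return coding
    out, pos = [], 0
    for s, e in coding:
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        out.append((pos, length))
    return out


def plant_repeats(
    seq: SequenceRecord,
    specs: Sequence[PlantSpec],
    scrub: bool = True,
    seed: int = 0,
    annotation: AnnotationTable | None = None,
    params: SSRParams | None = None,
    dmax_values: Iterable[int] = (0, 10, 20, 30, 40, 50),
    max_scrub_rounds: int = 1000,
) -> SyntheticTruth:
    """Write the requested repeats into the genome and (optionally) scrub
    every spontaneous background repeat, making the planted list exhaustive.

    Auto-placed tracts keep a repeat-free buffer of 6 x max(iterations)
    bases from every other planted tract; explicitly positioned tracts may
    sit arbitrarily close (compound layouts need gap 0) but never overlap.
    """
    params = params or SSRParams()
    rng = np.random.default_rng(seed)
    for sp in specs:
        if sp.iterations < params.min_iterations[len(sp.motif)]:
            raise GenerationError(
                f"{sp.motif!r} x{sp.iterations} is below the detection threshold"
            )
    chars = bytearray(seq.seq, "ascii")
    length = len(chars)
    placed: list[tuple[int, int, PlantSpec]] = []  # 0-based half-open

    def overlaps(a: int, b: int, margin: int = 0) -> bool:
        return any(a - margin < e and s < b + margin for s, e, _ in placed)

    buffer = 6 * max((sp.iterations for sp in specs), default=0)
    for sp in specs:  # explicit positions first
        if sp.position == "auto":
            continue
        a = int(sp.position) - 1
        b = a + sp.tract_len
        if a < 0 or b > length or overlaps(a, b):
            raise GenerationError(f"cannot place {sp.motif!r} at {sp.position}")
        placed.append((a, b, sp))
    for sp in specs:
        if sp.position != "auto":
            continue
        slots = [
            (s, e) for s, e in _free_intervals(length, annotation, sp.region)
            if e - s >= sp.tract_len
        ]
        if not slots:
            raise GenerationError(f"no room for {sp.motif!r} in region {sp.region!r}")
        for _ in range(1000):
            s, e = slots[rng.integers(len(slots))]
            a = int(rng.integers(s, e - sp.tract_len + 1))
            b = a + sp.tract_len
            if not overlaps(a, b, margin=buffer):
                placed.append((a, b, sp))
                break
        else:
            raise GenerationError(f"cannot place {sp.motif!r} without overlap")
    for a, b, sp in placed:
        chars[a:b] = (sp.motif * sp.iterations).encode("ascii")

    planted = tuple(
        sorted(
            (
                SSRRecord(
                    genome_id=seq.id,
                    motif=sp.motif,
                    motif_len=len(sp.motif),
                    iterations=sp.iterations,
                    start=a + 1,
                    end=b,
                    tract_len=b - a,
                )
                for a, b, sp in placed
            ),
            key=lambda r: (r.start, r.motif_len),
        )
    )
    protected = np.zeros(length, dtype=bool)
    for a, b, _ in placed:
        protected[a:b] = True

    gc = seq.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    planted_keys = {(p.start, p.end, p.motif) for p in planted}
    if scrub:
        for _ in range(max_scrub_rounds):
            genome = SequenceRecord(id=seq.id, seq=chars.decode("ascii"))
            extras = [
                d for d in find_ssrs(genome, params)
                if (d.start, d.end, d.motif) not in planted_keys
            ]
            if not extras:
                break
            progressed = False
            for d in extras:
                lo, hi = max(0, d.start - 2), min(length, d.end + 1)
                idx = np.flatnonzero(~protected[lo:hi]) + lo
                if idx.size == 0:
                    continue  # spurious repeat wholly inside planted bases
                chars_arr = rng.choice(_BASES, size=idx.size, p=probs)
                for i, c in zip(idx, chars_arr):
                    chars[i] = c
                progressed = True
            if not progressed:
                raise GenerationError(
                    "spontaneous repeat inside planted bases cannot be scrubbed"
                )
        else:
            raise GenerationError("scrubbing did not converge")

    genome = SequenceRecord(id=seq.id, seq=chars.decode("ascii"))
    return SyntheticTruth(
        genome=genome,
        annotation=annotation,
        planted=planted,
        expected_cssrs_at_dmax=expected_compound_counts(planted, dmax_values),
    )


def generate_annotation(
    length: int,
    n_cds: int,
    coding_fraction_target: float,
    seed: int,
    genome_id: str = "synthetic",
) -> AnnotationTable:
    """n_cds non-overlapping intervals covering coding_fraction_target of
    the genome (construction is exact up to integer rounding)."""
    if not 0 < coding_fraction_target <= 1:
        raise GenerationError("coding_fraction_target must be in (0, 1]")
    coding_bp = round(coding_fraction_target * length)
    if n_cds < 1 or coding_bp < n_cds:
        raise GenerationError(
            f"cannot cover {coding_bp} bp with {n_cds} non-empty intervals"
        )
    rng = np.random.default_rng(seed)

    def _split(total: int, parts: int, min_part: int) -> np.ndarray:
        if parts == 0:
            return np.array([], dtype=int)
        w = rng.dirichlet(np.full(parts, 5.0))
        sizes = np.maximum(np.floor(w * (total - parts * min_part)).astype(int), 0) + min_part
        sizes[0] += total - sizes.sum()  # fix rounding drift
        return sizes

    cds_sizes = _split(coding_bp, n_cds, 1)
    gap_sizes = _split(length - coding_bp, n_cds + 1, 0)
    intervals, pos = [], 0
    for i in range(n_cds):
        pos += int(gap_sizes[i])
        start = pos + 1
        pos += int(cds_sizes[i])
        strand = "+" if rng.random() < 0.5 else "-"
        intervals.append(CdsInterval(label=f"gp{i + 1}", start=start, end=pos, strand=strand))
    return AnnotationTable(genome_id=genome_id, intervals=tuple(intervals))


# Motif pool for cohort simulation, GC-biased like the phage genomes this
# emulates. Every motif is aperiodic and its pure tandem tract contains no
# other qualifying repeat, so planted truth stays exhaustive after scrubbing.
_COHORT_MOTIFS: dict[int, tuple[str, ...]] = {
    1: ("C", "G", "C", "G", "T", "A"),  # duplicates bias the draw toward G/C
    2: ("CG", "GC", "GT", "TG", "CT", "TC", "AC", "AG"),
    3: ("CGG", "GGC", "GCC", "AGC", "ACG", "AAG"),
    4: ("GCCA", "ACGG"),
    5: ("GCACG",),
    6: ("GCATCG",),
}
_COHORT_K_WEIGHTS = {1: 0.25, 2: 0.45, 3: 0.22, 4: 0.05, 5: 0.01, 6: 0.02}


def _layout_loci(
    length: int,
    annotation: AnnotationTable,
    rng: np.random.Generator,
    rate_per_kb: float,
    cluster_prob: float,
    coding_prob: float,
    params: SSRParams,
) -> list[PlantSpec]:
    """Sample explicit plant positions: isolated loci and occasional 2-3
    member clusters (gaps 1-9 bp), >= 60 bp apart so independent loci never
    chain even at dMAX 50."""
    n_loci = max(1, round(length / 1000 * rate_per_kb))
    occupied: list[tuple[int, int]] = []  # 0-based half-open, buffer included
    specs: list[PlantSpec] = []
    ks = sorted(_COHORT_K_WEIGHTS)
    kw = np.array([_COHORT_K_WEIGHTS[k] for k in ks])
    kw = kw / kw.sum()

    def draw_motifs() -> list[tuple[str, int]]:
        size = 1
        if rng.random() < cluster_prob:
            size = int(rng.integers(2, 4))
        out = []
        for _ in range(size):
            k = int(rng.choice(ks, p=kw))
            motif = _COHORT_MOTIFS[k][rng.integers(len(_COHORT_MOTIFS[k]))]
            lo = params.min_iterations[k]
            hi = {1: 12, 2: 9, 3: 9, 4: 5, 5: 4, 6: 4}[k]
            out.append((motif, int(rng.integers(lo, hi + 1))))
        return out

    placed = 0
    for _ in range(n_loci * 30):
        if placed >= n_loci:
            break
        members = draw_motifs()
        gaps = [int(rng.integers(1, 10)) for _ in members[1:]]
        span = sum(len(m) * it for m, it in members) + sum(gaps)
        region = "coding" if rng.random() < coding_prob else "non-coding"
        slots = [
            (s, e) for s, e in _free_intervals(length, annotation, region)
            if e - s >= span
        ]
        if not slots:
            continue
        s, e = slots[rng.integers(len(slots))]
        a = int(rng.integers(s, e - span + 1))
        b = a + span
        if any(a - 60 < oe and os < b + 60 for os, oe in occupied):
            continue
        pos = a
        for (motif, it), gap in zip(members, gaps + [0]):
            specs.append(PlantSpec(motif=motif, iterations=it, position=pos + 1, region=region))
            pos += len(motif) * it + gap
        occupied.append((a, b))
        placed += 1
    return specs


def generate_cohort(
    n_genomes: int = 20,
    seed: int = 0,
    length_range: tuple[int, int] = (42_000, 112_000),
    gc_range: tuple[float, float] = (0.50, 0.69),
    coding_fraction: float = 0.78,
    rate_per_kb: float = 2.0,
    cluster_prob: float = 0.12,
    params: SSRParams | None = None,
) -> list[SyntheticTruth]:
    """A phage-like study cohort with exhaustive planted ground truth.

    Defaults emulate the target study conditions: 42-112 kb genomes, GC
    0.50-0.69, CDS covering ~78% of each genome, roughly 2 planted repeats
    per kb with ~12% of loci forming compound clusters, and each repeat
    placed in a coding region with probability equal to the coding
    fraction.
    """
    params = params or SSRParams()
    rng = np.random.default_rng(seed)
    truths = []
    for i in range(n_genomes):
        sub = rng.integers(2**31, size=4)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        gc = float(rng.uniform(*gc_range))
        gid = f"SYN{i + 1:03d}"
        annotation = generate_annotation(
            length, int(rng.integers(50, 91)), coding_fraction, int(sub[0]), genome_id=gid
        )
        genome = generate_genome(length, gc, int(sub[1]), genome_id=gid)
        local = np.random.default_rng(int(sub[2]))
        specs = _layout_loci(
            length, annotation, local, rate_per_kb, cluster_prob, coding_fraction, params
        )
        truths.append(
            plant_repeats(
                genome, specs, scrub=True, seed=int(sub[3]),
                annotation=annotation, params=params,
            )
        )
    return truths


def brute_force_ssr_oracle(
    seq: SequenceRecord, params: SSRParams | None = None
) -> list[SSRRecord]:
    """Exhaustive reference detector: every start, every period 1-6,
    extend maximally, keep left-maximal aperiodic tracts over threshold.
    Intended for sequences up to ~10 kb."""
    params = params or SSRParams()
    s = seq.seq
    L = len(s)

    def eq(a: str, b: str) -> bool:
        return a == b and a != "N"

    found = {}
    for p in range(1, params.max_motif_len + 1):
        thr = params.min_iterations[p]
        for start in range(L - p * thr + 1):
            if start > 0 and eq(s[start - 1], s[start - 1 + p]):
                continue  # extendable left: not the run's first start
            t = p
            while start + t < L and eq(s[start + t], s[start + t - p]):
                t += 1
            iterations = t // p
            if iterations < thr:
                continue
            motif = s[start : start + p]
            if "N" in motif:
                continue
            if motif in (motif + motif)[1:-1]:
                continue  # periodic motif: reported at its minimal period
            key = (start + 1, start + iterations * p, motif)
            found[key] = SSRRecord(
                genome_id=seq.id,
                motif=motif,
                motif_len=p,
                iterations=iterations,
                start=start + 1,
                end=start + iterations * p,
                tract_len=iterations * p,
            )
    return sorted(found.values(), key=lambda r: (r.start, r.motif_len))
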