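"""End-to-end survey: extract -> compound -> annotate -> stats -> host range.

Emits one directory of TSV tables plus a JSON manifest recording the
parameters, package version and input checksums. A rerun with the same
config produces byte-identical tables (no timestamps; floats rounded to 2
decimals at serialization only).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .annotation_overlap import classify_ssrs
from .cssr_engine import CssrParams, build_cssrs, dmax_sweep
from .errors import ComputationError
from .host_range import compare_groups, group_composition
from .sequence_io import AnnotationTable, read_fasta, read_genbank_features
from .ssr_engine import SSRParams, SSRRecord, find_ssrs, motif_summary
from .summary_stats import study_constants, summarize_genome, zscores

logger = logging.getLogger(__name__)

TABLES = (
    "ssr.tsv",
    "cssr.tsv",
    "labeled.tsv",
    "summary.tsv",
    "motif_summary.tsv",
    "sweep.tsv",
    "hostrange.tsv",
)


@dataclass
class RunConfig:
    fasta: Path
    outdir: Path
    genbank: Mapping[str, Path] = field(default_factory=dict)  # genome_id -> file
    ssr_params: SSRParams = field(default_factory=SSRParams)
    cssr_params: CssrParams = field(default_factory=CssrParams)
    dmax_values: Sequence[int] = (0, 10, 20, 30, 40, 50)
    groups: Mapping[str, str] | None = None  # genome_id -> group label
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.fasta = Path(self.fasta)
        self.outdir = Path(self.outdir)
        if not self.fasta.exists():
            raise FileNotFoundError(self.fasta)
        for gid, p in self.genbank.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"{gid}: {p}")
        if any(not 0 <= d <= 50 for d in self.dmax_values):
            raise ValueError("dmax values must lie in [0, 50]")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _round(v, nd=2):
    return round(v, nd) if isinstance(v, float) else v


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(2)
    out.to_csv(path, sep="\t", index=False)


def read_ssr_table(path: Path | str) -> dict[str, list[SSRRecord]]:
    """Load a ssr.tsv written by this pipeline, keyed by genome."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[SSRRecord]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.genome_id), []).append(
            SSRRecord(
                genome_id=str(row.genome_id),
                motif=str(row.motif),
                motif_len=int(row.motif_len),
                iterations=int(row.iterations),
                start=int(row.start),
                end=int(row.end),
                tract_len=int(row.tract_len),
            )
        )
    return out


def run_survey(config: RunConfig) -> Path:
    """Run the full survey; returns the output directory.

    On any stage failure the partially written tables are removed and the
    error re-raised.
    """
    logging.basicConfig(level=config.log_level)
    config.outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        return _run(config, created)
    except Exception:
        for p in created:
            p.unlink(missing_ok=True)
        raise


def _run(config: RunConfig, created: list[Path]) -> Path:
    genomes = read_fasta(config.fasta)
    annotations: dict[str, AnnotationTable] = {
        gid: read_genbank_features(path) for gid, path in config.genbank.items()
    }

    ssr_rows, cssr_rows, labeled_rows, summary_rows, sweep_rows = [], [], [], [], []
    all_ssrs: list[SSRRecord] = []
    ssrs_by_genome: dict[str, list[SSRRecord]] = {}
    summaries = []
    for genome in genomes:
        ssrs = find_ssrs(genome, config.ssr_params)
        cssrs, _ = build_cssrs(ssrs, config.cssr_params)
        ssrs_by_genome[genome.id] = ssrs
        all_ssrs.extend(ssrs)
        region_of: dict[tuple[int, int, str], tuple[str, str, int]] = {}
        if genome.id in annotations:
            labels = classify_ssrs(ssrs, annotations[genome.id], genome_len=genome.length)
            for lab in labels:
                region_of[(lab.ssr.start, lab.ssr.end, lab.ssr.motif)] = (
                    lab.label,
                    lab.cds_label,
                    lab.overlap_bp,
                )
                labeled_rows.append(
                    {
                        "genome_id": genome.id,
                        "motif": lab.ssr.motif,
                        "start": lab.ssr.start,
                        "end": lab.ssr.end,
                        "label": lab.label,
                        "cds_label": lab.cds_label,
                        "overlap_bp": lab.overlap_bp,
                    }
                )
        for ssr in ssrs:
            region = region_of.get((ssr.start, ssr.end, ssr.motif), ("", "", 0))
            ssr_rows.append(
                {
                    "genome_id": genome.id,
                    "motif": ssr.motif,
                    "motif_len": ssr.motif_len,
                    "iterations": ssr.iterations,
                    "start": ssr.start,
                    "end": ssr.end,
                    "tract_len": ssr.tract_len,
                    "region_label": region[0],
                }
            )
        for ci, cssr in enumerate(cssrs, start=1):
            gaps = (None,) + cssr.gaps
            for mi, member in enumerate(cssr.members):
                cssr_rows.append(
                    {
                        "genome_id": genome.id,
                        "cssr_id": ci,
                        "cssr_class": cssr.cssr_class,
                        "cssr_start": cssr.start,
                        "cssr_end": cssr.end,
                        "span_len": cssr.span_len,
                        "n_members": cssr.n_members,
                        "member_index": mi + 1,
                        "motif": member.motif,
                        "member_start": member.start,
                        "member_end": member.end,
                        "gap_to_prev": "" if gaps[mi] is None else gaps[mi],
                    }
                )
        for row in dmax_sweep(ssrs, config.dmax_values).to_dict("records"):
            sweep_rows.append({"genome_id": genome.id, **row})
        summaries.append(summarize_genome(genome, ssrs, cssrs))

    try:
        constants = study_constants(summaries)
        zs = {z.genome_id: z for z in zscores(summaries, constants)}
        c_prime = constants.c_prime
    except ComputationError:
        logger.warning("no compound SSRs anywhere in the cohort; z-scores omitted")
        constants, zs, c_prime = None, {}, None
    for s in summaries:
        z = zs.get(s.genome_id)
        row = dataclasses.asdict(s)
        row["cssr_exp"] = _round(z.cssr_exp) if z else ""
        row["z"] = _round(z.z) if z and z.z is not None else ""
        row["gc_fraction"] = round(row["gc_fraction"], 4)
        for k in ("ra", "rd", "cra", "crd", "cssr_percent", "ssr_in_cssr_percent"):
            row[k] = _round(row[k])
        summary_rows.append(row)

    hostrange_rows, chi_results = [], {}
    if config.groups:
        for k in (1, 2):
            comps = group_composition(ssrs_by_genome, config.groups, k)
            for comp in comps:
                for cls in sorted(comp.counts):
                    hostrange_rows.append(
                        {
                            "k": k,
                            "group_id": comp.group_id,
                            "motif_class": cls,
                            "count": comp.counts[cls],
                            "percent": round(comp.percents[cls], 2),
                        }
                    )
            nonempty = [c for c in comps if c.total > 0]
            if len(nonempty) == 2:
                try:
                    result, classes = compare_groups(*nonempty)
                    chi_results[f"k{k}"] = {
                        "statistic": round(result.statistic, 4),
                        "df": result.df,
                        "p_value": result.p_value,
                        "classes": classes,
                    }
                except ComputationError as exc:
                    chi_results[f"k{k}"] = {"error": str(exc)}

    out = config.outdir
    frames = {
        "ssr.tsv": pd.DataFrame(
            ssr_rows,
            columns=["genome_id", "motif", "motif_len", "iterations", "start", "end",
                     "tract_len", "region_label"],
        ),
        "cssr.tsv": pd.DataFrame(
            cssr_rows,
            columns=["genome_id", "cssr_id", "cssr_class", "cssr_start", "cssr_end",
                     "span_len", "n_members", "member_index", "motif", "member_start",
                     "member_end", "gap_to_prev"],
        ),
        "labeled.tsv": pd.DataFrame(
            labeled_rows,
            columns=["genome_id", "motif", "start", "end", "label", "cds_label", "overlap_bp"],
        ),
        "summary.tsv": pd.DataFrame(summary_rows),
        "motif_summary.tsv": motif_summary(all_ssrs),
        "sweep.tsv": pd.DataFrame(
            sweep_rows, columns=["genome_id", "dmax", "n_cssr", "cssr_percent"]
        ),
        "hostrange.tsv": pd.DataFrame(
            hostrange_rows, columns=["k", "group_id", "motif_class", "count", "percent"]
        ),
    }
    for name, df in frames.items():
        path = out / name
        created.append(path)
        _write_tsv(df, path)

    pct_coding = None
    if labeled_rows:
        n_coding = sum(1 for r in labeled_rows if r["label"] == "coding")
        pct_coding = round(100.0 * n_coding / len(labeled_rows), 2)
    manifest = {
        "version": __version__,
        "parameters": {
            "min_iterations": dict(config.ssr_params.min_iterations),
            "dmax": config.cssr_params.dmax,
            "dmax_sweep": list(map(int, config.dmax_values)),
        },
        "inputs": {
            "fasta": {"path": str(config.fasta), "sha256": _sha256(config.fasta)},
            "genbank": {
                gid: {"path": str(p), "sha256": _sha256(p)}
                for gid, p in config.genbank.items()
            },
        },
        "cohort": {
            "n_genomes": len(genomes),
            "n_ssr": sum(s.n_ssr for s in summaries),
            "n_cssr": sum(s.n_cssr for s in summaries),
            "ccssr": sum(s.ccssr for s in summaries),
            "c_prime": round(c_prime, 4) if c_prime is not None else None,
            "pct_coding": pct_coding,
        },
        "host_range_chi_square": chi_results,
    }
    manifest_path = out / "manifest.json"
    created.append(manifest_path)
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
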