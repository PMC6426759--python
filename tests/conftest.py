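from __future__ import annotations

from pathlib import Path

import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from phage_ssr import SequenceRecord, SSRRecord


def make_ssr(motif: str, iterations: int, start: int, genome_id: str = "g") -> SSRRecord:
    """Construct a consistent SSRRecord from motif, copies and 1-based start."""
    k = len(motif)
    return SSRRecord(
        genome_id=genome_id,
        motif=motif,
        motif_len=k,
        iterations=iterations,
        start=start,
        end=start + iterations * k - 1,
        tract_len=iterations * k,
    )


def write_genbank(
    path: Path,
    seq: str,
    features: list[tuple[int, int, int, dict]],
    record_id: str = "TESTGB",
) -> Path:
    """Write a minimal GenBank flat file.

    ``features`` entries are (start_1based, end_1based, strand, qualifiers).
    """
    rec = BioSeqRecord(Seq(seq), id=record_id, name=record_id, description="synthetic")
    rec.annotations["molecule_type"] = "DNA"
    for start, end, strand, quals in features:
        rec.features.append(
            SeqFeature(FeatureLocation(start - 1, end, strand=strand), type="CDS",
                       qualifiers={k: [v] for k, v in quals.items()})
        )
    SeqIO.write([rec], str(path), "genbank")
    return path


@pytest.fixture
def seqrec():
    def _make(s: str, identifier: str = "g") -> SequenceRecord:
        return SequenceRecord(id=identifier, seq=s)

    return _make


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Three scrubbed synthetic genomes (one with SSRs but no compound loci),
    written to disk as FASTA + GenBank, with their ground truths."""
    from phage_ssr import write_fasta
    from phage_ssr.synthetic_data import (
        PlantSpec,
        generate_annotation,
        generate_genome,
        plant_repeats,
    )

    root = tmp_path_factory.mktemp("cohort")
    truths = []
    layouts = [
        # genome A: two compound clusters + isolated repeats
        [PlantSpec("CG", 4, 2001), PlantSpec("GT", 5, 2012),
         PlantSpec("C", 7, 5000), PlantSpec("AAG", 4, 8000),
         PlantSpec("GC", 3, 8020), PlantSpec("ACG", 3, 12000)],
        # genome B: one cluster, a few singles
        [PlantSpec("TG", 6, 1500), PlantSpec("CGG", 3, 1520),
         PlantSpec("G", 8, 9000), PlantSpec("CT", 4, 11000)],
        # genome C: isolated SSRs only -> zero compound loci
        [PlantSpec("C", 6, 3000), PlantSpec("AG", 4, 6000), PlantSpec("GGC", 3, 9500)],
    ]
    fasta = root / "cohort.fasta"
    genbanks = {}
    records = []
    for i, specs in enumerate(layouts):
        gid = f"PH{i + 1}"
        ann = generate_annotation(15000, 12, 0.78, seed=40 + i, genome_id=gid)
        genome = generate_genome(15000, 0.60, seed=50 + i, genome_id=gid)
        truth = plant_repeats(genome, specs, scrub=True, seed=60 + i, annotation=ann)
        truths.append(truth)
        records.append(truth.genome)
        gb = root / f"{gid}.gb"
        write_genbank(
            gb, truth.genome.seq,
            [(c.start, c.end, 1 if c.strand == "+" else -1, {"gene": c.label})
             for c in ann.intervals],
            record_id=gid,
        )
        genbanks[gid] = gb
    write_fasta(records, fasta)
    return {"fasta": fasta, "genbank": genbanks, "truths": truths, "root": root}
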