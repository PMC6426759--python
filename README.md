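# phage-ssr

Perfect microsatellite (SSR) and compound-microsatellite (cSSR) survey
pipeline for bacteriophage-scale genomes.

Microsatellites — tandem repetitions of 1–6 bp motifs — are mutational
hotspots and markers of genome evolution, and in phage genomes their
placement relative to coding sequence and their clustering into compound
loci carry comparative-genomic signal. This package is for researchers who
want that survey reproducible end to end: detect perfect SSRs at the
standard thresholds, chain them into compound loci under a distance cutoff,
compute the abundance/density/significance statistics, place every repeat
in coding or non-coding sequence from a GenBank annotation, and compare
motif composition between genome groups — with a synthetic-genome module so
every stage can be verified against exhaustive planted ground truth.

## The model in brief

- **SSR**: a maximal perfect tandem tract of an aperiodic motif of length
  k ∈ {1..6}, with at least 6 whole copies for mononucleotides and 3 for
  longer motifs (defaults, configurable). Partial trailing copies never
  count; N breaks tracts.
- **cSSR**: ≥ 2 SSRs whose successive gaps are each ≤ dMAX (default 10 bp,
  range 0–50). Classes: compound (gap 0), interrupted-pure /
  interrupted-compound (interrupted pairs of same / different motif class),
  complex (≥ 3 members with an interruption).
- **Statistics**: relative abundance RA = SSRs/kb and relative density
  RD = SSR bp/kb (cRA, cRD for compound loci); the compound percentages
  100·cSSR/SSR and 100·CcSSR/SSR, where CcSSR counts SSRs inside compound
  loci; the cohort model c′ = (1/n)Σ CcSSRᵢ/cSSRᵢ, E = CcSSR/c′,
  z = (O − E)/√E; OLS regressions of SSR metrics on genome size and GC;
  Pearson chi-square on pooled motif-class counts between host-range
  groups.

See `docs/methods.md` for the full conventions (maximality, minimal
period, gap arithmetic, tie-breaking, degenerate inputs).

## Worked example

```python
from phage_ssr import (find_ssrs, build_cssrs, summarize_genome,
                       classify_ssrs, coding_fraction)
from phage_ssr.synthetic_data import (generate_genome, generate_annotation,
                                      plant_repeats, PlantSpec)

annotation = generate_annotation(50_000, n_cds=40, coding_fraction_target=0.78, seed=7)
background = generate_genome(50_000, gc=0.64, seed=7)
truth = plant_repeats(
    background,
    [PlantSpec("CG", 4, position=10_001), PlantSpec("GT", 5, position=10_012),
     PlantSpec("C", 7, region="coding"), PlantSpec("AAG", 4, region="non-coding")],
    scrub=True, seed=8, annotation=annotation,
)
ssrs = find_ssrs(truth.genome)
for s in ssrs:
    print(f"{s.motif:>4} x{s.iterations}  {s.start}-{s.end}")
cssrs, standalone = build_cssrs(ssrs)
print("compound loci:", [(c.cssr_class, c.start, c.end, c.gaps) for c in cssrs])
summary = summarize_genome(truth.genome, ssrs, cssrs)
print(f"RA={summary.ra:.2f}/kb  RD={summary.rd:.2f} bp/kb  cSSR%={summary.cssr_percent:.2f}")
pct, _ = coding_fraction(classify_ssrs(ssrs, annotation))
print(f"coding: {pct:.0f}%")
```

prints

```
  CG x4  10001-10008
  GT x5  10012-10021
 AAG x4  11206-11217
   C x7  35871-35877
compound loci: [('interrupted-compound', 10001, 10021, (3,))]
RA=0.08/kb  RD=0.74 bp/kb  cSSR%=25.00
coding: 75%
```

The four planted repeats are recovered exactly (the scrubbed background
contains nothing else). The CG and GT tracts, 3 bp apart, chain into one
interrupted-compound locus spanning 10001–10021; RA and RD are the per-kb
counts over the 50 kb genome; cSSR% = 1 compound locus / 4 SSRs; the C run
was planted inside a CDS and the AAG run outside, and with the CG/GT pair
landing in coding sequence 3 of 4 SSRs (75%) are coding.

## Command line

```sh
phage-ssr extract  --fasta genomes.fa --out ssr.tsv
phage-ssr compound --ssr ssr.tsv --dmax 10 --out cssr.tsv
phage-ssr sweep    --ssr ssr.tsv --dmax 10,20,30,40,50 --out sweep.tsv
phage-ssr annotate --ssr ssr.tsv --genbank genome.gb --out labeled.tsv
phage-ssr stats    --fasta genomes.fa --ssr ssr.tsv --out summary.tsv
phage-ssr hostrange --ssr ssr.tsv --groups groups.tsv --k 1 --out comparison.tsv
phage-ssr simulate --length 50000 --gc 0.64 --cds 80 --coding-frac 0.78 \
                   --seed 7 --out-prefix sim/genome
phage-ssr survey   --fasta genomes.fa --genbank ID=genome.gb --outdir out/
```

`survey` runs every stage and writes seven TSV tables plus a manifest with
parameters and input checksums; reruns are byte-identical.

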