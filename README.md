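# ataxmap

Positional-cloning toolkit for recessive Mendelian traits in pedigreed
populations. Given SNP-array genotypes for a small family, whole-genome
variant calls for an affected individual, and a panel of unrelated controls,
the pipeline narrows the genome to a critical interval and a short candidate
list in four classical steps:

1. **Parametric linkage** — exact two-point LOD scores per marker under a
   fully penetrant recessive model, computed by Elston–Stewart peeling on a
   loop-free family, and extraction of positively linked regions.
2. **Autozygosity mapping** — runs of homozygosity (ROH) per individual,
   intersected across affected individuals with a shared allele signature,
   minus every region in which any control is also homozygous.
3. **Variant filtering and annotation** — variants homozygous in the case and
   absent from all controls, restricted to the critical interval, annotated
   with transcript consequences (HGVS-like `c.`/`p.` notation) from a GFF3 +
   FASTA pair.
4. **Segregation testing** — genotype-by-phenotype table for the final
   candidate across the whole cohort, checked for perfect recessive
   co-segregation.

A gene-dropping simulator (`ataxmap simulate`) produces complete synthetic
datasets — pedigree, array genotypes with Haldane-model recombination, case
and control VCFs, genome FASTA, gene models, and a truth file — so the entire
pipeline is testable end-to-end against a known planted causal variant.

## Worked example

Simulate a dataset and run the full pipeline on it:

```sh
ataxmap simulate --seed 7 --out-dir data/
ataxmap run-all --data-dir data/ --out-dir run/
```

`run/report.json` then contains (numbers for seed 7 defaults: 5 chromosomes ×
400 markers, 600 controls):

- `critical_intervals` — the control-excluded, linkage-supported autozygous
  intervals; with zero genotyping error these normally contain the planted
  locus (recovered in ~17–20 of 20 replicates at defaults; see
  `docs/methods.md` for the failure mode).
- `candidates` — the private homozygous variants inside those intervals with
  their consequences; the planted variant appears as the sole missense
  candidate, e.g. `c.4898G>T` / `p.Gly1633Val` in the minus-strand target
  gene.
- `segregation` — the cohort genotype table with `"perfect": true` and zero
  discordant individuals.
- `funnel` — per-stage counts (private homozygous → in interval →
  intergenic/intronic/exonic).

Each stage is also available as its own subcommand operating on files, so the
workflow composes incrementally:

```sh
ataxmap qc      --ped data/array.ped --map data/array.map --out-dir qc/
ataxmap linkage --fam data/pedigree.fam --ped qc/qc.ped --map qc/qc.map --out-dir lk/
ataxmap roh     --ped qc/qc.ped --map qc/qc.map --out-dir roh/
# intersect linked regions with case-shared intervals (any BED of autozygous
# intervals shared by the affected individuals), optionally subtracting
# control ROH:
ataxmap map     --linked lk/linked_regions.bed --case-shared case_shared.bed \
                --control-roh control_roh.bed --out critical.bed
ataxmap filter-variants --case-vcf data/case.vcf --controls-vcf data/controls.vcf \
                --regions critical.bed --out private.tsv
ataxmap annotate --variants private.tsv --gff3 data/genes.gff3 \
                --fasta data/genome.fa --out candidates.tsv
ataxmap segregate --genotypes candidate_genotypes.tsv --fam data/pedigree.fam
```

(`roh.bed` is per-individual; split it by the name column to build the
case-shared and control BEDs, or use `run-all`, which performs the shared-
signature intersection and control exclusion internally and writes
`critical_regions.bed` directly.)

## Library use

```python
from ataxmap.simulate import SimulationConfig, simulate
from ataxmap.pipeline import run_on_dataset

ds = simulate(SimulationConfig(seed=7))
report = run_on_dataset(ds)
print(report.critical_intervals)
print(report.candidates)
```

Core modules: `pedigree` (structure, loops, kinship/inbreeding, Mendelian
checks, FAM I/O), `genotypes` (PED/MAP I/O, QC, allele frequencies),
`linkage` (two-locus peeling likelihood, LOD curves, linked regions),
`intervals` (closed 1-based interval algebra, BED I/O), `autozygosity` (exact
maximal-window ROH scan, shared-signature intersection, control exclusion),
`variants` (VCF/GFF3/FASTA handling, CDS mapping on both strands, protein
consequence), `segregation` (tables and the perfect-segregation test),
`simulate` (gene dropping with Haldane recombination and rejection
conditioning on the family structure).

## Conventions

- Genomic intervals are 1-based and closed internally; BED output is 0-based
  half-open.
- Genotypes are coded 0/1/2 (alternate-allele dosage) with −1 for missing.
- LOD at θ = 0.5 is identically zero by construction.

See `docs/methods.md` for the statistical model, parameter defaults, and
design decisions.
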