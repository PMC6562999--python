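# Methods

This document records the statistical model, the default parameters, and the
design decisions behind ataxmap. Everything here is implemented and tested in
the package; file references are to `src/ataxmap/`.

## 1. Two-locus pedigree likelihood (`linkage.py`)

### Model

Each individual carries an ordered pair of haplotypes, one paternal and one
maternal. A haplotype is a (disease allele, marker allele) pair over two
biallelic loci, giving 4 haplotypes and 16 ordered two-locus genotypes per
individual. The likelihood of the pedigree data at recombination fraction θ
is the standard parametric two-point linkage likelihood:

- **Founders** draw each haplotype independently from population frequencies
  under Hardy–Weinberg and linkage equilibrium: `P(h) = P(d) · P(m)`, with
  disease-allele frequency `q` (default 0.001) and marker allele frequencies
  estimated from genotyped founders (fallback 0.5 when no founder is
  genotyped, clamped to [1e−4, 1−1e−4]).
- **Transmission**: a parent passes one of its two haplotypes either intact
  (probability (1−θ)/2 each) or recombined (θ/2 each). The child's state is
  the product of the two parental transmission tensors.
- **Penetrance**: P(affected | disease dosage d) is a penetrance vector;
  the default is fully penetrant recessive (0, 0, 1). Unknown phenotypes
  contribute a factor of 1.
- **Marker data**: an individual's observed marker dosage (0/1/2, −1 missing)
  constrains its 16 states; missing calls constrain nothing.

The likelihood is evaluated exactly by Elston–Stewart peeling implemented as
generic variable elimination over one 16-state variable per individual, in
reverse topological order. Looped pedigrees are rejected with an explicit
error (see §7).

`LOD(θ) = log10 L(θ) − log10 L(0.5)`; the value at θ = 0.5 is set to exactly
0.0 rather than computed, since the two loci factorize there. The default θ
grid is (0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5).

### Correctness oracle

The peeling likelihood is checked against a brute-force enumeration over all
per-individual ordered two-locus genotypes (with zero-probability pruning) on
hundreds of random loop-free pedigrees; agreement is within 1e−9 log10 units
(observed ~1e−15). Because the transmission tensor has no zeros for
θ ∈ (0, 0.5), the enumeration cannot prune below the product of per-member
admissible state counts; random pedigrees are resampled when that product
exceeds 200,000 so the reference evaluation stays tractable.

### Linked regions

Markers are classified per chromosome, in map order:

- **supporting**: max LOD over the grid > 1e−6;
- **anti-linked**: max LOD ≤ 1e−6 *and* LOD at the smallest θ < −1e−6
  (evidence against linkage);
- **uninformative**: LOD identically ~0 (e.g. both parents homozygous).

A linked region is a maximal run of markers containing no anti-linked marker
and at least one supporting marker; its interval spans the outermost
supporting markers. Rationale: under two-point analysis a large fraction of
markers inside a truly linked region are individually uninformative, and
breaking runs at them would fragment every real signal; uninformative markers
are therefore neutral, while any marker with net evidence against linkage
splits the run (a `+ + − +` sign pattern yields two regions).

**Known limitation.** With a single nuclear family (~10 meioses), a marker
whose only informative meiosis happens to be a recombinant gets an
everywhere-non-positive LOD curve and splits the linked run even when it lies
next to the true locus. On default simulations this causes the final interval
list to miss the planted locus in roughly 1–3 of 20 replicates. A classical
remedy is to split only at strong exclusion evidence (LOD ≤ −2); the package
keeps the stricter sign-split rule as its defined semantics and documents the
recovery rate instead.

## 2. Runs of homozygosity (`autozygosity.py`)

ROH detection is an exact maximal-window scan, not a heuristic sliding
window. A window [i, j] over one individual's calls on one chromosome is
admissible when calls i and j are homozygous and it contains at most
`max_het` heterozygous (default 1) and `max_missing` missing (default 2)
calls. Using prefix sums and a monotone two-pointer sweep, the detector emits
every *maximal* admissible window (one per distinct greedy right endpoint),
then filters by `min_markers` (default 20) and `min_length_bp`
(default 500,000). The test suite checks segment-for-segment equality against
an independent quadratic reference scan on random matrices, including
50 × 5,000 cases.

### Case-shared intervals and control exclusion

Case ROH segments are intersected across all affected individuals and then
split wherever two cases are homozygous for *opposite* alleles; missing calls
are compatible with any signature. Control exclusion is **allele-blind** by
default: every region covered by any control's ROH is subtracted, the
stricter rule. An **allele-aware** mode (subtract only when the
control's homozygous signature matches the case signature) is available
behind a flag (`exclude_control_homozygosity(..., allele_aware=True)`).
Fragments below `min_length_bp` are dropped. Critical regions are the
intersection of the surviving case intervals with the linked regions, each
reported with its marker count and peak LOD.

## 3. Variants and consequences (`variants.py`)

- VCF input via cyvcf2; multiallelic records are decomposed into biallelic
  ALT rows. The private-variant filter keeps variants homozygous-alternate in
  the case and absent from all controls, flagging `controls_missing:<n>` and
  `not_in_controls` where coverage is incomplete.
- Transcript models come from GFF3 (via gffutils). CDS coordinate mapping
  supports both strands; on the minus strand genomic ref/alt are
  reverse-complemented into coding ref/alt (a genomic C>A becomes a coding
  G>T). Codon index is `(cds_pos + 2) // 3`.
- Consequence classes: nonsense > missense > synonymous; indels and
  non-coding positions are reported as located (intergenic / intronic / UTR)
  but `unsupported` for protein prediction. Notation is HGVS-like
  (`c.4898G>T`, `p.Gly1633Val`).

## 4. Segregation (`segregation.py`)

`tabulate` builds an affected / non-affected × hom-ref / het / hom-alt count
table (unknown phenotypes and missing genotypes excluded).
`perfect_segregation` checks the table against a penetrance vector: under
full recessive penetrance, every affected must be homozygous-alternate and no
non-affected may be; the discordant count is reported.

## 5. Simulator (`simulate.py`)

The default pedigree is a two-litter family with a marriage/inbreeding loop:
one sire (`AD149`) produced litter 1 with a dam who later produced litter 2
with that sire's son (`AD180`), and all three breeding animals trace to a
common founder carrying the causal haplotype.

Gene dropping: founder chromosomes are labelled haplotypes; each meiosis
draws crossover counts from a Poisson process under the Haldane model
(default 1 cM/Mb) and recombines parental haplotypes piecewise. Genotypes at
markers, background variants, and the planted causal variant are read off
the founder-origin mosaics, so marker LD with the causal locus arises
physically rather than being imposed.

The drop is conditioned by rejection sampling (causal chromosome only, since
chromosomes are independent): all three breeding parents are carriers, no
breeding ancestor is homozygous for the causal allele, and each litter
contains at least two affected pups. The planted variant is a minus-strand
missense at CDS position 4898 (codon 1633, Gly→Val). An error model applies
independent allele flips (default rate 0.001) and missingness
(default 0.005) to the array genotypes.

Defaults: 5 chromosomes × 12 Mb, 400 markers per chromosome, 600 unrelated
controls, background variants every 50 kb. Everything is deterministic given
the config seed; written files are byte-stable.

## 6. Pipeline (`pipeline.py`)

Stages: validate pedigree → QC (markers filtered before individuals, both
call-rate thresholds default 0.9; one pass, see below) → select the largest
fully genotyped loop-free nuclear family containing an affected child →
two-point LOD scan on that family → linked regions → ROH for all genotyped
individuals → case-shared intervals → control exclusion → intersection with
linked regions → private homozygous variant filter → restriction to critical
intervals → consequence annotation → segregation test of the top candidate.
The report echoes all parameters, the config seed, and package versions.

QC is deliberately a single marker-then-individual pass: dropping individuals
can push further markers below threshold, so the operation is not idempotent;
callers wanting a fixpoint can iterate it (convergence is tested).

## 7. Numerical and representational choices

- Intervals are 1-based closed internally; BED export/import converts to and
  from 0-based half-open.
- Genotypes are alternate-allele dosages 0/1/2 with −1 for missing, stored as
  small integer numpy arrays.
- Likelihoods are computed in linear space per factor with log-space
  accumulation across eliminations; zero likelihood is reported as −inf.
- Pedigree loops are detected on the marriage-graph; the peeling
  implementation refuses looped pedigrees rather than returning approximate
  answers, and the pipeline selects a loop-free nuclear subfamily for the
  linkage stage.
- Kinship/inbreeding uses the recursive kinship-matrix algorithm and is
  validated against an empirical gene-drop identity-by-descent oracle.
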