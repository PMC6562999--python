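"""Gene-dropping simulator with a planted fully penetrant recessive variant.

The default template reproduces the statistical structure the mapping
pipeline assumes: two litters out of one dam mated to a sire and to that
sire's son, all three parents tracing back to a single common founder a few
generations up who carries one copy of the causal allele.  Affected pups are
therefore autozygous for the founder haplotype around the causal locus,
while unaffected relatives are not — exactly the configuration that
linkage + autozygosity mapping exploits.

Meioses follow the Haldane model: crossovers are a Poisson process on the
genetic map (no interference), so the recombination fraction between loci
d Morgans apart is (1 - exp(-2d)) / 2.  The gene drop is conditioned by
rejection sampling on the template structure (all three parents carriers,
no breeding ancestor homozygous, and a minimum number of affected pups per
litter); within that conditioning, transmissions are unbiased Mendelian
draws.

Emitted artifacts: PLINK PED/MAP array genotypes (with configurable
genotyping error and missingness), a FAM pedigree, a single-sample case VCF
and a control-cohort VCF, a multi-sample pedigree VCF (the targeted-
genotyping stand-in), a toy genome FASTA, a GFF3 with toy transcripts
including a multi-exon minus-strand gene hosting the causal variant, and a
truth TSV.  Everything is a pure function of the configuration seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, MarkerMap, MISSING, write_ped_map
from .pedigree import (
    AFFECTED,
    FEMALE,
    MALE,
    UNAFFECTED,
    Individual,
    Pedigree,
    write_fam,
)
from .variants import TranscriptModel, VariantRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
# codons excluding stops, for random CDS filler
_SAFE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class SimulationConfig:
    seed: int
    n_chromosomes: int = 5
    chrom_length_bp: int = 12_000_000
    markers_per_chrom: int = 400
    cm_per_mb: float = 1.0
    marker_freq_min: float = 0.05
    marker_freq_max: float = 0.95
    genotyping_error_rate: float = 0.001
    missing_rate: float = 0.005
    n_controls: int = 600
    background_variant_spacing_bp: int = 50_000
    founder_private_fraction: float = 0.3
    common_variant_freq_max: float = 0.25
    controls_carry_causal: bool = False
    min_affected_per_litter: int = 2
    litter_size: int = 5
    max_attempts: int = 50_000

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{k + 1}" for k in range(self.n_chromosomes)]

    @property
    def causal_chrom(self) -> str:
        return "chr3" if self.n_chromosomes >= 3 else self.chrom_names[-1]


# ---------------------------------------------------------------------------
# pedigree template (Fig-1-like)

FOUNDERS = ["CF", "FA", "FB", "FC", "FD"]
CARRIER_FOUNDER = "CF"


def template_pedigree(litter_size: int = 5) -> tuple[Pedigree, list[str], list[str]]:
    """Two-litter template: common founder CF, sire AD149 (also grandsire of
    litter 2 through his son AD180) and one dam shared by both litters.

    Returns (pedigree, litter1 pup ids, litter2 pup ids); phenotypes are
    unknown until a gene drop assigns them.
    """
    inds = [
        Individual("CF", sex=MALE),
        Individual("FA", sex=FEMALE),
        Individual("FB", sex=FEMALE),
        Individual("FC", sex=MALE),
        Individual("FD", sex=FEMALE),
        Individual("P1", "CF", "FA", MALE),
        Individual("M1", "CF", "FA", FEMALE),
        Individual("AD149", "P1", "FB", MALE),
        Individual("DAM", "FC", "M1", FEMALE),
        Individual("AD180", "AD149", "FD", MALE),
    ]
    litter1 = [f"L1C{k + 1}" for k in range(litter_size)]
    litter2 = [f"L2C{k + 1}" for k in range(litter_size)]
    for k, iid in enumerate(litter1):
        inds.append(Individual(iid, "AD149", "DAM", MALE if k % 2 else FEMALE))
    for k, iid in enumerate(litter2):
        inds.append(Individual(iid, "AD180", "DAM", MALE if k % 2 else FEMALE))
    return Pedigree(inds), litter1, litter2


ARRAY_PARENTS = ["AD149", "AD180", "DAM"]


# ---------------------------------------------------------------------------
# haplotypes and meiosis


@dataclass
class Haplotype:
    """Piecewise founder-haplotype origin along one chromosome.

    ``breakpoints`` are ascending crossover positions; segment k (between
    breakpoints k-1 and k) descends from founder haplotype ``sources[k]``.
    """

    breakpoints: np.ndarray
    sources: np.ndarray

    @classmethod
    def founder(cls, hap_id: int) -> "Haplotype":
        return cls(np.empty(0), np.array([hap_id]))

    def source_at(self, positions: np.ndarray) -> np.ndarray:
        return self.sources[np.searchsorted(self.breakpoints, positions, side="right")]


def sample_crossovers(rng: np.random.Generator, length_bp: int, cm_per_mb: float) -> np.ndarray:
    """Haldane crossover positions (bp) for one meiosis on a linear map."""
    morgans = length_bp / 1e6 * cm_per_mb / 100.0
    n = rng.poisson(morgans)
    return np.sort(rng.uniform(0, length_bp, size=n))


def recombine(h0: Haplotype, h1: Haplotype, crossovers: np.ndarray, start: int) -> Haplotype:
    """Transmitted haplotype: alternate between the parent's two haplotypes
    at each crossover, starting from haplotype ``start``."""
    bps: list[float] = []
    srcs: list[int] = []
    prev = -math.inf
    cur = start
    for edge in list(crossovers) + [math.inf]:
        h = h0 if cur == 0 else h1
        lo = int(np.searchsorted(h.breakpoints, prev, side="right"))
        hi = int(np.searchsorted(h.breakpoints, edge, side="left"))
        piece_starts = [prev] + list(h.breakpoints[lo:hi])
        piece_srcs = list(h.sources[lo : hi + 1])
        for x, s in zip(piece_starts, piece_srcs):
            if srcs and srcs[-1] == s:
                continue  # same origin as the running segment: extend it
            if x != -math.inf:
                bps.append(float(x))
            srcs.append(int(s))
        prev = edge
        cur = 1 - cur
    return Haplotype(np.asarray(bps, dtype=float), np.asarray(srcs, dtype=np.int64))


def gene_drop(
    ped: Pedigree,
    rng: np.random.Generator,
    chrom_lengths: Mapping[str, int],
    cm_per_mb: float,
) -> tuple[dict[str, dict[str, tuple[Haplotype, Haplotype]]], dict[str, list[float]]]:
    """Drop founder haplotypes through every meiosis of the pedigree.

    Founder ``k`` (in ``ped.founders`` order) receives intact haplotypes
    ``2k`` (paternal) and ``2k + 1`` (maternal).  Returns per-individual,
    per-chromosome (paternal, maternal) haplotypes and a crossover log keyed
    ``individual.pat|mat.chrom``.
    """
    founder_ids = {iid: k for k, iid in enumerate(ped.founders)}
    haps: dict[str, dict[str, tuple[Haplotype, Haplotype]]] = {}
    xlog: dict[str, list[float]] = {}
    for iid in ped.topological_order():
        ind = ped[iid]
        haps[iid] = {}
        for chrom, length in chrom_lengths.items():
            if ind.is_founder:
                k = founder_ids[iid]
                haps[iid][chrom] = (Haplotype.founder(2 * k), Haplotype.founder(2 * k + 1))
            else:
                out = []
                for parent, tag in ((ind.sire_id, "pat"), (ind.dam_id, "mat")):
                    xs = sample_crossovers(rng, length, cm_per_mb)
                    start = int(rng.integers(2))
                    p0, p1 = haps[parent][chrom]
                    out.append(recombine(p0, p1, xs, start))
                    xlog[f"{iid}.{tag}.{chrom}"] = [round(x, 1) for x in xs]
                haps[iid][chrom] = (out[0], out[1])
    return haps, xlog


# ---------------------------------------------------------------------------
# toy annotation: one large multi-exon minus-strand causal gene plus small
# flanking genes per chromosome (so intronic and intergenic classes occur)

CAUSAL_GENE = "SCN8A"
CAUSAL_CDS_POS = 4898  # coding position of the planted substitution
CAUSAL_CODON = 1633
_CAUSAL_CDS_CODONS = 1981  # 1980 residues + stop
_CAUSAL_EXON_SIZES = [663] + [660] * 8  # coding order; sums to 5943
_CAUSAL_INTRON = 8_000
_CAUSAL_GENE_END = 5_100_000  # genomic 5' end of the minus-strand gene


def build_transcripts(config: SimulationConfig) -> list[TranscriptModel]:
    """Deterministic toy transcript layout for the simulated genome."""
    out = []
    # causal gene: minus strand, exons descend from _CAUSAL_GENE_END
    exons = []
    end = _CAUSAL_GENE_END
    for size in _CAUSAL_EXON_SIZES:  # coding order = descending genomic
        exons.append((end - size + 1, end))
        end = end - size - _CAUSAL_INTRON
    exons = sorted(exons)
    out.append(
        TranscriptModel(
            gene_id=CAUSAL_GENE,
            transcript_id=f"{CAUSAL_GENE}.t1",
            chrom=config.causal_chrom,
            strand="-",
            exons=exons,
            cds_start=exons[0][0],
            cds_end=exons[-1][1],
        )
    )
    # two small genes per chromosome: 3 exons of 120 bp across a 300 kb span
    for chrom in config.chrom_names:
        for tag, anchor, strand in (("A", 1_000_000, "+"), ("B", 8_000_000, "-")):
            exons = [
                (anchor, anchor + 119),
                (anchor + 150_000, anchor + 150_119),
                (anchor + 299_880, anchor + 299_999),
            ]
            out.append(
                TranscriptModel(
                    gene_id=f"G{chrom[3:]}{tag}",
                    transcript_id=f"G{chrom[3:]}{tag}.t1",
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds_start=exons[0][0],
                    cds_end=exons[-1][1],
                )
            )
    return out


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(rng.choice(_SAFE_CODONS) for _ in range(n_codons - 1))
    return body + "TAA"


def build_genome(
    config: SimulationConfig, rng: np.random.Generator, transcripts: list[TranscriptModel]
) -> dict[str, str]:
    """Random chromosome sequences with each transcript's CDS painted in.

    The causal gene's codon at CAUSAL_CODON is forced to GGA (Gly) so the
    planted G>T substitution at codon offset 2 yields GTA (Val): a missense
    change, with genomic plus-strand alleles C>A on the minus-strand gene.
    """
    genome: dict[str, bytearray] = {}
    for chrom in config.chrom_names:
        arr = _BASES[rng.integers(0, 4, size=config.chrom_length_bp, dtype=np.int64)]
        genome[chrom] = bytearray(arr.tobytes())
    for t in transcripts:
        n_codons = t.cds_length // 3
        cds = _random_cds(rng, n_codons)
        if t.gene_id == CAUSAL_GENE:
            k = CAUSAL_CODON - 1
            cds = cds[: 3 * k] + "GGA" + cds[3 * k + 3 :]
        positions = t._cds_positions()  # coding order
        target = genome[t.chrom]
        if t.strand == "+":
            for p, base in zip(positions, cds):
                target[p - 1] = ord(base)
        else:
            for p, base in zip(positions, cds):
                target[p - 1] = ord(_COMP[base])
    return {c: s.decode() for c, s in ((c, bytes(b)) for c, b in genome.items())}


# ---------------------------------------------------------------------------
# founders' alleles at markers and sequence variants


def _founder_marker_alleles(
    rng: np.random.Generator, n_haps: int, freqs_a1: np.ndarray
) -> np.ndarray:
    """(n_haps x n_markers) 0/1 matrix, 1 = allele2, drawn at 1 - freq_a1."""
    return (rng.random((n_haps, freqs_a1.size)) < (1.0 - freqs_a1)).astype(np.int8)


@dataclass
class VariantSites:
    """Per-chromosome background-variant bookkeeping."""

    positions: np.ndarray  # ascending, 1-based
    refs: list[str]
    alts: list[str]
    is_private: np.ndarray  # bool
    pop_freq: np.ndarray  # alt frequency for common variants (0 for private)
    founder_alleles: np.ndarray  # (n_haps x n_sites) 0/1 alt indicator
    causal_index: int  # index of the causal site on its chromosome, else -1


def _build_variant_sites(
    config: SimulationConfig,
    rng: np.random.Generator,
    genome: Mapping[str, str],
    causal_pos: int,
    n_haps: int,
    causal_hap: int,
) -> dict[str, VariantSites]:
    sites: dict[str, VariantSites] = {}
    for chrom in config.chrom_names:
        length = config.chrom_length_bp
        n = length // config.background_variant_spacing_bp
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n, replace=False))
        pos = pos[pos != causal_pos] if chrom == config.causal_chrom else pos
        causal_index = -1
        if chrom == config.causal_chrom:
            pos = np.sort(np.append(pos, causal_pos))
            causal_index = int(np.searchsorted(pos, causal_pos))
        n = pos.size
        is_private = rng.random(n) < config.founder_private_fraction
        pop_freq = np.where(
            is_private, 0.0, rng.uniform(0.001, config.common_variant_freq_max, n)
        )
        founder = (rng.random((n_haps, n)) < pop_freq).astype(np.int8)
        private_hap = rng.integers(0, n_haps, size=n)
        for j in np.flatnonzero(is_private):
            founder[:, j] = 0
            founder[private_hap[j], j] = 1
        refs, alts = [], []
        seq = genome[chrom]
        for p in pos:
            ref = seq[p - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            refs.append(ref)
            alts.append(alt)
        if causal_index >= 0:
            # the causal substitution: plus-strand C>A, carried only by the
            # carrier founder's haplotype
            is_private[causal_index] = True
            pop_freq[causal_index] = 0.0
            founder[:, causal_index] = 0
            founder[causal_hap, causal_index] = 1
            alts[causal_index] = "A"
        sites[chrom] = VariantSites(pos, refs, alts, is_private, pop_freq, founder, causal_index)
    return sites


# ---------------------------------------------------------------------------
# dataset


@dataclass
class TruthFile:
    causal_chrom: str
    causal_pos: int
    ref: str
    alt: str
    cds_position: int
    codon_index: int
    c_notation: str
    p_notation: str
    consequence: str
    causal_dosage: dict[str, int]
    crossovers: dict[str, list[float]]

    def to_tsv(self, path) -> None:
        rows = [
            ("causal", "chrom", self.causal_chrom),
            ("causal", "pos", self.causal_pos),
            ("causal", "ref", self.ref),
            ("causal", "alt", self.alt),
            ("causal", "cds_position", self.cds_position),
            ("causal", "codon_index", self.codon_index),
            ("causal", "c_notation", self.c_notation),
            ("causal", "p_notation", self.p_notation),
            ("causal", "consequence", self.consequence),
        ]
        rows += [("dosage", iid, d) for iid, d in sorted(self.causal_dosage.items())]
        rows += [
            ("crossovers", key, ",".join(f"{x:.1f}" for x in xs))
            for key, xs in sorted(self.crossovers.items())
        ]
        with open(path, "w") as fh:
            fh.write("section\tkey\tvalue\n")
            for sec, key, val in rows:
                fh.write(f"{sec}\t{key}\t{val}\n")


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    pedigree: Pedigree
    litter1: list[str]
    litter2: list[str]
    cohort_ids: list[str]  # array-genotyped individuals
    case_id: str  # affected individual whose genome is "sequenced"
    gm: GenotypeMatrix  # array genotypes with error/missingness applied
    variants: list[VariantRecord]  # genotypes for every pedigree member
    control_dosage: np.ndarray  # (n_sites x n_controls) alt dosage, site order = variants
    transcripts: list[TranscriptModel]
    genome: dict[str, str]
    truth: TruthFile

    @property
    def case_ids(self) -> list[str]:
        return [i for i in self.cohort_ids if self.pedigree[i].phenotype == AFFECTED]

    @property
    def control_cohort_ids(self) -> list[str]:
        return [i for i in self.cohort_ids if self.pedigree[i].phenotype == UNAFFECTED]

    def case_variants(self) -> list[VariantRecord]:
        """Single-sample view of the case's sequence variants."""
        return [
            VariantRecord(v.chrom, v.pos, v.ref, v.alt, {self.case_id: v.genotypes[self.case_id]})
            for v in self.variants
        ]

    def control_index(self) -> dict[tuple[str, int, str, str], tuple[int, int]]:
        """(chrom, pos, ref, alt) -> (n carrier controls, n missing controls)."""
        out = {}
        for k, v in enumerate(self.variants):
            carriers = int(np.sum(self.control_dosage[k] > 0))
            out[v.key] = (carriers, 0)
        return out

    # -- file emission -----------------------------------------------------
    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fam": outdir / "pedigree.fam",
            "ped": outdir / "array.ped",
            "map": outdir / "array.map",
            "case_vcf": outdir / "case.vcf",
            "controls_vcf": outdir / "controls.vcf",
            "pedigree_vcf": outdir / "pedigree.vcf",
            "fasta": outdir / "genome.fa",
            "gff3": outdir / "genes.gff3",
            "truth": outdir / "truth.tsv",
        }
        write_fam(self.pedigree, paths["fam"])
        write_ped_map(self.pedigree, self.gm, paths["ped"], paths["map"])
        contigs = [(c, self.config.chrom_length_bp) for c in self.config.chrom_names]
        _write_vcf(
            paths["case_vcf"],
            [self.case_id],
            self.variants,
            lambda v, k: [v.genotypes[self.case_id]],
            contigs,
        )
        ped_samples = self.pedigree.topological_order()
        _write_vcf(
            paths["pedigree_vcf"],
            ped_samples,
            self.variants,
            lambda v, k: [v.genotypes[s] for s in ped_samples],
            contigs,
        )
        n_controls = self.config.n_controls
        _write_vcf(
            paths["controls_vcf"],
            [f"CTRL{i + 1}" for i in range(n_controls)],
            self.variants,
            lambda v, k: list(self.control_dosage[k]),
            contigs,
        )
        _write_fasta(paths["fasta"], self.genome)
        _write_gff3(paths["gff3"], self.transcripts)
        self.truth.to_tsv(paths["truth"])
        return paths


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def _write_vcf(path, samples, variants, genotype_fn, contigs) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for k, v in enumerate(variants):
            gts = "\t".join(_GT_STR[int(g)] for g in genotype_fn(v, k))
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def _write_fasta(path, genome: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def _write_gff3(path, transcripts) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            span = t.span
            fh.write(
                f"{t.chrom}\ttoy\tgene\t{span.start}\t{span.end}\t.\t{t.strand}\t.\t"
                f"ID={t.gene_id}\n"
            )
            fh.write(
                f"{t.chrom}\ttoy\tmRNA\t{span.start}\t{span.end}\t.\t{t.strand}\t.\t"
                f"ID={t.transcript_id};Parent={t.gene_id}\n"
            )
            for n, (s, e) in enumerate(t.exons, 1):
                fh.write(
                    f"{t.chrom}\ttoy\texon\t{s}\t{e}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id}.exon{n};Parent={t.transcript_id}\n"
                )
            for n, (s, e) in enumerate(t.cds_exon_intervals, 1):
                fh.write(
                    f"{t.chrom}\ttoy\tCDS\t{s}\t{e}\t.\t{t.strand}\t0\t"
                    f"ID={t.transcript_id}.cds{n};Parent={t.transcript_id}\n"
                )


# ---------------------------------------------------------------------------
# top-level simulation


def _dosage_at(
    haps: Mapping[str, Mapping[str, tuple[Haplotype, Haplotype]]],
    iid: str,
    chrom: str,
    positions: np.ndarray,
    founder_alleles: np.ndarray,
) -> np.ndarray:
    hp, hm = haps[iid][chrom]
    src_p = hp.source_at(positions)
    src_m = hm.source_at(positions)
    cols = np.arange(positions.size)
    return founder_alleles[src_p, cols].astype(np.int16) + founder_alleles[src_m, cols]


def _causal_dosage(haps, iid: str, chrom: str, pos: int, causal_hap: int) -> int:
    hp, hm = haps[iid][chrom]
    p = np.asarray([float(pos)])
    return int(hp.source_at(p)[0] == causal_hap) + int(hm.source_at(p)[0] == causal_hap)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Run the full conditioned gene-dropping simulation.

    Deterministic for a fixed config (including its seed): re-running
    produces byte-identical emitted files.
    """
    rng = np.random.default_rng(config.seed)
    ped, litter1, litter2 = template_pedigree(config.litter_size)
    chrom_lengths = {c: config.chrom_length_bp for c in config.chrom_names}
    n_haps = 2 * len(ped.founders)
    causal_hap = 2 * ped.founders.index(CARRIER_FOUNDER)  # CF's paternal haplotype

    transcripts = build_transcripts(config)
    causal_tx = next(t for t in transcripts if t.gene_id == CAUSAL_GENE)
    causal_pos = causal_tx.cds_to_genomic(CAUSAL_CDS_POS)
    genome = build_genome(config, rng, transcripts)

    # array markers
    marker_frames = {}
    marker_founder = {}
    for chrom in config.chrom_names:
        pos = np.sort(
            rng.choice(
                np.arange(1, config.chrom_length_bp + 1),
                size=config.markers_per_chrom,
                replace=False,
            )
        )
        freqs = rng.uniform(config.marker_freq_min, config.marker_freq_max, pos.size)
        pairs = [sorted(rng.choice(list("ACGT"), size=2, replace=False)) for _ in pos]
        marker_frames[chrom] = pd.DataFrame(
            {
                "chrom": chrom,
                "id": [f"{chrom}_M{k + 1}" for k in range(pos.size)],
                "cm": pos / 1e6 * config.cm_per_mb,
                "pos": pos,
                "a1": [p[0] for p in pairs],
                "a2": [p[1] for p in pairs],
            }
        )
        marker_founder[chrom] = _founder_marker_alleles(rng, n_haps, freqs)

    # sequence variants
    var_sites = _build_variant_sites(config, rng, genome, causal_pos, n_haps, causal_hap)

    # conditioned gene drop; chromosomes segregate independently, so the
    # rejection loop only needs to re-drop the causal chromosome
    needed_carriers = ["AD149", "DAM", "AD180"]
    pups = litter1 + litter2
    non_pups = [i for i in ped.ids if i not in pups]
    accepted = None
    for _ in range(config.max_attempts):
        haps, xlog = gene_drop(
            ped, rng, {config.causal_chrom: config.chrom_length_bp}, config.cm_per_mb
        )
        dosage = {
            iid: _causal_dosage(haps, iid, config.causal_chrom, causal_pos, causal_hap)
            for iid in ped.ids
        }
        if any(dosage[i] != 1 for i in needed_carriers):
            continue
        if any(dosage[i] == 2 for i in non_pups):
            continue
        if sum(dosage[i] == 2 for i in litter1) < config.min_affected_per_litter:
            continue
        if sum(dosage[i] == 2 for i in litter2) < config.min_affected_per_litter:
            continue
        accepted = (haps, xlog, dosage)
        break
    if accepted is None:
        raise RuntimeError(
            f"no gene drop satisfied the template conditions in {config.max_attempts} attempts"
        )
    haps, xlog, dosage = accepted
    other = {c: l for c, l in chrom_lengths.items() if c != config.causal_chrom}
    if other:
        haps_rest, xlog_rest = gene_drop(ped, rng, other, config.cm_per_mb)
        for iid in ped.ids:
            haps[iid].update(haps_rest[iid])
        xlog.update(xlog_rest)

    # phenotypes: fully penetrant recessive
    for iid in ped.ids:
        ped[iid].phenotype = AFFECTED if dosage[iid] == 2 else UNAFFECTED

    cohort = ARRAY_PARENTS + litter1 + litter2
    case_id = next(i for i in pups if dosage[i] == 2)

    # array genotype matrix with error + missingness
    mmap = MarkerMap(pd.concat(marker_frames.values(), ignore_index=True))
    calls = np.zeros((len(cohort), len(mmap)), dtype=np.int8)
    col0 = 0
    for chrom in config.chrom_names:
        pos = marker_frames[chrom]["pos"].to_numpy()
        for r, iid in enumerate(cohort):
            calls[r, col0 : col0 + pos.size] = _dosage_at(
                haps, iid, chrom, pos.astype(float), marker_founder[chrom]
            )
        col0 += pos.size
    if config.genotyping_error_rate > 0:
        e = config.genotyping_error_rate
        b1 = (calls >= 1).astype(np.int8)
        b2 = (calls == 2).astype(np.int8)
        f1 = rng.random(calls.shape) < e
        f2 = rng.random(calls.shape) < e
        calls = (b1 ^ f1) + (b2 ^ f2)
        calls = calls.astype(np.int8)
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = MISSING
    gm = GenotypeMatrix(cohort, mmap, calls)

    # sequence-variant genotypes for every pedigree member + controls
    variants: list[VariantRecord] = []
    control_rows = []
    for chrom in config.chrom_names:
        vs = var_sites[chrom]
        member_dos = {
            iid: _dosage_at(haps, iid, chrom, vs.positions.astype(float), vs.founder_alleles)
            for iid in ped.ids
        }
        n_sites = vs.positions.size
        ctrl = np.zeros((n_sites, config.n_controls), dtype=np.int8)
        common = ~vs.is_private
        ctrl[common] = rng.binomial(
            2, vs.pop_freq[common][:, None], (int(common.sum()), config.n_controls)
        ).astype(np.int8)
        if config.controls_carry_causal and vs.causal_index >= 0:
            ctrl[vs.causal_index] = rng.binomial(2, 0.05, config.n_controls).astype(np.int8)
        for j in range(n_sites):
            variants.append(
                VariantRecord(
                    chrom,
                    int(vs.positions[j]),
                    vs.refs[j],
                    vs.alts[j],
                    {iid: int(member_dos[iid][j]) for iid in ped.ids},
                )
            )
        control_rows.append(ctrl)
    control_dosage = np.vstack(control_rows)

    # truth record, with the consequence computed from the built CDS
    from .variants import cds_sequence, protein_change

    cseq = cds_sequence(causal_tx, genome)
    cc = protein_change(CAUSAL_CDS_POS, "G", "T", cseq)
    truth = TruthFile(
        causal_chrom=config.causal_chrom,
        causal_pos=causal_pos,
        ref=genome[config.causal_chrom][causal_pos - 1],
        alt="A",
        cds_position=CAUSAL_CDS_POS,
        codon_index=cc.codon_index,
        c_notation=cc.c_notation,
        p_notation=cc.p_notation,
        consequence=cc.klass,
        causal_dosage=dosage,
        crossovers=xlog,
    )
    return SimulatedDataset(
        config=config,
        pedigree=ped,
        litter1=litter1,
        litter2=litter2,
        cohort_ids=cohort,
        case_id=case_id,
        gm=gm,
        variants=variants,
        control_dosage=control_dosage,
        transcripts=transcripts,
        genome=genome,
        truth=truth,
    )
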