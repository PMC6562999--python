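"""Private-variant filtering and transcript-based consequence annotation.

Implements the candidate funnel for a recessive trait: variants homozygous
for the alternate allele in the sequenced case and absent from every control
genome are restricted to the mapped critical interval and classified as
intergenic, intronic or exonic; exonic single-nucleotide substitutions get
HGVS-style c./p. annotation against a transcript model (CDS coordinates run
5'->3' on the coding strand, so minus-strand transcripts reverse-complement
the alleles: a genomic C>A becomes a coding G>T).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .intervals import GenomeInterval

HOM_REF, HET, HOM_ALT, GT_MISSING = 0, 1, 2, -1

_SEVERITY = {"nonsense": 3, "missense": 2, "synonymous": 1, "unsupported": 0}


class AnnotationError(ValueError):
    pass


class OutOfCdsError(AnnotationError):
    pass


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict[str, int] = field(default_factory=dict)  # sample -> 0/1/2/-1
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# VCF input (cyvcf2); multi-allelic sites are decomposed to biallelic records


def _gt_code(gt_type: int) -> int:
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    return {0: HOM_REF, 1: HET, 2: GT_MISSING, 3: HOM_ALT}[int(gt_type)]


def read_vcf(path) -> list[VariantRecord]:
    """Read a VCF into VariantRecords, splitting multi-allelic sites.

    For a decomposed alternate allele, a genotype is coded against that
    allele alone (other alternates at the site count as non-carrying).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: list[VariantRecord] = []
    for v in vcf:
        alts = v.ALT or []
        if len(alts) == 1:
            gts = {s: _gt_code(t) for s, t in zip(samples, v.gt_types)}
            out.append(VariantRecord(v.CHROM, v.POS, v.REF, alts[0], gts))
        else:
            geno = np.asarray(v.genotypes, dtype=object)
            for k, alt in enumerate(alts, start=1):
                gts = {}
                for s, g in zip(samples, geno):
                    alleles = [a for a in g[:-1]]
                    if any(a < 0 for a in alleles):
                        gts[s] = GT_MISSING
                    else:
                        gts[s] = sum(a == k for a in alleles)
                out.append(VariantRecord(v.CHROM, v.POS, v.REF, alt, gts))
    return out


def control_carrier_index(path) -> dict[tuple[str, int, str, str], tuple[int, int]]:
    """Index a control-cohort VCF: (chrom, pos, ref, alt) -> (n_carriers, n_missing).

    A carrier is any sample with at least one copy of the alternate allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    index: dict[tuple[str, int, str, str], tuple[int, int]] = {}
    for v in vcf:
        alts = v.ALT or []
        t = v.gt_types
        n_missing = int(np.sum(t == 2))
        if len(alts) == 1:
            carriers = int(np.sum((t == 1) | (t == 3)))
            index[(v.CHROM, v.POS, v.REF, alts[0])] = (carriers, n_missing)
        else:
            geno = v.genotypes
            for k, alt in enumerate(alts, start=1):
                carriers = sum(1 for g in geno if k in g[:-1])
                index[(v.CHROM, v.POS, v.REF, alt)] = (carriers, n_missing)
    return index


# ---------------------------------------------------------------------------
# filtering


def private_hom_filter(
    case_variants: Iterable[VariantRecord],
    control_index: Mapping[tuple[str, int, str, str], tuple[int, int]],
    case_sample: str | None = None,
) -> list[VariantRecord]:
    """Variants homozygous-alt in the case with no control carrying the alt.

    Controls missing at a site count as non-carriers; such variants are kept
    but flagged ``controls_missing:<n>``.  Sites absent from the control
    index entirely count as unobserved in controls (flagged ``not_in_controls``).
    """
    out = []
    for v in case_variants:
        if case_sample is None:
            if len(v.genotypes) != 1:
                raise ValueError("case_sample required for multi-sample case VCFs")
            gt = next(iter(v.genotypes.values()))
        else:
            gt = v.genotypes.get(case_sample, GT_MISSING)
        if gt != HOM_ALT:
            continue
        entry = control_index.get(v.key)
        if entry is None:
            v.flags.append("not_in_controls")
        else:
            carriers, missing = entry
            if carriers > 0:
                continue
            if missing > 0:
                v.flags.append(f"controls_missing:{missing}")
        out.append(v)
    return out


def restrict_to_intervals(
    variants: Iterable[VariantRecord], intervals: Sequence[GenomeInterval]
) -> list[VariantRecord]:
    """Variants whose position falls inside any closed interval."""
    return [
        v
        for v in variants
        if any(iv.contains(v.chrom, v.pos) for iv in intervals)
    ]


# ---------------------------------------------------------------------------
# transcript model


@dataclass
class TranscriptModel:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # genomic 1-based inclusive, sorted
    cds_start: int  # genomic, 1-based inclusive
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise AnnotationError(f"exon {s}-{e} malformed")
            if s <= prev_end:
                raise AnnotationError("exons overlap or are unsorted")
            prev_end = e
        if self.cds_start > self.cds_end:
            raise AnnotationError("CDS start > end")
        if not (self._in_exon(self.cds_start) and self._in_exon(self.cds_end)):
            raise AnnotationError("CDS bounds outside exons")
        if self.cds_length % 3 != 0:
            raise AnnotationError(f"CDS length {self.cds_length} not divisible by 3")

    def _in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.exons[0][0], self.exons[-1][1])

    @property
    def cds_exon_intervals(self) -> list[tuple[int, int]]:
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 <= e2:
                out.append((s2, e2))
        return out

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_exon_intervals)

    def _cds_positions(self) -> np.ndarray:
        """Genomic positions of CDS bases in 5'->3' coding order."""
        parts = [np.arange(s, e + 1) for s, e in self.cds_exon_intervals]
        arr = np.concatenate(parts)
        return arr[::-1] if self.strand == "-" else arr

    def genomic_to_cds(self, pos: int) -> int:
        """1-based CDS coordinate of a genomic position (coding-strand order)."""
        arr = self._cds_positions()
        hits = np.flatnonzero(arr == pos)
        if hits.size == 0:
            raise OutOfCdsError(
                f"position {self.chrom}:{pos} outside the CDS of {self.transcript_id}"
            )
        return int(hits[0]) + 1

    def cds_to_genomic(self, cds_pos: int) -> int:
        arr = self._cds_positions()
        if not 1 <= cds_pos <= arr.size:
            raise OutOfCdsError(f"CDS position {cds_pos} outside 1..{arr.size}")
        return int(arr[cds_pos - 1])

    def contains_exonic(self, pos: int) -> bool:
        return self._in_exon(pos)


def genomic_to_cds(
    variant: VariantRecord, transcript: TranscriptModel
) -> tuple[int, str, str]:
    """(cds_position, coding ref, coding alt) for an SNV inside the CDS.

    Minus-strand transcripts reverse-complement the alleles.
    """
    if not variant.is_snv:
        raise AnnotationError("CDS mapping supports single-nucleotide variants only")
    cds_pos = transcript.genomic_to_cds(variant.pos)
    if transcript.strand == "-":
        comp = str.maketrans("ACGTacgt", "TGCAtgca")
        return cds_pos, variant.ref.translate(comp), variant.alt.translate(comp)
    return cds_pos, variant.ref, variant.alt


def classify_location(
    variant: VariantRecord, transcripts: Sequence[TranscriptModel]
) -> tuple[str, list[str]]:
    """('exonic' | 'intronic' | 'intergenic', overlapping gene ids).

    Exonic beats intronic when the position is exonic in any transcript;
    intronic means inside some transcript's span but in none of its exons.
    """
    genes: list[str] = []
    exonic = intronic = False
    for t in transcripts:
        if not t.span.contains(variant.chrom, variant.pos):
            continue
        if t.gene_id not in genes:
            genes.append(t.gene_id)
        if t.contains_exonic(variant.pos):
            exonic = True
        else:
            intronic = True
    if exonic:
        return "exonic", genes
    if intronic:
        return "intronic", genes
    return "intergenic", []


# ---------------------------------------------------------------------------
# protein consequence


@dataclass
class ConsequenceCall:
    klass: str  # intergenic | intronic | synonymous | missense | nonsense | unsupported
    gene_id: str | None = None
    transcript_id: str | None = None
    cds_position: int | None = None
    codon_index: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    c_notation: str | None = None
    p_notation: str | None = None


def _translate_codon(codon: str) -> str:
    codon = codon.upper()
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


def protein_change(
    cds_position: int, ref: str, alt: str, cds_sequence: str
) -> ConsequenceCall:
    """Consequence of a coding-strand substitution within a CDS sequence.

    codon_index = ceil(cds_position / 3); the offset within the codon is
    ((cds_position - 1) mod 3) + 1.  The reference base must match the CDS
    sequence at that position.
    """
    if len(cds_sequence) % 3 != 0:
        raise AnnotationError("CDS sequence length not divisible by 3")
    if not 1 <= cds_position <= len(cds_sequence):
        raise OutOfCdsError(f"CDS position {cds_position} outside sequence")
    if cds_sequence[cds_position - 1].upper() != ref.upper():
        raise AnnotationError(
            f"reference mismatch at c.{cds_position}: sequence has "
            f"{cds_sequence[cds_position - 1]!r}, variant says {ref!r}"
        )
    codon_index = (cds_position + 2) // 3
    offset = (cds_position - 1) % 3  # 0-based within codon
    codon = cds_sequence[3 * (codon_index - 1) : 3 * codon_index].upper()
    alt_codon = codon[:offset] + alt.upper() + codon[offset + 1 :]
    ref_aa = _translate_codon(codon)
    alt_aa = _translate_codon(alt_codon)
    if alt_aa == ref_aa:
        klass = "synonymous"
    elif alt_aa == "*":
        klass = "nonsense"
    else:
        klass = "missense"
    ref3 = seq3(ref_aa) if ref_aa != "*" else "Ter"
    alt3 = seq3(alt_aa) if alt_aa != "*" else "Ter"
    return ConsequenceCall(
        klass=klass,
        cds_position=cds_position,
        codon_index=codon_index,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        c_notation=f"c.{cds_position}{ref.upper()}>{alt.upper()}",
        p_notation=f"p.{ref3}{codon_index}{alt3}",
    )


def cds_sequence(transcript: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced CDS sequence (coding strand) from per-chromosome sequences."""
    chrom_seq = str(genome[transcript.chrom])
    parts = [chrom_seq[s - 1 : e] for s, e in transcript.cds_exon_intervals]
    seq = "".join(parts)
    if transcript.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def annotate_variant(
    variant: VariantRecord,
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, str] | None,
) -> list[ConsequenceCall]:
    """All consequence calls for one variant across overlapping transcripts."""
    loc, genes = classify_location(variant, transcripts)
    if loc in ("intergenic", "intronic"):
        return [ConsequenceCall(klass=loc, gene_id=genes[0] if genes else None)]
    calls = []
    for t in transcripts:
        if not (t.span.contains(variant.chrom, variant.pos) and t.contains_exonic(variant.pos)):
            continue
        if not variant.is_snv:
            calls.append(ConsequenceCall("unsupported", t.gene_id, t.transcript_id))
            continue
        try:
            cds_pos, cref, calt = genomic_to_cds(variant, t)
        except OutOfCdsError:
            # exonic but untranslated (UTR); reported without protein change
            calls.append(ConsequenceCall("unsupported", t.gene_id, t.transcript_id))
            continue
        if genome is None:
            calls.append(ConsequenceCall("unsupported", t.gene_id, t.transcript_id))
            continue
        cc = protein_change(cds_pos, cref, calt, cds_sequence(t, genome))
        cc.gene_id, cc.transcript_id = t.gene_id, t.transcript_id
        calls.append(cc)
    return calls or [ConsequenceCall("unsupported")]


def candidate_report(
    variants: Sequence[VariantRecord],
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-variant consequence table plus funnel counts by location class.

    Rows are ordered by (chrom, pos); a variant hitting several transcripts
    is labelled by its most severe consequence (nonsense > missense >
    synonymous > unsupported).  Counts use the three-way intergenic /
    intronic / exonic split and always sum to the number of input variants.
    """
    rows = []
    counts = {"intergenic": 0, "intronic": 0, "exonic": 0}
    for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
        loc, genes = classify_location(v, transcripts)
        counts[loc] += 1
        calls = annotate_variant(v, transcripts, genome)
        if loc == "exonic":
            best = max(calls, key=lambda c: _SEVERITY.get(c.klass, 0))
        else:
            best = calls[0]
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "location": loc,
                "genes": ",".join(genes),
                "consequence": best.klass if loc == "exonic" else loc,
                "gene": best.gene_id or "",
                "transcript": best.transcript_id or "",
                "c_notation": best.c_notation or "",
                "p_notation": best.p_notation or "",
                "flags": ";".join(v.flags),
            }
        )
    cols = [
        "chrom", "pos", "ref", "alt", "location", "genes", "consequence",
        "gene", "transcript", "c_notation", "p_notation", "flags",
    ]
    return pd.DataFrame(rows, columns=cols), counts


# ---------------------------------------------------------------------------
# GFF3 transcript input (gene/mRNA/exon/CDS features)


def read_gff3(path) -> list[TranscriptModel]:
    """Load transcript models from a GFF3 subset via gffutils.

    Expects gene -> mRNA -> exon/CDS features; the CDS genomic bounds are
    the min/max over CDS features of each mRNA.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    out = []
    for mrna in db.features_of_type("mRNA"):
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        if not exons or not cds:
            continue
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        out.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_start=min(s for s, _ in cds),
                cds_end=max(e for _, e in cds),
            )
        )
    return out
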