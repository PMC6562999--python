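"""Genotype-phenotype segregation table and perfect-segregation test.

For a recessive candidate variant, perfect segregation means every affected
individual is homozygous for the alternate allele and no non-affected
individual is: the discordant count is zero.  Discordance is model-driven
(an affected heterozygote is only discordant if the penetrance of one copy
is zero), so reduced-penetrance presets reuse the same operation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .linkage import DiseaseModel
from .pedigree import AFFECTED, UNAFFECTED, UNKNOWN_PHENO

GENOTYPE_LABELS = ("hom_ref", "het", "hom_alt")


@dataclass
class SegregationTable:
    """2x3 contingency counts of phenotype x candidate genotype."""

    counts: pd.DataFrame  # rows affected/non_affected, cols hom_ref/het/hom_alt
    excluded_unknown: list[str]  # ids left out for unknown phenotype

    @property
    def n_affected(self) -> int:
        return int(self.counts.loc["affected"].sum())

    @property
    def n_non_affected(self) -> int:
        return int(self.counts.loc["non_affected"].sum())

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


def tabulate(
    genotypes: Mapping[str, int], phenotypes: Mapping[str, str]
) -> SegregationTable:
    """Cross-tabulate candidate genotypes (0/1/2 alt dosage) by phenotype.

    Every genotyped individual must have a phenotype entry; individuals of
    unknown phenotype are excluded from the table and listed in the report.
    """
    counts = pd.DataFrame(
        0, index=["affected", "non_affected"], columns=list(GENOTYPE_LABELS)
    )
    excluded = []
    for iid, gt in genotypes.items():
        if iid not in phenotypes:
            raise KeyError(f"genotyped individual {iid!r} has no phenotype entry")
        pheno = phenotypes[iid]
        if pheno == UNKNOWN_PHENO:
            excluded.append(iid)
            continue
        if gt not in (0, 1, 2):
            continue  # missing genotype
        row = "affected" if pheno == AFFECTED else "non_affected"
        counts.loc[row, GENOTYPE_LABELS[gt]] += 1
    return SegregationTable(counts, sorted(excluded))


def perfect_segregation(
    table: SegregationTable, model: DiseaseModel
) -> tuple[bool, int]:
    """(perfect, discordant count) under the given penetrance model.

    A genotype class is discordant with 'affected' when its penetrance is 0
    and with 'non-affected' when its penetrance is 1.
    """
    f = model.penetrances
    discordant = 0
    for g, label in enumerate(GENOTYPE_LABELS):
        if f[g] == 0.0:
            discordant += int(table.counts.loc["affected", label])
        if f[g] == 1.0:
            discordant += int(table.counts.loc["non_affected", label])
    return discordant == 0, discordant


def read_genotype_tsv(path) -> dict[str, int]:
    """Two-column TSV (id, genotype as 0/1/2 or ./missing) -> dosage map."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            iid, gt = line.split()[:2]
            out[iid] = int(gt) if gt in {"0", "1", "2"} else -1
    return out
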