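"""Shared builders and independent oracles (no pytest dependency)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ataxmap.genotypes import GenotypeMatrix, MarkerMap
from ataxmap.pedigree import (
    AFFECTED,
    FEMALE,
    MALE,
    UNAFFECTED,
    UNKNOWN_PHENO,
    Individual,
    Pedigree,
)


# ---------------------------------------------------------------------------
# genotype-matrix builders


def make_mmap(chrom_positions: dict[str, list[int]]) -> MarkerMap:
    rows = []
    for chrom, positions in chrom_positions.items():
        for k, pos in enumerate(positions):
            rows.append((chrom, f"{chrom}_m{k + 1}", pos / 1e6, int(pos), "A", "G"))
    return MarkerMap(
        pd.DataFrame(rows, columns=["chrom", "id", "cm", "pos", "a1", "a2"])
    )


def make_gm(ids: list[str], chrom_positions: dict[str, list[int]], calls) -> GenotypeMatrix:
    return make_gm_from_map(ids, make_mmap(chrom_positions), calls)


def make_gm_from_map(ids: list[str], mmap: MarkerMap, calls) -> GenotypeMatrix:
    return GenotypeMatrix(ids, mmap, np.asarray(calls, dtype=np.int8))


# ---------------------------------------------------------------------------
# pedigree builders


def nuclear_family(phenotypes: list[str], parent_phenos=(UNAFFECTED, UNAFFECTED)) -> Pedigree:
    """Two founders plus one child per phenotype in ``phenotypes``."""
    inds = [
        Individual("sire", None, None, MALE, parent_phenos[0]),
        Individual("dam", None, None, FEMALE, parent_phenos[1]),
    ]
    for k, ph in enumerate(phenotypes):
        inds.append(
            Individual(f"kid{k + 1}", "sire", "dam", MALE if k % 2 else FEMALE, ph)
        )
    return Pedigree(inds)


def random_loopfree_pedigree(rng: np.random.Generator, max_members: int = 9) -> Pedigree:
    """Random tree of nuclear families (each individual mates at most once,
    always with a fresh founder), hence loop-free by construction."""
    counter = [0]

    def nid() -> str:
        counter[0] += 1
        return f"I{counter[0]}"

    def pheno() -> str:
        return [AFFECTED, UNAFFECTED, UNAFFECTED, UNKNOWN_PHENO][int(rng.integers(4))]

    sire = Individual(nid(), None, None, MALE, pheno())
    dam = Individual(nid(), None, None, FEMALE, pheno())
    inds = [sire, dam]
    couples = [(sire.id, dam.id)]
    unmarried: list[Individual] = []
    while couples and len(inds) < max_members:
        s, d = couples.pop(0)
        for _ in range(int(rng.integers(1, 4))):
            if len(inds) >= max_members:
                break
            sex = MALE if rng.random() < 0.5 else FEMALE
            kid = Individual(nid(), s, d, sex, pheno())
            inds.append(kid)
            unmarried.append(kid)
        for kid in list(unmarried):
            if len(inds) + 3 > max_members:
                break
            if rng.random() < 0.35:
                unmarried.remove(kid)
                spouse_sex = FEMALE if kid.sex == MALE else MALE
                spouse = Individual(nid(), None, None, spouse_sex, pheno())
                inds.append(spouse)
                couples.append(
                    (kid.id, spouse.id) if kid.sex == MALE else (spouse.id, kid.id)
                )
    return Pedigree(inds)


def random_calls(rng: np.random.Generator, ped: Pedigree, p_missing: float = 0.1) -> dict[str, int]:
    out = {}
    for iid in ped.ids:
        out[iid] = -1 if rng.random() < p_missing else int(rng.integers(3))
    return out


# ---------------------------------------------------------------------------
# independent ROH window oracle


def roh_window_oracle(calls, max_het: int, max_missing: int) -> list[tuple[int, int]]:
    """All maximal windows bounded by homozygous calls with at most
    ``max_het`` heterozygous and ``max_missing`` missing calls inside.

    Direct definition: for each homozygous left endpoint, walk right while
    the budgets hold and record the furthest homozygous call; a window is
    maximal iff no valid window strictly contains it, which for left
    endpoints in ascending order means its right endpoint exceeds every
    right endpoint seen so far.
    """
    calls = list(calls)
    n = len(calls)
    valid: list[tuple[int, int]] = []
    for i in range(n):
        if calls[i] not in (0, 2):
            continue
        het = mis = 0
        best_j = None
        for j in range(i, n):
            c = calls[j]
            if c == 1:
                het += 1
            elif c == -1:
                mis += 1
            if het > max_het or mis > max_missing:
                break
            if c in (0, 2):
                best_j = j
        if best_j is not None:
            valid.append((i, best_j))
    out = []
    far = -1
    for i, j in valid:  # ascending i
        if j > far:
            out.append((i, j))
            far = j
    return out
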