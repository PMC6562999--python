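"""SNV-array genotype container with PLINK PED/MAP text IO and call-rate QC.

Genotype calls are stored as an individuals x markers int8 matrix coded
against each marker's allele pair: 0 = homozygous allele1, 1 = heterozygous,
2 = homozygous allele2, -1 = missing ("0 0" in PED text).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .pedigree import Pedigree

MISSING = -1


class FormatError(ValueError):
    """Malformed PED/MAP input; message names the file line."""


class MarkerMap:
    """Ordered marker metadata: chromosome, position, id and allele pair.

    Positions must be strictly increasing within each chromosome and marker
    ids unique.  ``a2`` may be None for markers seen monomorphic in the data.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"chrom", "id", "cm", "pos", "a1", "a2"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"marker map missing columns {sorted(missing)}")
        frame = frame.reset_index(drop=True)
        if frame["id"].duplicated().any():
            dup = frame.loc[frame["id"].duplicated(), "id"].iloc[0]
            raise FormatError(f"duplicate marker id {dup!r}")
        for chrom, grp in frame.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                k = int(np.argmax(np.diff(pos) <= 0))
                raise FormatError(
                    f"positions not strictly increasing on {chrom} near row {grp.index[k + 1] + 1}"
                )
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> pd.Series:
        return self.frame["id"]

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chrom"]))

    @property
    def positions(self) -> np.ndarray:
        return self.frame["pos"].to_numpy()

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.frame["chrom"] == chrom).to_numpy())

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.frame.iloc[idx])


@dataclass
class GenotypeMatrix:
    individual_ids: list[str]
    marker_map: MarkerMap
    calls: np.ndarray  # int8, shape (n_individuals, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individual_ids), len(self.marker_map)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} inconsistent with "
                f"{len(self.individual_ids)} individuals x {len(self.marker_map)} markers"
            )

    def row(self, iid: str) -> np.ndarray:
        return self.calls[self.individual_ids.index(iid)]

    def marker_call_rate(self) -> np.ndarray:
        if len(self.individual_ids) == 0:
            return np.zeros(len(self.marker_map))
        return (self.calls != MISSING).mean(axis=0)

    def individual_call_rate(self) -> np.ndarray:
        if len(self.marker_map) == 0:
            return np.zeros(len(self.individual_ids))
        return (self.calls != MISSING).mean(axis=1)

    def subset_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.individual_ids), self.marker_map.subset(idx), self.calls[:, idx])

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        rows = [self.individual_ids.index(i) for i in ids]
        return GenotypeMatrix(list(ids), self.marker_map, self.calls[rows])


# ---------------------------------------------------------------------------
# PED/MAP text IO


def read_ped_map(ped_path, map_path):
    """Read PLINK text PED + MAP into (Pedigree, GenotypeMatrix).

    The MAP file has 4 columns (chrom, id, cM, bp); allele pairs are inferred
    from the PED genotypes (lexicographically sorted).  "0 0" is a missing
    call; a genotype with exactly one "0" allele or more than two distinct
    alleles at a marker is a format error.
    """
    from .pedigree import Individual, Pedigree, _PHENO_FROM_FAM, _SEX_FROM_FAM, UNKNOWN_SEX, UNKNOWN_PHENO

    map_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
            chrom, mid, cm, pos = parts
            map_rows.append((chrom, mid, float(cm), int(pos)))
    n_markers = len(map_rows)

    inds, genos = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_markers} fields, got {len(parts)}"
                )
            _, iid, sire, dam, sex, pheno = parts[:6]
            alleles = parts[6:]
            for k, a in enumerate(alleles):
                if len(a) != 1:
                    raise FormatError(
                        f"{ped_path}:{ln}: allele field {k + 7} is {a!r} (one symbol expected)"
                    )
            inds.append(
                Individual(
                    iid,
                    None if sire == "0" else sire,
                    None if dam == "0" else dam,
                    _SEX_FROM_FAM.get(sex, UNKNOWN_SEX),
                    _PHENO_FROM_FAM.get(pheno, UNKNOWN_PHENO),
                )
            )
            genos.append(alleles)

    # infer allele pairs per marker
    a1s, a2s = [], []
    for m in range(n_markers):
        seen = set()
        for row in genos:
            seen.update(row[2 * m : 2 * m + 2])
        seen.discard("0")
        if len(seen) > 2:
            raise FormatError(f"{ped_path}: marker {map_rows[m][1]} has >2 alleles {sorted(seen)}")
        ordered = sorted(seen)
        a1s.append(ordered[0] if ordered else "0")
        a2s.append(ordered[1] if len(ordered) == 2 else None)

    calls = np.full((len(genos), n_markers), MISSING, dtype=np.int8)
    for i, row in enumerate(genos):
        for m in range(n_markers):
            x, y = row[2 * m], row[2 * m + 1]
            if x == "0" or y == "0":
                if x != y:
                    raise FormatError(
                        f"{ped_path}: half-missing genotype at marker {map_rows[m][1]}, individual {inds[i].id}"
                    )
                continue
            calls[i, m] = (x != a1s[m]) + (y != a1s[m])

    mmap = MarkerMap(
        pd.DataFrame(map_rows, columns=["chrom", "id", "cm", "pos"]).assign(a1=a1s, a2=a2s)
    )
    return Pedigree(inds), GenotypeMatrix([i.id for i in inds], mmap, calls)


def write_ped_map(ped, gm: GenotypeMatrix, ped_path, map_path, family_id: str = "FAM1") -> None:
    """Write canonical space-separated PED/MAP (round-trips with read_ped_map)."""
    from .pedigree import _PHENO_TO_FAM, _SEX_TO_FAM

    frame = gm.marker_map.frame
    with open(map_path, "w") as fh:
        for row in frame.itertuples():
            cm = f"{row.cm:g}"
            fh.write(f"{row.chrom} {row.id} {cm} {row.pos}\n")

    a1 = frame["a1"].to_numpy()
    a2 = frame["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(gm.individual_ids):
            ind = ped[iid]
            fields = [
                family_id,
                ind.id,
                ind.sire_id or "0",
                ind.dam_id or "0",
                _SEX_TO_FAM[ind.sex],
                _PHENO_TO_FAM[ind.phenotype],
            ]
            for m, c in enumerate(gm.calls[i]):
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [a1[m], a1[m]]
                elif c == 1:
                    fields += [a1[m], a2[m]]
                else:
                    fields += [a2[m], a2[m]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# QC


def qc_filter(
    gm: GenotypeMatrix,
    min_marker_call_rate: float = 0.90,
    min_individual_call_rate: float = 0.90,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop markers with call rate strictly below threshold, then re-assess
    individuals on the surviving markers.

    Returns the filtered matrix and a report (id, type, call_rate, action)
    covering every marker and individual.  An exactly-threshold call rate is
    retained (strict "<" exclusion).
    """
    for thr in (min_marker_call_rate, min_individual_call_rate):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"call-rate threshold {thr} outside [0, 1]")
    rows = []
    mrate = gm.marker_call_rate()
    keep_m = mrate >= min_marker_call_rate
    for mid, r, k in zip(gm.marker_map.ids, mrate, keep_m):
        rows.append((mid, "marker", float(r), "kept" if k else "removed"))
    gm2 = gm.subset_markers(np.flatnonzero(keep_m))

    irate = gm2.individual_call_rate()
    keep_i = irate >= min_individual_call_rate
    for iid, r, k in zip(gm2.individual_ids, irate, keep_i):
        rows.append((iid, "individual", float(r), "kept" if k else "removed"))
    gm3 = gm2.subset_individuals([i for i, k in zip(gm2.individual_ids, keep_i) if k])

    report = pd.DataFrame(rows, columns=["id", "type", "call_rate", "action"])
    return gm3, report


def allele_frequencies(
    gm: GenotypeMatrix, ped: "Pedigree | None" = None, founders_only: bool = False
) -> pd.Series:
    """Per-marker frequency of allele1 (NaN where no allele was called).

    ``founders_only`` restricts counting to pedigree founders so transmitted
    copies are not double-counted when the estimate feeds a linkage
    likelihood.
    """
    calls = gm.calls
    if founders_only:
        if ped is None:
            raise ValueError("founders_only requires a pedigree")
        rows = [k for k, iid in enumerate(gm.individual_ids) if iid in ped and ped[iid].is_founder]
        calls = calls[rows]
    called = calls != MISSING
    n_alleles = 2 * called.sum(axis=0)
    # dosage of allele1 per call = 2 - code
    a1_count = np.where(called, 2 - calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, a1_count / np.maximum(n_alleles, 1), np.nan)
    return pd.Series(freq, index=list(gm.marker_map.ids), name="freq_a1")
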