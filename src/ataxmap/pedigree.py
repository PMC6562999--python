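"""Pedigree representation, validation, kinship and Mendelian checks.

A pedigree is a directed acyclic family graph.  Individuals are founders
(both parents unknown) or non-founders (both parents present in the
pedigree); half-founders are rejected at load so the likelihood machinery
can treat founders uniformly.  Phenotypes follow PLINK FAM conventions:
2 = affected, 1 = unaffected, 0/-9 = unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .genotypes import GenotypeMatrix

MALE, FEMALE, UNKNOWN_SEX = "male", "female", "unknown"
AFFECTED, UNAFFECTED, UNKNOWN_PHENO = "affected", "unaffected", "unknown"

_SEX_FROM_FAM = {"1": MALE, "2": FEMALE, "0": UNKNOWN_SEX}
_SEX_TO_FAM = {MALE: "1", FEMALE: "2", UNKNOWN_SEX: "0"}
_PHENO_FROM_FAM = {"2": AFFECTED, "1": UNAFFECTED, "0": UNKNOWN_PHENO, "-9": UNKNOWN_PHENO}
_PHENO_TO_FAM = {AFFECTED: "2", UNAFFECTED: "1", UNKNOWN_PHENO: "0"}


class PedigreeError(ValueError):
    """Structural pedigree problem (unknown id, loop where unsupported, ...)."""


@dataclass
class Individual:
    id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str = UNKNOWN_SEX
    phenotype: str = UNKNOWN_PHENO

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None and self.dam_id is None


@dataclass
class Violation:
    individual: str
    rule: str
    detail: str = ""


class Pedigree:
    """Collection of individuals keyed by id, with derived graph structure."""

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self.individuals[ind.id] = ind
        if any(
            (i.sire_id is None) != (i.dam_id is None) for i in self.individuals.values()
        ):
            bad = [
                i.id
                for i in self.individuals.values()
                if (i.sire_id is None) != (i.dam_id is None)
            ]
            raise PedigreeError(f"half-founders not supported: {bad}")

    # -- basic accessors ---------------------------------------------------
    def __contains__(self, iid: str) -> bool:
        return iid in self.individuals

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, iid: str) -> Individual:
        try:
            return self.individuals[iid]
        except KeyError:
            raise PedigreeError(f"unknown individual id {iid!r}") from None

    @property
    def ids(self) -> list[str]:
        return list(self.individuals)

    @property
    def founders(self) -> list[str]:
        return [i.id for i in self.individuals.values() if i.is_founder]

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        ind = self[iid]
        return ind.sire_id, ind.dam_id

    def children(self, iid: str) -> list[str]:
        return [
            i.id
            for i in self.individuals.values()
            if iid in (i.sire_id, i.dam_id)
        ]

    # -- derived structure -------------------------------------------------
    def generation_index(self) -> dict[str, int]:
        """Depth in parent-edges from the founders (founder = 0).

        Raises PedigreeError on cycles or unresolved parent references.
        """
        depth: dict[str, int] = {}

        def visit(iid: str, stack: tuple[str, ...]) -> int:
            if iid in depth:
                return depth[iid]
            if iid in stack:
                raise PedigreeError(f"cycle in pedigree through {iid!r}")
            ind = self[iid]
            if ind.is_founder:
                depth[iid] = 0
            else:
                depth[iid] = 1 + max(
                    visit(ind.sire_id, stack + (iid,)),
                    visit(ind.dam_id, stack + (iid,)),
                )
            return depth[iid]

        for iid in self.individuals:
            visit(iid, ())
        return depth

    def topological_order(self) -> list[str]:
        """Parents before children."""
        depth = self.generation_index()
        return sorted(self.individuals, key=lambda i: (depth[i], i))

    def has_loops(self) -> bool:
        """True if the marriage-node graph contains a cycle.

        Loops (inbreeding or marriage loops) break single-pass peeling.
        The check builds the undirected graph linking each individual to the
        couple node of its parents and of every mating it takes part in, and
        counts edges vs. nodes per connected component.
        """
        couples = {
            (i.sire_id, i.dam_id)
            for i in self.individuals.values()
            if not i.is_founder
        }
        nodes: list[object] = list(self.individuals) + list(couples)
        index = {n: k for k, n in enumerate(nodes)}
        edges = set()
        for couple in couples:
            sire, dam = couple
            edges.add((index[sire], index[couple]))
            edges.add((index[dam], index[couple]))
        for ind in self.individuals.values():
            if not ind.is_founder:
                edges.add((index[ind.id], index[(ind.sire_id, ind.dam_id)]))
        # forest iff every component has edges = nodes - 1
        parent = list(range(len(nodes)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in edges:
            ra, rb = find(a), find(b)
            if ra == rb:
                return True
            parent[ra] = rb
        return False

    # -- subsetting --------------------------------------------------------
    def subfamily(self, ids: Iterable[str]) -> "Pedigree":
        """Restriction to ``ids``; parents outside the subset become unknown."""
        keep = set(ids)
        subs = []
        for iid in keep:
            ind = self[iid]
            inside = ind.sire_id in keep and ind.dam_id in keep
            subs.append(
                Individual(
                    ind.id,
                    ind.sire_id if inside else None,
                    ind.dam_id if inside else None,
                    ind.sex,
                    ind.phenotype,
                )
            )
        return Pedigree(subs)

    def nuclear_families(self) -> list[tuple[str, str, list[str]]]:
        """(sire, dam, children) for every mating, children sorted by id."""
        fams: dict[tuple[str, str], list[str]] = {}
        for ind in self.individuals.values():
            if not ind.is_founder:
                fams.setdefault((ind.sire_id, ind.dam_id), []).append(ind.id)
        return [(s, d, sorted(kids)) for (s, d), kids in sorted(fams.items())]


# ---------------------------------------------------------------------------
# validation


def validate_pedigree(ped: Pedigree) -> list[Violation]:
    """Check structural invariants; violations are data, not exceptions."""
    out: list[Violation] = []
    for ind in ped.individuals.values():
        for role, pid, want in (("sire", ind.sire_id, MALE), ("dam", ind.dam_id, FEMALE)):
            if pid is None:
                continue
            if pid not in ped.individuals:
                out.append(Violation(ind.id, "unresolved-parent", f"{role} {pid!r} absent"))
                continue
            psex = ped.individuals[pid].sex
            if psex not in (want, UNKNOWN_SEX):
                out.append(
                    Violation(ind.id, "parent-sex", f"{role} {pid!r} has sex {psex}")
                )
    # cycle check only on the resolvable part
    if not any(v.rule == "unresolved-parent" for v in out):
        try:
            ped.generation_index()
        except PedigreeError as exc:
            iid = str(exc).split("through ")[-1].strip("'\"")
            out.append(Violation(iid, "cycle", str(exc)))
    else:
        # self-parentage is still detectable
        for ind in ped.individuals.values():
            if ind.id in (ind.sire_id, ind.dam_id):
                out.append(Violation(ind.id, "cycle", "individual is its own parent"))
    return out


# ---------------------------------------------------------------------------
# kinship


def kinship(ped: Pedigree, a: str, b: str) -> float:
    """Recursive kinship coefficient phi(a, b).

    phi(x, x) = (1 + F_x) / 2 with F_x = phi(sire_x, dam_x); for distinct
    individuals, phi(a, b) = (phi(sire_a, b) + phi(dam_a, b)) / 2 where a is
    the later-generation member of the pair.  Distinct founders are taken
    as unrelated.
    """
    depth = ped.generation_index()

    @lru_cache(maxsize=None)
    def phi(x: str, y: str) -> float:
        if x == y:
            ind = ped[x]
            if ind.is_founder:
                return 0.5
            return 0.5 * (1.0 + phi(ind.sire_id, ind.dam_id))
        # recurse on the deeper individual so parents are never descendants of y
        if (depth[x], x) < (depth[y], y):
            x, y = y, x
        ind = ped[x]
        if ind.is_founder:
            return 0.0
        return 0.5 * (phi(ind.sire_id, y) + phi(ind.dam_id, y))

    ped[a], ped[b]  # raise on unknown ids
    return phi(a, b)


def inbreeding(ped: Pedigree, iid: str) -> float:
    """Inbreeding coefficient F = kinship of the parents (founder: 0)."""
    ind = ped[iid]
    if ind.is_founder:
        return 0.0
    return kinship(ped, ind.sire_id, ind.dam_id)


def common_ancestors(ped: Pedigree, ids: Iterable[str], max_generations: int) -> set[str]:
    """Ancestors (including self) of every listed individual within a path bound.

    Path length is counted in parent-edges (parent = 1 generation); an
    ancestor qualifies if reachable from each listed individual by some
    lineage of length <= max_generations.
    """
    id_list = list(ids)
    if not id_list:
        raise PedigreeError("ids must be nonempty")
    common: set[str] | None = None
    for iid in id_list:
        reach: dict[str, int] = {}
        frontier = {ped[iid].id: 0}
        while frontier:
            nxt: dict[str, int] = {}
            for x, d in frontier.items():
                if x in reach and reach[x] <= d:
                    continue
                reach[x] = d
                if d < max_generations:
                    for p in ped.parents(x):
                        if p is not None:
                            nxt[p] = min(nxt.get(p, d + 1), d + 1)
            frontier = nxt
        common = set(reach) if common is None else common & set(reach)
    return common or set()


# ---------------------------------------------------------------------------
# Mendelian consistency


def _gamete_set(dosage: int) -> frozenset[int]:
    # possible transmitted allele-2 counts per gamete
    if dosage == 0:
        return frozenset({0})
    if dosage == 2:
        return frozenset({1})
    return frozenset({0, 1})


_BOTH = frozenset({0, 1})


def mendelian_errors(ped: Pedigree, gm: "GenotypeMatrix") -> pd.DataFrame:
    """Per-individual, per-marker count of Mendelian-impossible calls.

    Trio check: the offspring dosage must decompose into one gamete from each
    genotyped parent; when only one parent is genotyped the other's gamete is
    unconstrained (duo check).  Missing calls never count as errors.
    Returns a DataFrame (individuals x markers) of 0/1 flags.
    """
    idx = {iid: k for k, iid in enumerate(gm.individual_ids)}
    calls = gm.calls
    flags = np.zeros_like(calls, dtype=np.int64)
    for iid in gm.individual_ids:
        if iid not in ped:
            continue
        sire, dam = ped.parents(iid)
        si = idx.get(sire) if sire is not None else None
        di = idx.get(dam) if dam is not None else None
        if si is None and di is None:
            continue
        row = calls[idx[iid]]
        for m in range(calls.shape[1]):
            c = row[m]
            if c < 0:
                continue
            sg = _gamete_set(calls[si, m]) if si is not None and calls[si, m] >= 0 else _BOTH
            dg = _gamete_set(calls[di, m]) if di is not None and calls[di, m] >= 0 else _BOTH
            if not any(a + b == c for a in sg for b in dg):
                flags[idx[iid], m] = 1
    return pd.DataFrame(flags, index=list(gm.individual_ids), columns=list(gm.marker_map.ids))


# ---------------------------------------------------------------------------
# FAM-dialect IO


def read_fam(path) -> Pedigree:
    """Read a PLINK FAM-dialect pedigree (fid iid sire dam sex phenotype)."""
    inds = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise PedigreeError(f"{path}:{ln}: expected 6 columns, got {len(parts)}")
            _, iid, sire, dam, sex, pheno = parts
            inds.append(
                Individual(
                    iid,
                    None if sire == "0" else sire,
                    None if dam == "0" else dam,
                    _SEX_FROM_FAM.get(sex, UNKNOWN_SEX),
                    _PHENO_FROM_FAM.get(pheno, UNKNOWN_PHENO),
                )
            )
    return Pedigree(inds)


def write_fam(ped: Pedigree, path, family_id: str = "FAM1") -> None:
    with open(path, "w") as fh:
        for iid in ped.topological_order():
            ind = ped[iid]
            fh.write(
                " ".join(
                    [
                        family_id,
                        ind.id,
                        ind.sire_id or "0",
                        ind.dam_id or "0",
                        _SEX_TO_FAM[ind.sex],
                        _PHENO_TO_FAM[ind.phenotype],
                    ]
                )
                + "\n"
            )
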