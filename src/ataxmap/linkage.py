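"""Two-point parametric linkage analysis on loop-free pedigrees.

The likelihood is the exact joint probability of observed marker genotypes
and phenotypes under a two-locus model: a biallelic disease locus with
penetrance vector (f0, f1, f2) and allele frequency q, and a biallelic
marker at recombination fraction theta.  Founders carry Hardy-Weinberg
haplotype frequencies at linkage equilibrium; each meiosis transmits one of
the four recombinant haplotype products with the theta-parameterised
probabilities.  Summation over the 16 ordered two-locus genotypes per
individual is done by Elston-Stewart peeling (variable elimination from the
deepest generation upward), which is exact and fast on loop-free pedigrees.

LOD(theta) = log10 L(theta) - log10 L(1/2); by construction LOD(1/2) = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genotypes import GenotypeMatrix, MarkerMap, allele_frequencies
from .intervals import GenomeInterval
from .pedigree import (
    AFFECTED,
    UNAFFECTED,
    Pedigree,
    PedigreeError,
    mendelian_errors,
)

DEFAULT_THETA_GRID = (0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
_FREQ_EPS = 1e-4  # clamp for (near-)monomorphic markers
_LOD_TOL = 1e-6  # numerical zero for region classification


class UnsupportedPedigreeError(PedigreeError):
    pass


@dataclass(frozen=True)
class DiseaseModel:
    """Penetrances P(affected | 0/1/2 disease alleles) and disease allele frequency."""

    penetrances: tuple[float, float, float]
    disease_allele_freq: float = 0.001

    def __post_init__(self) -> None:
        if not all(0.0 <= f <= 1.0 for f in self.penetrances):
            raise ValueError(f"penetrances {self.penetrances} outside [0, 1]")
        if not 0.0 < self.disease_allele_freq < 1.0:
            raise ValueError("disease allele frequency must lie in (0, 1)")

    @classmethod
    def fully_penetrant_recessive(cls, disease_allele_freq: float = 0.001) -> "DiseaseModel":
        return cls((0.0, 0.0, 1.0), disease_allele_freq)


# ---------------------------------------------------------------------------
# state space
#
# Haplotype h in 0..3: h = 2*d + m, d = disease allele (1 = disease), m =
# marker allele (1 = allele2).  Ordered genotype g in 0..15: g = 4*h_pat + h_mat.

_HP = np.arange(16) // 4
_HM = np.arange(16) % 4
_D_DOSE = (_HP >> 1) + (_HM >> 1)  # disease-allele count per genotype
_M_DOSE = (_HP & 1) + (_HM & 1)  # marker allele2 count per genotype


def _haplotype_freqs(q: float, freq_a1: float) -> np.ndarray:
    pm = np.array([freq_a1, 1.0 - freq_a1])
    pd = np.array([1.0 - q, q])
    return np.array([pd[h >> 1] * pm[h & 1] for h in range(4)])


def _transmission_tensor(theta: float) -> np.ndarray:
    """T[g_parent, h_child] = P(transmitted haplotype | parent genotype)."""
    T = np.zeros((16, 4))
    for g in range(16):
        hp, hm = g // 4, g % 4
        dp, mp = hp >> 1, hp & 1
        dm, mm = hm >> 1, hm & 1
        for d in (0, 1):
            for m in (0, 1):
                p = 0.0
                # disease allele drawn from paternal haplotype of the parent
                if dp == d:
                    p += 0.5 * ((1 - theta) * (mp == m) + theta * (mm == m))
                if dm == d:
                    p += 0.5 * ((1 - theta) * (mm == m) + theta * (mp == m))
                T[g, 2 * d + m] = p
    return T


def _child_tensor(theta: float) -> np.ndarray:
    """T3[g_f, g_m, g_c] = P(child ordered genotype | parents).

    Child genotype g_c = 4*h_pat + h_mat with h_pat transmitted by the sire
    and h_mat by the dam.
    """
    T = _transmission_tensor(theta)
    return np.einsum("fa,mb->fmab", T, T).reshape(16, 16, 16)


def _local_factor(call: int, phenotype: str, model: DiseaseModel) -> np.ndarray:
    """Penetrance x marker-observation factor over the 16 genotype states."""
    f = np.asarray(model.penetrances)[_D_DOSE]
    if phenotype == AFFECTED:
        pen = f
    elif phenotype == UNAFFECTED:
        pen = 1.0 - f
    else:
        pen = np.ones(16)
    if call < 0:
        obs = np.ones(16)
    else:
        obs = (_M_DOSE == call).astype(float)
    return pen * obs


# ---------------------------------------------------------------------------
# peeling (variable elimination)


class _Factor:
    __slots__ = ("vars", "table")

    def __init__(self, vars: tuple[str, ...], table: np.ndarray):
        self.vars = vars
        self.table = table


def _product(factors: list[_Factor]) -> _Factor:
    union: list[str] = []
    for f in factors:
        for v in f.vars:
            if v not in union:
                union.append(v)
    pos = {v: i for i, v in enumerate(union)}
    out = None
    for f in factors:
        # broadcast f.table into the union axes: permute its axes into union
        # order (a view), then insert singleton axes for the missing variables
        axes = [pos[v] for v in f.vars]
        perm = sorted(range(len(axes)), key=axes.__getitem__)
        t = f.table.transpose(perm) if perm != list(range(len(axes))) else f.table
        own = set(axes)
        t = t[tuple(slice(None) if i in own else None for i in range(len(union)))]
        out = t if out is None else out * t
    return _Factor(tuple(union), out)


def _eliminate(factors: list[_Factor], order: Sequence[str]) -> float:
    for v in order:
        group = [f for f in factors if v in f.vars]
        rest = [f for f in factors if v not in f.vars]
        prod = _product(group)
        axis = prod.vars.index(v)
        summed = prod.table.sum(axis=axis)
        rest.append(_Factor(tuple(x for x in prod.vars if x != v), summed))
        factors = rest
    val = 1.0
    for f in factors:
        val *= float(f.table)
    return val


def _build_factors(
    ped: Pedigree,
    calls: Mapping[str, int],
    prior: np.ndarray,
    model: DiseaseModel,
    T3: np.ndarray,
) -> list[_Factor]:
    factors = []
    for iid in ped.ids:
        ind = ped[iid]
        psi = _local_factor(calls.get(iid, -1), ind.phenotype, model)
        if ind.is_founder:
            factors.append(_Factor((iid,), prior * psi))
        else:
            factors.append(_Factor((ind.sire_id, ind.dam_id, iid), T3 * psi))
    return factors


def _likelihood(
    ped: Pedigree,
    calls: Mapping[str, int],
    prior: np.ndarray,
    model: DiseaseModel,
    T3: np.ndarray,
    order: Sequence[str],
) -> float:
    return _eliminate(_build_factors(ped, calls, prior, model, T3), order)


def pedigree_log_likelihood(
    ped: Pedigree,
    marker_calls: Mapping[str, int],
    marker_allele_freq: float,
    model: DiseaseModel,
    theta: float,
) -> float:
    """Natural-log two-locus pedigree likelihood at recombination fraction theta.

    ``marker_calls`` maps individual id to the 0/1/2 allele2-dosage call
    (-1 or absence = missing).  ``marker_allele_freq`` is the frequency of
    marker allele1.  Raises UnsupportedPedigreeError on looped pedigrees;
    use :func:`pedigree_log_likelihood_bruteforce` for those.
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError(f"theta {theta} outside [0, 0.5]")
    if not 0.0 < marker_allele_freq < 1.0:
        raise ValueError("marker allele frequency must lie in (0, 1)")
    if ped.has_loops():
        raise UnsupportedPedigreeError(
            "pedigree contains loops; peeling is single-pass only — evaluate with "
            "pedigree_log_likelihood_bruteforce or restrict to a loop-free subfamily"
        )
    hf = _haplotype_freqs(model.disease_allele_freq, marker_allele_freq)
    prior = np.outer(hf, hf).reshape(16)
    T3 = _child_tensor(theta)
    order = list(reversed(ped.topological_order()))
    L = _likelihood(ped, marker_calls, prior, model, T3, order)
    return math.log(L) if L > 0.0 else -math.inf


def pedigree_log_likelihood_bruteforce(
    ped: Pedigree,
    marker_calls: Mapping[str, int],
    marker_allele_freq: float,
    model: DiseaseModel,
    theta: float,
) -> float:
    """Reference evaluator: explicit sum over every joint assignment of
    ordered two-locus genotypes, with zero-probability branches pruned.

    Exponential in pedigree size; intended for tests and for small looped
    pedigrees that peeling rejects.
    """
    hf = _haplotype_freqs(model.disease_allele_freq, marker_allele_freq)
    prior = np.outer(hf, hf).reshape(16)
    T3 = _child_tensor(theta)
    order = ped.topological_order()
    local = {
        iid: _local_factor(marker_calls.get(iid, -1), ped[iid].phenotype, model)
        for iid in order
    }
    states = {iid: np.flatnonzero(local[iid] > 0.0) for iid in order}

    def rec(k: int, assign: dict[str, int], p: float) -> float:
        if k == len(order):
            return p
        iid = order[k]
        ind = ped[iid]
        total = 0.0
        for g in states[iid]:
            if ind.is_founder:
                w = prior[g] * local[iid][g]
            else:
                w = T3[assign[ind.sire_id], assign[ind.dam_id], g] * local[iid][g]
            if w > 0.0:
                assign[iid] = g
                total += rec(k + 1, assign, p * w)
        assign.pop(iid, None)
        return total

    L = rec(0, {}, 1.0)
    return math.log(L) if L > 0.0 else -math.inf


# ---------------------------------------------------------------------------
# per-marker LOD scan


@dataclass
class LodCurve:
    marker_id: str
    thetas: np.ndarray
    lods: np.ndarray  # log10 units; -inf allowed at theta = 0

    @property
    def max_lod(self) -> float:
        return float(np.max(self.lods))

    @property
    def best_theta(self) -> float:
        return float(self.thetas[int(np.argmax(self.lods))])


@dataclass
class LinkedRegion:
    interval: GenomeInterval
    marker_ids: list[str]
    peak_lod: float


def two_point_lod(
    ped: Pedigree,
    gm: GenotypeMatrix,
    model: DiseaseModel,
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
    founders_only_freq: bool = True,
) -> tuple[dict[str, LodCurve], list[str]]:
    """Per-marker two-point LOD curves over a fixed theta grid.

    Marker allele frequencies are estimated from pedigree founders (falling
    back to all individuals, then to 0.5) and clamped away from 0/1.
    Markers with any Mendelian inconsistency in the pedigree are skipped and
    returned in the flagged list instead of a curve.
    """
    thetas = np.asarray(sorted(set(theta_grid)), dtype=float)
    if 0.5 not in thetas:
        thetas = np.append(thetas, 0.5)
    if ped.has_loops():
        raise UnsupportedPedigreeError(
            "pedigree contains loops; restrict the scan to a loop-free subfamily"
        )
    freqs_f = allele_frequencies(gm, ped, founders_only=founders_only_freq)
    freqs_all = allele_frequencies(gm, founders_only=False)
    flagged = list(
        mendelian_errors(ped, gm).sum(axis=0).pipe(lambda s: s[s > 0]).index
    )
    flagged_set = set(flagged)

    tensors = [_child_tensor(t) for t in thetas]
    order = list(reversed(ped.topological_order()))
    idx = {iid: k for k, iid in enumerate(gm.individual_ids)}
    members = [iid for iid in ped.ids if iid in idx]

    curves: dict[str, LodCurve] = {}
    for m, mid in enumerate(gm.marker_map.ids):
        if mid in flagged_set:
            continue
        f = freqs_f.iloc[m]
        if np.isnan(f):
            f = freqs_all.iloc[m]
        if np.isnan(f):
            f = 0.5
        f = min(max(float(f), _FREQ_EPS), 1.0 - _FREQ_EPS)
        hf = _haplotype_freqs(model.disease_allele_freq, f)
        prior = np.outer(hf, hf).reshape(16)
        calls = {iid: int(gm.calls[idx[iid], m]) for iid in members}
        logL = np.empty(len(thetas))
        for k, T3 in enumerate(tensors):
            L = _likelihood(ped, calls, prior, model, T3, order)
            logL[k] = math.log10(L) if L > 0.0 else -math.inf
        lods = logL - logL[-1]  # theta = 0.5 is last after sorting
        lods[-1] = 0.0
        curves[mid] = LodCurve(mid, thetas, lods)
    return curves, flagged


def linked_regions(
    curves: Mapping[str, LodCurve], mmap: MarkerMap, tol: float = _LOD_TOL
) -> list[LinkedRegion]:
    """Positively linked genome regions from per-marker LOD curves.

    Markers are classified as supporting (max LOD > tol), anti-linked
    (no theta with positive LOD, and negative LOD at the tightest theta:
    evidence of recombination against linkage) or uninformative (LOD
    identically ~0, e.g. monomorphic markers, which carry no evidence either
    way).  Regions are maximal map-order runs free of anti-linked markers
    that contain at least one supporting marker; each region spans the
    outermost supporting markers, which are its contributing markers.
    """
    frame = mmap.frame
    regions: list[LinkedRegion] = []
    for chrom in mmap.chroms:
        idxs = mmap.chrom_indices(chrom)
        run: list[int] = []

        def close(run_idx: list[int]) -> None:
            sup = [
                i
                for i in run_idx
                if frame["id"].iloc[i] in curves and curves[frame["id"].iloc[i]].max_lod > tol
            ]
            if not sup:
                return
            ids = [frame["id"].iloc[i] for i in sup]
            regions.append(
                LinkedRegion(
                    GenomeInterval(
                        chrom, int(frame["pos"].iloc[sup[0]]), int(frame["pos"].iloc[sup[-1]])
                    ),
                    ids,
                    max(curves[i].max_lod for i in ids),
                )
            )

        for i in idxs:
            mid = frame["id"].iloc[i]
            curve = curves.get(mid)
            if curve is None:
                run.append(i)  # flagged marker: no evidence either way
                continue
            anti = curve.max_lod <= tol and curve.lods[0] < -tol
            if anti:
                close(run)
                run = []
            else:
                run.append(i)
        close(run)
    return regions


def lod_table(curves: Mapping[str, LodCurve], mmap: MarkerMap):
    """Tidy per-marker LOD table (marker, chrom, pos, lod@theta..., max_lod)."""
    import pandas as pd

    rows = []
    for row in mmap.frame.itertuples():
        c = curves.get(row.id)
        if c is None:
            continue
        rec = {"marker": row.id, "chrom": row.chrom, "pos": row.pos}
        for t, l in zip(c.thetas, c.lods):
            rec[f"lod_{t:g}"] = l
        rec["max_lod"] = c.max_lod
        rows.append(rec)
    return pd.DataFrame(rows)
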