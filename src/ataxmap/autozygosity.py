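"""Runs of homozygosity, case-shared autozygosity and the critical interval.

A recessive causal allele inherited identical-by-descent from a common
founder sits inside a run of homozygosity (ROH) shared, with the same
alleles, by every affected individual and absent from unaffected relatives.
This module detects ROH with an exact maximal-run scan (deterministic,
oracle-checkable, unlike heuristic sliding-window callers), derives the
case-shared allele-matched intervals, removes regions homozygous in any
control, and intersects with the linkage signal to obtain critical regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genotypes import GenotypeMatrix, MarkerMap, MISSING
from .intervals import (
    GenomeInterval,
    intersect_lists,
    merge,
    subtract_many,
)
from .linkage import LinkedRegion

DEFAULT_MIN_MARKERS = 25
DEFAULT_MIN_LENGTH_BP = 500_000


@dataclass
class RohSegment:
    individual_id: str
    interval: GenomeInterval
    n_markers: int
    start_idx: int  # global marker index of the first run marker
    end_idx: int  # global marker index of the last run marker (inclusive)
    signature: np.ndarray  # per-marker call codes over the run (0/2 hom, 1 het, -1 missing)


def _maximal_hom_windows(
    calls: np.ndarray, max_het: int, max_missing: int
) -> list[tuple[int, int]]:
    """Maximal windows starting/ending on homozygous calls with at most
    ``max_het`` heterozygous and ``max_missing`` missing calls inside.

    A window is reported iff no valid window strictly contains it.  With the
    greedy right endpoint monotone in the left endpoint, the maximal set is
    the first left endpoint achieving each distinct right endpoint.
    """
    hom = np.flatnonzero((calls == 0) | (calls == 2))
    if hom.size == 0:
        return []
    het_ps = np.concatenate([[0], np.cumsum(calls == 1)])
    mis_ps = np.concatenate([[0], np.cumsum(calls == MISSING)])

    def ok(i: int, j: int) -> bool:
        return (
            het_ps[j + 1] - het_ps[i] <= max_het
            and mis_ps[j + 1] - mis_ps[i] <= max_missing
        )

    windows: list[tuple[int, int]] = []
    jp = 0  # index into hom of the greedy right end
    last_j = -1
    for ip in range(hom.size):
        i = hom[ip]
        if jp < ip:
            jp = ip
        while jp + 1 < hom.size and ok(i, hom[jp + 1]):
            jp += 1
        j = hom[jp]
        if j > last_j:
            windows.append((i, j))
            last_j = j
    return windows


def detect_roh(
    gm: GenotypeMatrix,
    min_markers: int = DEFAULT_MIN_MARKERS,
    min_length_bp: int = DEFAULT_MIN_LENGTH_BP,
    max_het: int = 0,
    max_missing: int = 2,
) -> dict[str, list[RohSegment]]:
    """Per-individual runs of homozygosity per chromosome.

    Maximal homozygous marker runs (with the configured heterozygous and
    missing-call allowances) are kept when they contain at least
    ``min_markers`` markers and span at least ``min_length_bp`` bases
    (first to last run marker, closed interval).
    """
    out: dict[str, list[RohSegment]] = {iid: [] for iid in gm.individual_ids}
    frame = gm.marker_map.frame
    for chrom in gm.marker_map.chroms:
        idxs = gm.marker_map.chrom_indices(chrom)
        pos = frame["pos"].to_numpy()[idxs]
        sub = gm.calls[:, idxs]
        for r, iid in enumerate(gm.individual_ids):
            for i, j in _maximal_hom_windows(sub[r], max_het, max_missing):
                n = j - i + 1
                span = int(pos[j] - pos[i] + 1)
                if n < min_markers or span < min_length_bp:
                    continue
                out[iid].append(
                    RohSegment(
                        iid,
                        GenomeInterval(chrom, int(pos[i]), int(pos[j])),
                        n,
                        int(idxs[i]),
                        int(idxs[j]),
                        sub[r, i : j + 1].copy(),
                    )
                )
    return out


def _segments_to_intervals(segments: Sequence[RohSegment]) -> list[GenomeInterval]:
    return merge(s.interval for s in segments)


def shared_case_homozygosity(
    segments: Mapping[str, list[RohSegment]],
    gm: GenotypeMatrix,
    case_ids: Sequence[str],
    min_markers: int = 1,
) -> list[GenomeInterval]:
    """Intervals where every case is inside a ROH and homozygous for the
    same allele at every retained marker.

    Case ROH intervals are intersected across all cases; within each
    intersection, maximal runs of markers at which every case call is
    homozygous for one common allele (missing calls are compatible with any
    allele) are emitted as intervals spanning the first to last such marker.
    """
    if not case_ids:
        raise ValueError("at least one case is required")
    for cid in case_ids:
        if cid not in segments:
            raise ValueError(f"no ROH segment list for case {cid!r}")
    common: list[GenomeInterval] | None = None
    for cid in case_ids:
        ivs = _segments_to_intervals(segments[cid])
        common = ivs if common is None else intersect_lists(common, ivs)
    rows = [gm.individual_ids.index(c) for c in case_ids]
    frame = gm.marker_map.frame
    pos_all = frame["pos"].to_numpy()
    chrom_all = frame["chrom"].to_numpy()

    out: list[GenomeInterval] = []
    for iv in common or []:
        on = np.flatnonzero(
            (chrom_all == iv.chrom) & (pos_all >= iv.start) & (pos_all <= iv.end)
        )
        if on.size == 0:
            continue
        calls = gm.calls[np.ix_(rows, on)]
        hom0 = np.any(calls == 0, axis=0)
        hom2 = np.any(calls == 2, axis=0)
        clean = ~np.any(calls == 1, axis=0)  # no case heterozygous
        # missing calls are compatible with any allele signature
        compatible = clean & ~(hom0 & hom2)
        # maximal runs of compatible markers
        k = 0
        while k < on.size:
            if not compatible[k]:
                k += 1
                continue
            j = k
            while j + 1 < on.size and compatible[j + 1]:
                j += 1
            if j - k + 1 >= min_markers:
                out.append(
                    GenomeInterval(iv.chrom, int(pos_all[on[k]]), int(pos_all[on[j]]))
                )
            k = j + 1
    return merge(out)


def exclude_control_homozygosity(
    case_intervals: Sequence[GenomeInterval],
    control_segments: Mapping[str, list[RohSegment]],
    min_length_bp: int = DEFAULT_MIN_LENGTH_BP,
    allele_aware: bool = False,
    gm: GenotypeMatrix | None = None,
    case_ids: Sequence[str] | None = None,
) -> list[GenomeInterval]:
    """Subtract control ROH from case-shared intervals.

    Default mode is allele-blind: any control ROH removes the overlapped
    region (the strict reading of requiring no homozygosity in any control).
    With ``allele_aware=True`` a control segment is only subtracted where its
    homozygous calls match the case allele at every overlapping marker
    (requires ``gm`` and ``case_ids`` to look the case alleles up).
    Fragments shorter than ``min_length_bp`` are dropped.
    """
    cover: list[GenomeInterval] = []
    for segs in control_segments.values():
        for s in segs:
            if not allele_aware:
                cover.append(s.interval)
                continue
            if gm is None or not case_ids:
                raise ValueError("allele_aware mode requires gm and case_ids")
            rows = [gm.individual_ids.index(c) for c in case_ids]
            span = np.arange(s.start_idx, s.end_idx + 1)
            ctrl = s.signature
            case_calls = gm.calls[np.ix_(rows, span)]
            hom_ctrl = (ctrl == 0) | (ctrl == 2)
            match = True
            for k in np.flatnonzero(hom_ctrl):
                col = case_calls[:, k]
                hom_case = col[(col == 0) | (col == 2)]
                if hom_case.size and np.any(hom_case != ctrl[k]):
                    match = False
                    break
            if match:
                cover.append(s.interval)
    result = subtract_many(list(case_intervals), cover)
    return [iv for iv in result if iv.length >= min_length_bp]


@dataclass
class CriticalRegion:
    interval: GenomeInterval
    n_markers: int
    peak_lod: float


def critical_regions(
    linked: Sequence[LinkedRegion],
    case_shared: Sequence[GenomeInterval],
    control_segments: Mapping[str, list[RohSegment]],
    mmap: MarkerMap,
    min_length_bp: int = DEFAULT_MIN_LENGTH_BP,
    allele_aware: bool = False,
    gm: GenotypeMatrix | None = None,
    case_ids: Sequence[str] | None = None,
) -> list[CriticalRegion]:
    """Intervals supported by linkage and case-shared autozygosity with no
    (allele-blind mode) control homozygosity, with array-marker counts."""
    overlap = intersect_lists([r.interval for r in linked], list(case_shared))
    surviving = exclude_control_homozygosity(
        overlap,
        control_segments,
        min_length_bp=min_length_bp,
        allele_aware=allele_aware,
        gm=gm,
        case_ids=case_ids,
    )
    frame = mmap.frame
    pos = frame["pos"].to_numpy()
    chrom = frame["chrom"].to_numpy()
    out = []
    for iv in surviving:
        n = int(np.sum((chrom == iv.chrom) & (pos >= iv.start) & (pos <= iv.end)))
        peak = max(
            (r.peak_lod for r in linked if r.interval.overlaps(iv)), default=0.0
        )
        out.append(CriticalRegion(iv, n, peak))
    return out
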