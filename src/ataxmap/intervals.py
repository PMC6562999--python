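"""Closed-interval algebra on 1-based inclusive genomic coordinates.

Genomic spans throughout the package (ROH segments, linked regions, the
critical interval) are represented as 1-based inclusive intervals, matching
the coordinate convention of published interval notation such as
chr27:3,154,712-8,679,881.  BED export converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A 1-based, inclusive genomic span on a single chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} (start > end)"
            )
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def __str__(self) -> str:  # chr27:3,154,712-8,679,881 style
        return f"{self.chrom}:{self.start:,}-{self.end:,}"


def span_bp(interval: GenomeInterval) -> int:
    """Length of a closed interval in base pairs (end - start + 1)."""
    return interval.length


def intersect(a: GenomeInterval, b: GenomeInterval) -> GenomeInterval | None:
    """Intersection of two closed intervals, or None if disjoint.

    Intervals on different chromosomes never intersect.  Touching closed
    intervals ([1,10] and [10,20]) intersect in the single shared base.
    """
    if not a.overlaps(b):
        return None
    return GenomeInterval(a.chrom, max(a.start, b.start), min(a.end, b.end))


def merge(intervals: Iterable[GenomeInterval]) -> list[GenomeInterval]:
    """Union of intervals: sorted, disjoint, with touching/overlapping runs fused."""
    out: list[GenomeInterval] = []
    for iv in sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end + 1:
            if iv.end > out[-1].end:
                out[-1] = GenomeInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def subtract(a: GenomeInterval, b: GenomeInterval) -> list[GenomeInterval]:
    """a minus b: 0, 1 or 2 fragments of a not covered by b."""
    if not a.overlaps(b):
        return [a]
    frags = []
    if b.start > a.start:
        frags.append(GenomeInterval(a.chrom, a.start, b.start - 1))
    if b.end < a.end:
        frags.append(GenomeInterval(a.chrom, b.end + 1, a.end))
    return frags


def subtract_many(
    intervals: Sequence[GenomeInterval], cover: Sequence[GenomeInterval]
) -> list[GenomeInterval]:
    """Subtract every interval in ``cover`` from every interval in ``intervals``."""
    result = list(intervals)
    for c in merge(cover):
        nxt: list[GenomeInterval] = []
        for iv in result:
            nxt.extend(subtract(iv, c))
        result = nxt
    return merge(result)


def intersect_lists(
    a: Sequence[GenomeInterval], b: Sequence[GenomeInterval]
) -> list[GenomeInterval]:
    """Pairwise intersection of two interval lists, merged."""
    out = []
    for x in a:
        for y in b:
            iv = intersect(x, y)
            if iv is not None:
                out.append(iv)
    return merge(out)


def to_bed_line(iv: GenomeInterval, name: str = ".") -> str:
    """Render one interval as a BED line (0-based half-open)."""
    return f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}"


def read_bed(path) -> list[GenomeInterval]:
    """Read BED intervals (0-based half-open) back into 1-based closed form."""
    out: list[GenomeInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append(GenomeInterval(chrom, int(start) + 1, int(end)))
    return out
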