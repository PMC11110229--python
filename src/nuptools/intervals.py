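"""Genomic interval primitives and base-pair arithmetic.

All internal coordinates are 0-based, half-open ``[start, end)``. GFF3 input
and output (1-based, closed) is converted at the IO boundary only. Touching
half-open intervals merge into one contiguous run, so base-pair accounting
never double-counts adjacent spans. Overlap counting ignores strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STRAND_FORWARD = "+"
STRAND_REVERSE = "-"
STRAND_NONE = "."

_VALID_STRANDS = {STRAND_FORWARD, STRAND_REVERSE, STRAND_NONE}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one sequence.

    Parameters
    ----------
    chrom : str
        Sequence (chromosome/scaffold) identifier.
    start : int
        0-based inclusive start. Must satisfy ``0 <= start < end``.
    end : int
        0-based exclusive end.
    strand : str, optional
        ``'+'``, ``'-'`` or ``'.'`` (unstranded, the default).
    """

    chrom: str
    start: int
    end: int
    strand: str = STRAND_NONE

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval ({self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def _group_by_chrom(
    intervals: Iterable[GenomicInterval],
) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in intervals:
        out[iv.chrom].append((iv.start, iv.end))
    return out


def _merge_pairs(pairs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge (start, end) pairs; touching runs coalesce."""
    if not pairs:
        return []
    pairs = sorted(pairs)
    merged = [list(pairs[0])]
    for s, e in pairs[1:]:
        if s <= merged[-1][1]:  # overlap or adjacency
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Return the disjoint sorted union of ``intervals``.

    Output intervals are pairwise disjoint and non-adjacent; strand is
    dropped (merged runs are unstranded). Intervals on different
    chromosomes are merged independently and returned sorted by
    (chrom, start).
    """
    by_chrom = _group_by_chrom(intervals)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        for s, e in _merge_pairs(by_chrom[chrom]):
            out.append(GenomicInterval(chrom, s, e))
    return out


def total_bp(intervals: Iterable[GenomicInterval]) -> int:
    """Total bases in the set union of ``intervals`` (no double counting)."""
    return sum(iv.length for iv in merge_intervals(intervals))


def _intersect_pairs(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersect two sorted disjoint pair lists by a two-pointer sweep."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect(
    set_a: Iterable[GenomicInterval], set_b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Interval-set intersection ``union(a) ∩ union(b)`` as disjoint intervals."""
    ma = _group_by_chrom(merge_intervals(set_a))
    mb = _group_by_chrom(merge_intervals(set_b))
    out: list[GenomicInterval] = []
    for chrom in sorted(set(ma) & set(mb)):
        for s, e in _intersect_pairs(ma[chrom], mb[chrom]):
            out.append(GenomicInterval(chrom, s, e))
    return out


def intersect_bp(
    set_a: Iterable[GenomicInterval], set_b: Iterable[GenomicInterval]
) -> int:
    """Number of bases shared by the unions of two interval sets.

    Symmetric, strand-agnostic, and equal to the per-base overlap of the
    two set unions.
    """
    return sum(iv.length for iv in intersect(set_a, set_b))


def subtract(
    set_a: Iterable[GenomicInterval], set_b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases of ``union(a)`` not in ``union(b)``, as disjoint intervals."""
    ma = _group_by_chrom(merge_intervals(set_a))
    mb = _group_by_chrom(merge_intervals(set_b))
    out: list[GenomicInterval] = []
    for chrom in sorted(ma):
        bs = mb.get(chrom, [])
        for s, e in ma[chrom]:
            cur = s
            for bs_s, bs_e in bs:
                if bs_e <= cur:
                    continue
                if bs_s >= e:
                    break
                if bs_s > cur:
                    out.append(GenomicInterval(chrom, cur, bs_s))
                cur = max(cur, bs_e)
                if cur >= e:
                    break
            if cur < e:
                out.append(GenomicInterval(chrom, cur, e))
    return out


def complement(
    intervals: Iterable[GenomicInterval], chrom_lengths: Mapping[str, int]
) -> list[GenomicInterval]:
    """Bases of every chromosome not covered by ``intervals``."""
    whole = [GenomicInterval(c, 0, n) for c, n in chrom_lengths.items() if n > 0]
    return subtract(whole, intervals)


def windowed_density(
    intervals: Iterable[GenomicInterval],
    window_bp: int,
    chrom_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Per-window feature counts and bp coverage along each chromosome.

    Windows tile each chromosome left to right; the last window may be
    short. ``count`` is the number of raw intervals whose start falls in
    the window; ``bp`` is the merged-coverage overlap with the window, so
    the ``bp`` column sums to the merged total feature bp per chromosome.

    Parameters
    ----------
    window_bp : int
        Window size in bases (>= 1). A window larger than a chromosome
        yields a single window spanning that chromosome.

    Returns
    -------
    pandas.DataFrame
        Columns ``chrom, window_start, window_end, count, bp``.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    intervals = list(intervals)
    raw_by_chrom = _group_by_chrom(intervals)
    merged_by_chrom = _group_by_chrom(merge_intervals(intervals))
    rows = []
    for chrom in sorted(chrom_lengths):
        clen = chrom_lengths[chrom]
        edges = list(range(0, clen, window_bp)) + [clen]
        starts = np.array(sorted(s for s, _ in raw_by_chrom.get(chrom, [])))
        merged = merged_by_chrom.get(chrom, [])
        for ws, we in zip(edges[:-1], edges[1:]):
            count = int(np.searchsorted(starts, we) - np.searchsorted(starts, ws))
            bp = sum(
                max(0, min(e, we) - max(s, ws)) for s, e in merged if s < we and e > ws
            )
            rows.append((chrom, ws, we, count, bp))
    return pd.DataFrame(
        rows, columns=["chrom", "window_start", "window_end", "count", "bp"]
    )
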