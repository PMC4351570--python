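"""Small interval-arithmetic helpers used by the region and exclusion logic.

All intervals are 0-based half-open ``(start, end)`` with ``start < end``,
grouped per contig.  The containers keep intervals sorted and merged so
overlap queries reduce to a binary search.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from .errors import InputError


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    """Sort and merge possibly overlapping intervals into an (n, 2) array."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    if not ivs:
        return np.empty((0, 2), dtype=np.int64)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two merged interval arrays."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    if not out:
        return np.empty((0, 2), dtype=np.int64)
    return np.asarray(out, dtype=np.int64)


def total_length(ivs: np.ndarray) -> int:
    if len(ivs) == 0:
        return 0
    return int((ivs[:, 1] - ivs[:, 0]).sum())


class IntervalSet:
    """Per-contig merged interval collection with overlap/containment queries."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end < start:
                raise InputError(f"interval end < start: {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        self._ivs: dict[str, np.ndarray] = {
            chrom: merge_intervals(v) for chrom, v in by_chrom.items()}

    @classmethod
    def from_bed(cls, path: str) -> "IntervalSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                rows.append((f[0], int(f[1]), int(f[2])))
        return cls(rows)

    def intervals(self, chrom: str) -> np.ndarray:
        return self._ivs.get(chrom, np.empty((0, 2), dtype=np.int64))

    @property
    def contigs(self) -> list[str]:
        return list(self._ivs)

    @property
    def total_bases(self) -> int:
        return sum(total_length(v) for v in self._ivs.values())

    def __len__(self) -> int:
        return sum(len(v) for v in self._ivs.values())

    def __iter__(self):
        for chrom in self._ivs:
            for s, e in self._ivs[chrom]:
                yield chrom, int(s), int(e)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) overlaps any interval on the contig."""
        ivs = self.intervals(chrom)
        if len(ivs) == 0 or end <= start:
            return False
        i = int(np.searchsorted(ivs[:, 0], end, side="left"))
        return i > 0 and ivs[i - 1, 1] > start

    def contains(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) lies fully inside a single interval."""
        ivs = self.intervals(chrom)
        if len(ivs) == 0 or end <= start:
            return False
        i = int(np.searchsorted(ivs[:, 0], start, side="right"))
        return i > 0 and ivs[i - 1, 1] >= end

    def covered_length(self, footprints: Iterable[tuple[str, int, int]]) -> int:
        """Bases of this set covered by the union of the given footprints."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in footprints:
            by_chrom.setdefault(chrom, []).append((s, e))
        covered = 0
        for chrom, fps in by_chrom.items():
            covered += total_length(
                intersect(self.intervals(chrom), merge_intervals(fps)))
        return covered

    def write_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, s, e in self:
                fh.write(f"{chrom}\t{s}\t{e}\n")
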