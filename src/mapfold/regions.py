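"""1-based inclusive genomic intervals (lowSS regions, core, motifs).

All coordinates in this package are 1-based and inclusive, matching the
subscript convention used for cis-elements (e.g. a hexamer at 18-23 has
start=18, end=23, length 6).  Explicit conversion to half-open 0-based BED
is available on export only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = ["Region", "RegionSet"]


@dataclass(frozen=True)
class Region:
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    label: str = ""
    meta: tuple = ()

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Region") -> bool:
        return self.start <= other.end and other.start <= self.end

    def intersect(self, other: "Region") -> "Region | None":
        s, e = max(self.start, other.start), min(self.end, other.end)
        if s > e:
            return None
        return Region(s, e, self.label or other.label)


class RegionSet:
    """Sorted, non-overlapping (after merge) collection of Regions."""

    def __init__(self, regions: Iterable[Region] = (), label: str = "") -> None:
        self.label = label
        self.regions: list[Region] = sorted(regions, key=lambda r: (r.start, r.end))

    @classmethod
    def from_tuples(cls, pairs: Iterable[tuple[int, int]], label: str = "") -> "RegionSet":
        return cls([Region(s, e) for s, e in pairs], label=label)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return [(r.start, r.end) for r in self.regions] == [
            (r.start, r.end) for r in other.regions
        ]

    def total_length(self) -> int:
        return sum(len(r) for r in self.regions)

    def merge(self, gap: int = 0) -> "RegionSet":
        """Merge regions separated by at most ``gap`` unannotated positions."""
        merged: list[Region] = []
        for r in self.regions:
            if merged and r.start <= merged[-1].end + gap + 1:
                last = merged[-1]
                merged[-1] = Region(
                    last.start, max(last.end, r.end), last.label or r.label
                )
            else:
                merged.append(r)
        return RegionSet(merged, label=self.label)

    def filter_min_length(self, min_len: int) -> "RegionSet":
        return RegionSet(
            [r for r in self.regions if len(r) >= min_len], label=self.label
        )

    def intersect(self, other: "RegionSet") -> "RegionSet":
        """Pairwise interval intersections of two region sets."""
        out = []
        for a in self.regions:
            for b in other.regions:
                c = a.intersect(b)
                if c is not None:
                    out.append(c)
        return RegionSet(out).merge(0)

    def to_mask(self, length: int) -> np.ndarray:
        """Boolean membership vector of the given molecule length."""
        m = np.zeros(length, dtype=bool)
        for r in self.regions:
            m[r.start - 1 : r.end] = True
        return m

    @classmethod
    def from_mask(cls, mask: np.ndarray, label: str = "") -> "RegionSet":
        mask = np.asarray(mask, dtype=bool)
        out, start = [], None
        for i, v in enumerate(mask):
            if v and start is None:
                start = i + 1
            elif not v and start is not None:
                out.append(Region(start, i))
                start = None
        if start is not None:
            out.append(Region(start, len(mask)))
        return cls(out, label=label)

    def jaccard(self, other: "RegionSet", length: int) -> float:
        """Jaccard index of nucleotide coverage between two region sets."""
        a, b = self.to_mask(length), other.to_mask(length)
        union = np.sum(a | b)
        return float(np.sum(a & b) / union) if union else 1.0

    def __repr__(self) -> str:
        spans = ", ".join(f"{r.start}-{r.end}" for r in self.regions[:6])
        more = "…" if len(self.regions) > 6 else ""
        return f"RegionSet({self.label!r}: [{spans}{more}], n={len(self.regions)})"
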