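"""BED-style genomic intervals (0-based, half-open).

A thin, sorted container used for enhancer tracks, coding masks and TSS
tables.  Operations are the handful the pipeline needs: subtraction,
overlap queries and merging; anything fancier belongs to a dedicated
interval library.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .datamodel import ValidationError


@dataclass(frozen=True, order=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end}: start >= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """A sorted collection of :class:`Interval` records."""

    def __init__(self, intervals: Iterable[Interval] = ()):
        self.intervals: list[Interval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def by_chrom(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def chroms(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}

    def merged(self) -> "IntervalSet":
        """Union of the intervals as maximal non-overlapping pieces
        (names/scores dropped)."""
        out: list[Interval] = []
        for chrom, ivs in sorted(self.by_chrom().items()):
            cur_s, cur_e = ivs[0].start, ivs[0].end
            for iv in ivs[1:]:
                if iv.start <= cur_e:
                    cur_e = max(cur_e, iv.end)
                else:
                    out.append(Interval(chrom, cur_s, cur_e))
                    cur_s, cur_e = iv.start, iv.end
            out.append(Interval(chrom, cur_s, cur_e))
        return IntervalSet(out)

    def subtract_from(self, chrom: str, start: int, end: int) -> list[tuple[int, int]]:
        """Pieces of [start, end) on ``chrom`` not covered by this set."""
        pieces: list[tuple[int, int]] = []
        pos = start
        for iv in self.merged().by_chrom().get(chrom, []):
            if iv.end <= pos or iv.start >= end:
                continue
            if iv.start > pos:
                pieces.append((pos, iv.start))
            pos = max(pos, iv.end)
            if pos >= end:
                break
        if pos < end:
            pieces.append((pos, end))
        return pieces

    def overlapping(
        self, chrom: str, start: int, end: int, min_score: float | None = None
    ) -> list[Interval]:
        """Intervals overlapping [start, end) by >= 1 bp, optionally with
        score strictly greater than ``min_score``."""
        hits = []
        for iv in self.by_chrom().get(chrom, []):
            if iv.start >= end:
                break
            if iv.end > start:
                if min_score is None or (iv.score is not None and iv.score > min_score):
                    hits.append(iv)
        return hits

    def overlaps_any(
        self, chrom: str, start: int, end: int, min_score: float | None = None
    ) -> bool:
        return bool(self.overlapping(chrom, start, end, min_score=min_score))
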