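"""Core genomic domain types and interval arithmetic.

Every coordinate in this package is 0-based, half-open (BED convention).
Inputs in 1-based inclusive dialects are converted on ingest by the readers
in :mod:`zicreg.io`; nothing downstream ever sees another convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

STRANDS = {"+", "-", "."}


class ValidationError(ValueError):
    """Raised when a record violates a coordinate or value invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("interval chromosome name is empty")
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class PeakCall:
    """One called binding site with its summit, score and stage label."""

    peak_id: str
    interval: GenomicInterval
    summit: int
    score: float
    stage: str
    qvalue: Optional[float] = None
    repeat_fraction: Optional[float] = None

    def __post_init__(self):
        if not self.interval.contains(self.summit):
            raise ValidationError(
                f"peak {self.peak_id}: summit {self.summit} outside "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.repeat_fraction is not None and not 0 <= self.repeat_fraction <= 1:
            raise ValidationError(
                f"peak {self.peak_id}: repeat_fraction {self.repeat_fraction}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene collapsed to one representative (longest) transcript.

    The TSS is strand-aware: the transcript start for ``+`` genes and the
    last transcript base (``end - 1``) for ``-`` genes.
    """

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self):
        if self.interval.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id} has no strand")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1


class IntervalSet:
    """An immutable set of disjoint intervals with fast coverage queries.

    Overlapping or adjacent input intervals are merged.  Used for repeat
    masks, blacklists and similar genome annotations.
    """

    def __init__(self, intervals: Iterable[tuple] = ()):
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            if isinstance(iv, GenomicInterval):
                chrom, start, end = iv.chrom, iv.start, iv.end
            else:
                chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            if end <= start:
                raise ValidationError(f"empty interval {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end))
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([m[0] for m in merged], dtype=np.int64)
            ends = np.array([m[1] for m in merged], dtype=np.int64)
            cum = np.concatenate([[0], np.cumsum(ends - starts)])
            self._data[chrom] = (starts, ends, cum)

    @classmethod
    def from_bed(cls, path) -> "IntervalSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split()
                rows.append((f[0], int(f[1]), int(f[2])))
        return cls(rows)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom in self.chroms:
            starts, ends, _ = self._data[chrom]
            out.extend(
                GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)
            )
        return out

    def total_bases(self) -> int:
        return sum(int(cum[-1]) for _, _, cum in self._data.values())

    def coverage(self, chrom: str, start: int, end: int) -> int:
        """Number of bases of [start, end) covered by the set."""
        if chrom not in self._data or end <= start:
            return 0
        starts, ends, cum = self._data[chrom]
        i = int(np.searchsorted(ends, start, side="right"))
        j = int(np.searchsorted(starts, end, side="left"))
        if i >= j:
            return 0
        total = int(cum[j] - cum[i])
        total -= max(0, start - int(starts[i]))
        total -= max(0, int(ends[j - 1]) - end)
        return total

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.coverage(chrom, start, end) > 0


def merge_intervals(
    intervals: Sequence[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Merge strictly overlapping (start, end) pairs; touching pairs stay apart."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s < out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]
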