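"""Step-valued genomic tracks: ChIP signal coverage and cross-species identity.

Tracks are stored per chromosome as sorted, non-overlapping constant-value
steps with a precomputed running integral, so interval sums are O(log n)
regardless of chromosome length.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np

from .core import ValidationError

log = logging.getLogger(__name__)


class StepTrack:
    """Base class: per-chromosome (starts, ends, values) step function."""

    def __init__(self, steps: dict[str, Iterable[tuple[int, int, float]]]):
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rows in steps.items():
            rows = sorted((int(s), int(e), float(v)) for s, e, v in rows)
            if not rows:
                continue
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=np.float64)
            if np.any(ends <= starts):
                raise ValidationError(f"{chrom}: step with end <= start")
            if np.any(starts[1:] < ends[:-1]):
                k = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValidationError(
                    f"{chrom}: overlapping steps at "
                    f"[{starts[k]},{ends[k]}) and [{starts[k + 1]},{ends[k + 1]})"
                )
            self._validate_values(chrom, values)
            cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            self._data[chrom] = (starts, ends, values, cum)
        if not self._data:
            log.warning("track is empty")

    def _validate_values(self, chrom: str, values: np.ndarray) -> None:
        if np.any(values < 0):
            raise ValidationError(f"{chrom}: negative track values")

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def extent(self, chrom: str) -> int:
        """Rightmost covered coordinate on ``chrom`` (0 if absent)."""
        if chrom not in self._data:
            return 0
        return int(self._data[chrom][1][-1])

    def steps(self, chrom: str) -> list[tuple[int, int, float]]:
        if chrom not in self._data:
            return []
        starts, ends, values, _ = self._data[chrom]
        return [(int(s), int(e), float(v)) for s, e, v in zip(starts, ends, values)]

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        """Integral of the step function over [start, end)."""
        if chrom not in self._data or end <= start:
            return 0.0
        starts, ends, values, cum = self._data[chrom]
        i = int(np.searchsorted(ends, start, side="right"))
        j = int(np.searchsorted(starts, end, side="left"))
        if i >= j:
            return 0.0
        total = float(cum[j] - cum[i])
        total -= float(values[i]) * max(0, start - int(starts[i]))
        total -= float(values[j - 1]) * max(0, int(ends[j - 1]) - end)
        return total

    def to_dense(self, chrom: str, length: Optional[int] = None) -> np.ndarray:
        """Per-base value array (uncovered bases are 0)."""
        n = self.extent(chrom) if length is None else int(length)
        arr = np.zeros(n, dtype=np.float64)
        if chrom in self._data:
            starts, ends, values, _ = self._data[chrom]
            for s, e, v in zip(starts, ends, values):
                if s >= n:
                    break
                arr[s : min(int(e), n)] = v
        return arr

    @classmethod
    def from_dense(cls, arrays: dict[str, np.ndarray], **kwargs) -> "StepTrack":
        """Run-length encode per-base arrays.

        Zero runs are kept: an explicit zero (e.g. an aligned base with no
        identity) is data, and the track extent must cover it.
        """
        steps: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, arr in arrays.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.size == 0:
                steps[chrom] = []
                continue
            bounds = np.concatenate(
                [[0], np.flatnonzero(np.diff(arr)) + 1, [arr.size]]
            )
            steps[chrom] = [
                (int(s), int(e), float(arr[s]))
                for s, e in zip(bounds[:-1], bounds[1:])
            ]
        return cls(steps, **kwargs)


class SignalTrack(StepTrack):
    """ChIP-seq coverage with a library size for per-million normalization."""

    def __init__(self, steps, library_size: float):
        if library_size <= 0:
            raise ValidationError("library_size must be > 0")
        self.library_size = float(library_size)
        super().__init__(steps)

    @classmethod
    def from_dense(cls, arrays, library_size=None):
        if library_size is None:
            library_size = sum(float(np.sum(a)) for a in arrays.values())
        return super().from_dense(arrays, library_size=library_size)


class IdentityTrack(StepTrack):
    """Per-base cross-species identity fraction versus one comparator species.

    Bases without an alignment carry identity 0; values must lie in [0, 1].
    """

    def __init__(self, steps, comparator: str = "unknown"):
        self.comparator = comparator
        super().__init__(steps)

    def _validate_values(self, chrom: str, values: np.ndarray) -> None:
        bad = (values < 0) | (values > 1)
        if np.any(bad):
            k = int(np.argmax(bad))
            raise ValidationError(
                f"{chrom}: identity value {values[k]} outside [0, 1]"
            )

    @classmethod
    def from_dense(cls, arrays, comparator="unknown"):
        return super().from_dense(arrays, comparator=comparator)
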