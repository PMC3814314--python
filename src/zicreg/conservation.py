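"""Conserved non-coding element (CNE) detection and peak overlap.

A CNE is a maximal interval of length >= ``window`` bp (default 50) in
which *every* sliding window of ``window`` bp has mean per-base identity
of at least ``min_identity`` (default 0.70) against the comparator
species.  Peak summits extended by 500 bp on each side are then
intersected with the CNE coordinates of each comparator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, PeakCall, ValidationError
from .tracks import IdentityTrack


@dataclass(frozen=True)
class Cne:
    interval: GenomicInterval
    comparator: str
    mean_identity: float


def call_cnes(
    track: IdentityTrack,
    min_identity: float = 0.70,
    window: int = 50,
) -> list[Cne]:
    """All maximal intervals whose every ``window``-bp sub-window passes.

    Runs in O(n) per chromosome via prefix sums: a window starting at i is
    admissible iff its mean identity >= min_identity, and a maximal run of
    admissible starts i0..i1 yields the CNE [i0, i1 + window).
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    out: list[Cne] = []
    for chrom in track.chroms:
        dense = track.to_dense(chrom)
        n = dense.size
        if n < window:
            continue
        prefix = np.concatenate([[0.0], np.cumsum(dense)])
        wsums = prefix[window:] - prefix[:-window]
        ok = wsums >= min_identity * window - 1e-9
        if not ok.any():
            continue
        padded = np.concatenate([[False], ok, [False]])
        d = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)  # exclusive in "start" space
        for s, e in zip(run_starts, run_ends):
            lo, hi = int(s), int(e) - 1 + window
            mean_id = float((prefix[hi] - prefix[lo]) / (hi - lo))
            out.append(
                Cne(GenomicInterval(chrom, lo, hi), track.comparator, mean_id)
            )
    return out


def overlap_peaks_cnes(
    peaks: Sequence[PeakCall],
    cnes_by_comparator: Mapping[str, Iterable[Cne]],
    flank: int = 500,
) -> tuple[pd.DataFrame, dict[str, int], int]:
    """Flag peaks whose extended summit overlaps a CNE of each comparator.

    The summit is extended by ``flank`` bp on each side (half-open window
    [summit - flank, summit + flank)); any >= 1 bp overlap counts.  Returns
    a per-peak flag table, per-comparator flagged counts, and the count of
    peaks flagged for *all* comparators.
    """
    comparators = sorted(cnes_by_comparator)
    from .core import IntervalSet

    sets = {
        c: IntervalSet(
            (cne.interval.chrom, cne.interval.start, cne.interval.end)
            for cne in cnes_by_comparator[c]
        )
        for c in comparators
    }
    rows = []
    for p in peaks:
        lo = max(0, p.summit - flank)
        hi = p.summit + flank
        row = {"peak_id": p.peak_id}
        for c in comparators:
            row[c] = sets[c].overlaps(p.chrom, lo, hi)
        rows.append(row)
    flags = pd.DataFrame(rows, columns=["peak_id", *comparators])
    counts = {c: int(flags[c].sum()) for c in comparators}
    in_all = int(flags[comparators].all(axis=1).sum()) if comparators else 0
    return flags, counts, in_all
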