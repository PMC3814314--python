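"""Peak filtering and genomic-location classification.

Peaks overlapping a blacklist (unassembled contigs, centromeres, telomeres,
segmental duplications) or consisting of more than 70% repeat sequence are
removed.  Surviving peaks are classified by their summit as promoter
(within 5 kb upstream of a TSS), intragenic, or intergenic, with promoter
taking precedence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import GeneAnnotation, IntervalSet, PeakCall, ValidationError

LOCATION_CLASSES = ("promoter", "intragenic", "intergenic")


def compute_repeat_fraction(peak: PeakCall, repeat_mask: IntervalSet) -> float:
    """Fraction of the peak interval covered by the repeat mask."""
    iv = peak.interval
    return repeat_mask.coverage(iv.chrom, iv.start, iv.end) / iv.length


@dataclass(frozen=True)
class RemovalRecord:
    peak_id: str
    reason: str  # "blacklist" or "repeat"
    detail: str


def filter_peaks(
    peaks: Iterable[PeakCall],
    blacklist: Optional[IntervalSet] = None,
    repeat_mask: Optional[IntervalSet] = None,
    max_repeat_fraction: float = 0.70,
    blacklist_chroms: Sequence[str] = (),
) -> tuple[list[PeakCall], list[RemovalRecord]]:
    """Remove blacklisted and repeat-dominated peaks.

    A peak is removed iff (a) its interval overlaps any blacklist interval
    by >= 1 bp or sits on a blacklisted chromosome, or (b) its repeat
    fraction strictly exceeds ``max_repeat_fraction`` (a fraction of
    exactly 0.70 is retained).  The removal log records one reason per
    removed peak; the repeat fraction is stored on every peak.
    """
    blacklist = blacklist or IntervalSet()
    repeat_mask = repeat_mask or IntervalSet()
    bl_chroms = set(blacklist_chroms)
    retained: list[PeakCall] = []
    removed: list[RemovalRecord] = []
    for p in peaks:
        p.repeat_fraction = compute_repeat_fraction(p, repeat_mask)
        iv = p.interval
        if iv.chrom in bl_chroms or blacklist.overlaps(iv.chrom, iv.start, iv.end):
            removed.append(RemovalRecord(p.peak_id, "blacklist", iv.chrom))
        elif p.repeat_fraction > max_repeat_fraction:
            removed.append(
                RemovalRecord(p.peak_id, "repeat", f"{p.repeat_fraction:.3f}")
            )
        else:
            retained.append(p)
    return retained, removed


def _promoter_windows(
    genes: Iterable[GeneAnnotation], upstream: int, downstream: int
) -> IntervalSet:
    """Strand-aware promoter windows around each TSS.

    For a + gene the window is [tss - upstream, tss + downstream); for a -
    gene the mirror image [tss - downstream + 1, tss + upstream + 1).  With
    ``downstream = 0`` the window is strictly upstream and excludes the TSS
    base itself.
    """
    rows = []
    for g in genes:
        t = g.tss
        if g.strand == "+":
            s, e = t - upstream, t + downstream
        else:
            s, e = t - downstream + 1, t + upstream + 1
        s = max(0, s)
        if e > s:
            rows.append((g.chrom, s, e))
    return IntervalSet(rows)


class LocationClassifier:
    """Classifies summits as promoter / intragenic / intergenic.

    ``promoter_downstream=0`` (default) implements the upstream-only
    promoter definition; set it to 5000 for a symmetric +/-5 kb window.
    """

    def __init__(
        self,
        genes: Sequence[GeneAnnotation],
        promoter_upstream: int = 5000,
        promoter_downstream: int = 0,
    ):
        self.promoters = _promoter_windows(
            genes, promoter_upstream, promoter_downstream
        )
        self.gene_spans = IntervalSet(
            (g.chrom, g.interval.start, g.interval.end) for g in genes
        )

    def classify(self, peak: PeakCall) -> str:
        pos = peak.summit
        if self.promoters.overlaps(peak.chrom, pos, pos + 1):
            return "promoter"
        if self.gene_spans.overlaps(peak.chrom, pos, pos + 1):
            return "intragenic"
        return "intergenic"


def classify_location(
    peak: PeakCall,
    genes: Sequence[GeneAnnotation],
    promoter_upstream: int = 5000,
    promoter_downstream: int = 0,
) -> str:
    return LocationClassifier(
        genes, promoter_upstream, promoter_downstream
    ).classify(peak)


def location_distribution(
    peaks: Sequence[PeakCall],
    genes: Sequence[GeneAnnotation],
    promoter_upstream: int = 5000,
    promoter_downstream: int = 0,
) -> tuple[dict[str, int], dict[str, float]]:
    """Counts and fractions of peaks per location class (fractions sum to 1)."""
    if not peaks:
        raise ValidationError("no peaks: location distribution undefined")
    clf = LocationClassifier(genes, promoter_upstream, promoter_downstream)
    counts = {c: 0 for c in LOCATION_CLASSES}
    for p in peaks:
        counts[clf.classify(p)] += 1
    n = len(peaks)
    return counts, {c: counts[c] / n for c in LOCATION_CLASSES}


def distance_to_tss_histogram(
    distances: Sequence[float], bin_edges: Sequence[float]
) -> np.ndarray:
    """Histogram of signed summit-to-TSS distances (upstream negative).

    ``distances`` come from the association module (one per assigned peak,
    nearest gene); counts over the bins sum to the number of distances
    falling inside the binned range.
    """
    counts, _ = np.histogram(np.asarray(distances, dtype=float), bins=bin_edges)
    return counts
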