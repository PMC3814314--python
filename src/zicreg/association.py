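"""Peak-to-gene association.

Two rules are provided, both summit-based:

* the GREAT-style "basal plus extension" rule — each gene owns a basal
  window (5 kb upstream / 1 kb downstream of its TSS, strand-aware)
  extended up to 100 kb on each side but stopping at the nearest other
  gene's basal boundary; a peak is assigned to every gene whose extended
  domain contains its summit;
* a fixed-radius TSS rule — a gene is associated with every peak whose
  summit lies within ``radius`` bp of its TSS (strand-ignoring, inclusive),
  used for direct-target calling at 100 kb and 500 kb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core import GeneAnnotation, GenomicInterval, PeakCall, ValidationError


@dataclass(frozen=True)
class RegulatoryDomain:
    """Basal-plus-extension regulatory domain owned by one gene."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    basal: tuple[int, int]
    extended: tuple[int, int]

    def __post_init__(self):
        bs, be = self.basal
        es, ee = self.extended
        if not (es <= bs < be <= ee):
            raise ValidationError(
                f"domain {self.gene_id}: basal {self.basal} not inside "
                f"extended {self.extended}"
            )


@dataclass(frozen=True)
class PeakGeneAssignment:
    """Genes assigned to one peak with signed summit-to-TSS distances."""

    peak_id: str
    genes: tuple[tuple[str, int], ...]  # (gene_id, signed distance)


def signed_distance(summit: int, gene: GeneAnnotation) -> int:
    """Summit minus TSS, negated for - strand genes (upstream negative)."""
    d = summit - gene.tss
    return -d if gene.strand == "-" else d


def _basal_window(gene: GeneAnnotation, up: int, down: int) -> tuple[int, int]:
    t = gene.tss
    if gene.strand == "+":
        return t - up, t + down
    return t - down + 1, t + up + 1


def build_regulatory_domains(
    genes: Sequence[GeneAnnotation],
    chrom_sizes: dict[str, int],
    basal_up: int = 5000,
    basal_down: int = 1000,
    extension: int = 100000,
) -> list[RegulatoryDomain]:
    """Build basal-plus-extension domains, clamped to chromosome bounds.

    Extension on each side runs to ``extension`` bp beyond the basal window
    but stops at the nearest other gene's basal boundary (of any strand),
    and never shrinks below the gene's own basal window.
    """
    domains: list[RegulatoryDomain] = []
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValidationError(f"unknown chromosome length for {g.chrom}")
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        L = chrom_sizes[chrom]
        basals = [_basal_window(g, basal_up, basal_down) for g in gs]
        starts = np.array(sorted(max(0, b[0]) for b in basals))
        ends = np.array(sorted(min(L, b[1]) for b in basals))
        for g, (bs, be) in zip(gs, basals):
            bs, be = max(0, bs), min(L, be)
            # nearest other-gene basal end at or left of our basal start
            i = int(np.searchsorted(ends, bs, side="right"))
            left_block = int(ends[i - 1]) if i > 0 else 0
            # nearest other-gene basal start at or right of our basal end
            j = int(np.searchsorted(starts, be, side="left"))
            right_block = int(starts[j]) if j < len(starts) else L
            es = max(bs - extension, left_block, 0)
            ee = min(be + extension, right_block, L)
            domains.append(
                RegulatoryDomain(
                    g.gene_id, chrom, g.strand, g.tss, (bs, be), (max(0, min(es, bs)), max(be, min(ee, L)))
                )
            )
    return domains


def associate_peaks_great(
    peaks: Iterable[PeakCall],
    domains: Sequence[RegulatoryDomain],
    genes: Sequence[GeneAnnotation],
) -> list[PeakGeneAssignment]:
    """Assign each peak to every gene whose extended domain holds its summit."""
    gene_map = {g.gene_id: g for g in genes}
    trees: dict[str, IntervalTree] = {}
    for d in domains:
        trees.setdefault(d.chrom, IntervalTree()).addi(
            d.extended[0], d.extended[1], d.gene_id
        )
    out = []
    for p in peaks:
        found = []
        tree = trees.get(p.chrom)
        if tree is not None:
            for iv in tree.at(p.summit):
                g = gene_map[iv.data]
                found.append((g.gene_id, signed_distance(p.summit, g)))
        found.sort(key=lambda x: (abs(x[1]), x[0]))
        out.append(PeakGeneAssignment(p.peak_id, tuple(found)))
    return out


def association_summary(
    assignments: Sequence[PeakGeneAssignment],
) -> dict[str, float]:
    """Fractions of peaks associated with none, one, or two-plus genes."""
    if not assignments:
        raise ValidationError("no assignments to summarize")
    n = len(assignments)
    counts = {"none": 0, "one": 0, "two_plus": 0}
    for a in assignments:
        k = len(a.genes)
        counts["none" if k == 0 else "one" if k == 1 else "two_plus"] += 1
    return {key: c / n for key, c in counts.items()}


def associate_peaks_radius(
    peaks: Sequence[PeakCall],
    genes: Sequence[GeneAnnotation],
    radius: int = 100000,
    from_summit: bool = True,
) -> dict[str, list[tuple[str, int]]]:
    """gene_id -> [(peak_id, signed distance)] for peaks within ``radius``.

    Distance is |summit - TSS| (strand-ignoring, boundary inclusive).  With
    ``from_summit=False`` the nearest peak-interval edge is used instead of
    the summit, with distance 0 for a TSS inside the peak.
    """
    by_chrom: dict[str, list[tuple[int, GeneAnnotation]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g))
    out: dict[str, list[tuple[str, int]]] = {g.gene_id: [] for g in genes}
    for chrom, items in by_chrom.items():
        items.sort(key=lambda x: x[0])
        tss_arr = np.array([t for t, _ in items])
        for p in peaks:
            if p.chrom != chrom:
                continue
            if from_summit:
                lo_q, hi_q = p.summit - radius, p.summit + radius
            else:
                lo_q, hi_q = p.interval.start - radius, p.interval.end - 1 + radius
            i = int(np.searchsorted(tss_arr, lo_q, side="left"))
            j = int(np.searchsorted(tss_arr, hi_q, side="right"))
            for t, g in items[i:j]:
                if not from_summit and p.interval.contains(t):
                    pass  # distance 0, always within radius
                elif not from_summit:
                    edge = min(abs(p.interval.start - t), abs(p.interval.end - 1 - t))
                    if edge > radius:
                        continue
                out[g.gene_id].append((p.peak_id, signed_distance(p.summit, g)))
    return out


def nearest_gene_distances(
    assignments: Sequence[PeakGeneAssignment],
) -> list[int]:
    """One signed distance per assigned peak: its nearest associated gene."""
    out = []
    for a in assignments:
        if a.genes:
            out.append(min((abs(d), d) for _, d in a.genes)[1])
    return out
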