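"""Differential-expression filtering and direct-target calling.

A gene is a direct-target call when it passes the stage's fold-change and
p-value thresholds *and* has at least one binding peak within the
association radius (default 100 kb) of its TSS.  The printed strictness of
each stage's thresholds is reproduced exactly: the morphant contrast uses
FC > 1.2 (strict) with p <= 0.05, the sorted-cell enriched contrast uses
FC >= 1.5 with p < 0.05 (strict), and the sorted-cell depleted contrast
uses FC >= 2 with no p filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import ValidationError

#: Stage presets reproducing each contrast's printed thresholds.
PRESETS: dict[str, dict] = {
    "8hpf": dict(fc_threshold=1.2, fc_inclusive=False, p_threshold=0.05, p_inclusive=True),
    "24hpf_coexpressed": dict(fc_threshold=1.5, fc_inclusive=True, p_threshold=0.05, p_inclusive=False),
    "24hpf_depleted": dict(fc_threshold=2.0, fc_inclusive=True, p_threshold=None, p_inclusive=False),
}


def select_de_genes(
    records: pd.DataFrame,
    fc_threshold: Optional[float] = None,
    fc_inclusive: bool = False,
    p_threshold: Optional[float] = None,
    p_inclusive: bool = True,
    preset: Optional[str] = None,
    adjust: str = "none",
) -> pd.DataFrame:
    """Filter an expression table to differentially expressed genes.

    ``records`` needs columns gene_id, fold_change, direction, p_value.
    Either give thresholds explicitly or name a ``preset``; a p_threshold
    of None disables the p filter.  ``adjust="bh"`` applies a
    Benjamini-Hochberg correction before the p filter (default: raw
    p-values, matching the printed thresholds).
    """
    if preset is not None:
        if preset not in PRESETS:
            raise ValidationError(
                f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
            )
        cfg = PRESETS[preset]
        fc_threshold = cfg["fc_threshold"]
        fc_inclusive = cfg["fc_inclusive"]
        p_threshold = cfg["p_threshold"]
        p_inclusive = cfg["p_inclusive"]
    if fc_threshold is None or fc_threshold <= 0:
        raise ValidationError("fc_threshold must be positive")
    fc = records["fold_change"].to_numpy()
    keep = fc >= fc_threshold if fc_inclusive else fc > fc_threshold
    if adjust not in {"none", "bh"}:
        raise ValidationError("adjust must be 'none' or 'bh'")
    if p_threshold is not None:
        if p_threshold <= 0:
            raise ValidationError("p_threshold must be positive")
        p = records["p_value"].to_numpy(dtype=float)
        if adjust == "bh":
            from scipy.stats import false_discovery_control

            p = false_discovery_control(p, method="bh")
        keep &= p <= p_threshold if p_inclusive else p < p_threshold
    return records.loc[keep].reset_index(drop=True)


@dataclass(frozen=True)
class TargetCall:
    gene_id: str
    direction: str  # "up" or "down"
    stage: str
    radius: int
    peaks: tuple[tuple[str, int], ...]  # (peak_id, signed distance)


def call_targets(
    de_genes: pd.DataFrame,
    association: Mapping[str, Sequence[tuple[str, int]]],
    known_genes: set[str],
    stage: str,
    radius: int = 100000,
) -> tuple[list[TargetCall], int]:
    """Join DE genes with peak associations; returns (targets, n_skipped).

    ``association`` maps gene_id -> [(peak_id, distance)] from the
    radius-rule association.  DE genes absent from the annotation are
    skipped with a count (they cannot be placed on the genome).
    """
    targets: list[TargetCall] = []
    skipped = 0
    for row in de_genes.itertuples(index=False):
        gid = row.gene_id
        if gid not in known_genes:
            skipped += 1
            continue
        peaks = tuple(association.get(gid, ()))
        if peaks:
            targets.append(TargetCall(gid, row.direction, stage, radius, peaks))
    return targets, skipped


def summarize_run(stage_reports: Mapping[str, Mapping]) -> pd.DataFrame:
    """Assemble per-stage pipeline counts into one tidy report table.

    ``stage_reports`` maps a stage label to a flat dict of metrics
    (raw/filtered peak counts, location fractions, motif fraction, class
    counts, CNE counts, DE and target counts ...).  Missing metrics are
    reported as 0 so an empty run yields an all-zero table.
    """
    keys: list[str] = []
    for rep in stage_reports.values():
        for k in rep:
            if k not in keys:
                keys.append(k)
    rows = []
    for stage, rep in stage_reports.items():
        row = {"stage": stage}
        for k in keys:
            row[k] = rep.get(k, 0)
        rows.append(row)
    return pd.DataFrame(rows, columns=["stage", *keys])


def format_report(report: pd.DataFrame) -> str:
    """Human-readable rendering of :func:`summarize_run`'s table."""
    lines = []
    for row in report.itertuples(index=False):
        lines.append(f"stage {row.stage}")
        for k in report.columns[1:]:
            v = getattr(row, k)
            if isinstance(v, float):
                lines.append(f"  {k:<28s} {v:.4g}")
            else:
                lines.append(f"  {k:<28s} {v}")
    return "\n".join(lines) + "\n"
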