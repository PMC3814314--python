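"""End-to-end run of the regulatory-genomics analysis on one dataset.

Thin orchestration over the per-step modules: filter peaks, classify
locations, calibrate and scan the consensus motif, merge and classify
two-stage binding regions, call CNEs and overlap them with peaks, filter
expression and call direct targets, then summarize.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import association, conservation, motifs, peaks as pk, stages, targets
from .core import IntervalSet
from .simulate import STAGE_A, STAGE_B, SyntheticDataset
from .tracks import IdentityTrack


@dataclass
class StageResult:
    stage: str
    n_raw_peaks: int
    retained: list
    removed: list
    location_fractions: dict[str, float]
    motif_fraction: float
    motif_hits: list
    de_genes: pd.DataFrame
    target_calls: list
    report: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    per_stage: dict[str, StageResult]
    classified_regions: list
    class_counts: dict[str, int]
    cne_flags: pd.DataFrame
    cne_counts: dict[str, int]
    threshold: motifs.CalibratedThreshold
    summary: pd.DataFrame


def run_pipeline(
    dataset: SyntheticDataset,
    seed: int = 0,
    radius: int = 100_000,
    bound_fold: float = 5.0,
    de_preset_by_stage: Optional[dict[str, str]] = None,
    pwm: Optional[motifs.Pwm] = None,
) -> PipelineResult:
    """Run every analysis step on a (synthetic or loaded) dataset."""
    cfg = dataset.config
    de_preset_by_stage = de_preset_by_stage or {
        STAGE_A: "8hpf",
        STAGE_B: "24hpf_coexpressed",
    }
    if pwm is None:
        import zicreg

        packaged = zicreg.zic3_consensus_pwm()
        if packaged.consensus == cfg.consensus:
            pwm = packaged
        else:
            pwm = motifs.Pwm.from_consensus(
                cfg.consensus, dominance=0.94, name="consensus"
            )
    rng = np.random.default_rng(seed)
    genome_seqs = dataset.sequences()
    known_genes = {g.gene_id for g in dataset.genes}

    calib = motifs.calibrate_threshold(pwm, n=10_000, target_rate=0.85, rng=rng)

    # stage-wise filtering, annotation, motif scan, DE + targets
    per_stage: dict[str, StageResult] = {}
    retained_by_stage = {}
    for stage in (STAGE_A, STAGE_B):
        raw = dataset.peaks[stage]
        retained, removed = pk.filter_peaks(raw, repeat_mask=dataset.repeat_mask)
        retained_by_stage[stage] = retained
        _, fractions = pk.location_distribution(retained, dataset.genes)
        hits, frac = motifs.scan_peaks(
            pwm, calib.threshold, retained, genome_seqs, half_window=400
        )
        expr = dataset.expression[stage]
        de = targets.select_de_genes(expr, preset=de_preset_by_stage[stage])
        assoc = association.associate_peaks_radius(
            retained, dataset.genes, radius=radius
        )
        calls, skipped = targets.call_targets(
            de, assoc, known_genes, stage, radius=radius
        )
        per_stage[stage] = StageResult(
            stage=stage,
            n_raw_peaks=len(raw),
            retained=retained,
            removed=removed,
            location_fractions=fractions,
            motif_fraction=frac,
            motif_hits=hits,
            de_genes=de,
            target_calls=calls,
            report=dict(
                n_raw_peaks=len(raw),
                n_retained=len(retained),
                n_removed=len(removed),
                frac_promoter=fractions["promoter"],
                frac_intragenic=fractions["intragenic"],
                frac_intergenic=fractions["intergenic"],
                motif_fraction=frac,
                n_de=len(de),
                n_targets=len(calls),
                n_targets_up=sum(c.direction == "up" for c in calls),
                n_targets_down=sum(c.direction == "down" for c in calls),
                n_de_skipped=skipped,
            ),
        )

    # two-stage region classification on filtered peaks
    regions = stages.merge_summit_windows(
        retained_by_stage[STAGE_A], retained_by_stage[STAGE_B], flank=2000
    )
    exclude = IntervalSet((r.chrom, r.start, r.end) for r in regions)
    bg_a = stages.estimate_background_density(
        dataset.signal[STAGE_A], exclude, dataset.chrom_sizes, rng=rng
    )
    bg_b = stages.estimate_background_density(
        dataset.signal[STAGE_B], exclude, dataset.chrom_sizes, rng=rng
    )
    classified = stages.classify_stage_binding(
        regions,
        dataset.signal[STAGE_A],
        dataset.signal[STAGE_B],
        STAGE_A,
        STAGE_B,
        rule="fold",
        fold=bound_fold,
        background_a=bg_a,
        background_b=bg_b,
    )
    counts = stages.class_counts(classified)

    # CNE calling + overlap with the early-stage peak set
    cnes = conservation.call_cnes(dataset.identity)
    flags, cne_counts, in_all = conservation.overlap_peaks_cnes(
        retained_by_stage[STAGE_A], {dataset.identity.comparator: cnes}
    )

    for stage in per_stage:
        per_stage[stage].report.update(
            n_class_I=counts["I"], n_class_II=counts["II"], n_class_III=counts["III"]
        )
    per_stage[STAGE_A].report[f"n_cne_{dataset.identity.comparator}"] = cne_counts[
        dataset.identity.comparator
    ]
    summary = targets.summarize_run({s: r.report for s, r in per_stage.items()})
    return PipelineResult(
        per_stage=per_stage,
        classified_regions=classified,
        class_counts=counts,
        cne_flags=flags,
        cne_counts=cne_counts,
        threshold=calib,
        summary=summary,
    )


def target_recovery(
    dataset: SyntheticDataset, result: PipelineResult
) -> dict[str, dict[str, float]]:
    """Recall and false-discovery rate of target calls against the manifest."""
    out = {}
    truth_col = {STAGE_A: "target_8hpf", STAGE_B: "target_24hpf"}
    mg = dataset.manifest_genes
    for stage, res in result.per_stage.items():
        true_set = set(mg.loc[mg[truth_col[stage]], "gene_id"])
        called = {c.gene_id for c in res.target_calls}
        tp = len(called & true_set)
        recall = tp / len(true_set) if true_set else float("nan")
        fdr = (len(called) - tp) / len(called) if called else 0.0
        out[stage] = dict(
            n_true=len(true_set), n_called=len(called), recall=recall, fdr=fdr
        )
    return out
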