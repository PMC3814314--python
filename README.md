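# zicreg

Integrative regulatory-genomics analysis of two-stage transcription-factor
binding, modeled on Zic3 in the zebrafish embryo at gastrula (8 hpf) and
late segmentation (24 hpf).  The package turns ChIP-seq peak calls,
expression perturbation tables and cross-species conservation tracks into
annotated distal-binding landscapes and direct-target-gene calls.  A
ground-truthed synthetic data generator makes every stage of the pipeline
testable end to end without any downloads.

It is written for computational biologists who want a small, fully tested
reference implementation of the classic peak-annotation / target-calling
recipe — and a simulator to probe when that recipe works.

## What the pipeline computes

Given per-stage peak calls with summits `s`, a gene annotation with
strand-aware TSSs `t`, signal tracks, an identity track and expression
tables:

- **Peak filtering** — peaks on blacklisted sequence, or with repeat
  fraction strictly greater than 0.70, are removed.
- **Location classes** — a summit is *promoter* if it lies within 5 kb
  upstream of any TSS (strand-aware), else *intragenic* if inside a
  transcript span, else *intergenic*.
- **Gene association** — two rules: GREAT-style regulatory domains (basal
  `[t−5 kb, t+1 kb)` extended up to 100 kb, stopping at the nearest other
  gene's basal boundary), and a plain radius rule
  `|s − t| ≤ r` with `r` = 100 kb (extendable to 500 kb).
- **Motif occurrence** — log-odds PWM scores
  `Σ_i log2 p_i(b_i)/q(b_i)`, maximized over offsets and strands in
  `[s−400, s+400)`.  The match threshold is *calibrated by simulation*:
  sample 10 000 sequences from the PWM columns and choose the score
  quantile at which 85% of them are detected.
- **Stage comparison** — ±2 kb summit windows from both stages are
  merged; per-region signal density (per kb, per million library units)
  classifies regions as class I (bound both stages), II (8 hpf only) or
  III (24 hpf only), with peaks missed by calling in one stage rescued
  when their density exceeds 5× the genome-wide background.
- **CNEs** — maximal intervals in which *every* 50 bp window has mean
  identity ≥ 0.70; peaks whose summits ±500 bp overlap a CNE are flagged.
- **Target calling** — a gene is a direct-target call when it passes the
  stage's printed expression thresholds (8 hpf morphant: FC > 1.2,
  p ≤ 0.05; 24 hpf co-expressed: FC ≥ 1.5, p < 0.05; 24 hpf depleted:
  FC ≥ 2) *and* has ≥ 1 peak within 100 kb of its TSS.

## Worked example

```python
from zicreg.simulate import SimulationConfig, generate
from zicreg.pipeline import run_pipeline, target_recovery

dataset = generate(SimulationConfig(seed=1))     # 10 Mb, 200 genes, 1000 peaks/stage
result = run_pipeline(dataset, seed=2)
print(result.class_counts)
print({s: r.report["motif_fraction"] for s, r in result.per_stage.items()})
print(target_recovery(dataset, result)["8hpf"])
```

prints

```
{'I': 400, 'II': 239, 'III': 233}
{'8hpf': 0.4905462184873949, '24hpf': 0.4723092998955068}
{'n_true': 199, 'n_called': 198, 'recall': 0.9949748743718593, 'fdr': 0.0}
```

Reading: of 872 merged binding regions, 400 are occupied at both stages
and the rest are stage-specific; about 49% of peaks carry a consensus
motif (the generator plants one in 50% of peaks, and the calibrated scan
adds a ~1.6% chance rate on the remainder while missing a few plants that
fall below threshold after filtering); and the expression-plus-binding
join recovers 198 of 199 true target genes with no false discoveries.

The same steps are available as numbered drivers under `analysis/`
(`01_simulate.py` … `06_targets.py`, run from that directory), which
write their tables to `results/`, and as a CLI
(`zicreg simulate|filter|annotate-location|associate|motif-calibrate|motif-scan|stage-classify|cne-call|cne-overlap|targets`).

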