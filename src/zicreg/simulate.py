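"""Ground-truthed synthetic data for the whole pipeline.

Generates a toy genome (i.i.d. background sequence with AT-dinucleotide
repeat blocks), a spaced gene annotation, two stages of summit-annotated
peak calls with triangular signal bumps, planted consensus motifs, a
cross-species identity track with conserved islands, and per-stage
expression tables whose differentially expressed genes are causally linked
to nearby planted peaks.  Every planted feature is recorded in a manifest
so each pipeline stage can be scored against known truth.

The default configuration is the study condition used throughout the test
suite: a 10 Mb genome over 5 chromosomes, 200 genes, 1000 peaks per stage,
30% stage-shared binding, a 50% motif plant rate, peak placement biased to
distal intergenic positions (10/30/60% promoter/intragenic/intergenic),
and a 4-fold expression effect on true targets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import GeneAnnotation, GenomicInterval, IntervalSet, PeakCall, ValidationError
from .motifs import BASES, Pwm, encode
from .tracks import IdentityTrack, SignalTrack
from . import io as zio

STAGE_A = "8hpf"
STAGE_B = "24hpf"


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the standard study condition."""

    genome_size: int = 10_000_000
    n_chroms: int = 5
    n_genes: int = 200
    n_peaks_per_stage: int = 1000
    frac_shared_peaks: float = 0.3
    motif_plant_rate: float = 0.5
    distance_mixture: tuple[float, float, float] = (0.1, 0.3, 0.6)
    n_cnes: int = 50
    cne_identity: float = 0.9
    background_identity: float = 0.3
    cne_near_peak_frac: float = 0.5
    de_effect: float = 4.0
    noise_sd: float = 0.1
    repeat_frac_rate: float = 0.05
    seed: int = 0
    # geometry and nuisance parameters
    min_gene_spacing: int = 20_000
    gene_length_range: tuple[int, int] = (2_000, 15_000)
    peak_halfwidth_range: tuple[int, int] = (250, 350)
    summit_jitter: int = 25
    min_summit_spacing: int = 900
    signal_bump_halfwidth: int = 300
    signal_bump_height: float = 100.0
    background_signal: float = 1.0
    signal_bin: int = 100
    cne_length_range: tuple[int, int] = (80, 250)
    target_p_alpha: float = 0.005
    comparator: str = "tetraodon"
    consensus: str = "GCCAGCAGGTGG"

    def __post_init__(self):
        fractions = [
            self.frac_shared_peaks,
            self.motif_plant_rate,
            self.cne_identity,
            self.background_identity,
            self.cne_near_peak_frac,
            self.repeat_frac_rate,
            *self.distance_mixture,
        ]
        if any(not 0 <= f <= 1 for f in fractions):
            raise ValidationError("all fractions must lie in [0, 1]")
        if abs(sum(self.distance_mixture) - 1) > 1e-9:
            raise ValidationError("distance_mixture must sum to 1")
        if min(self.genome_size, self.n_chroms, self.n_peaks_per_stage) <= 0:
            raise ValidationError("counts must be positive")
        if self.n_genes < 0 or self.n_cnes < 0:
            raise ValidationError("counts must be non-negative")
        if self.de_effect < 1:
            raise ValidationError("de_effect must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("distance_mixture", "gene_length_range",
                    "peak_halfwidth_range", "cne_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    chrom_sizes: dict[str, int]
    genome_codes: dict[str, np.ndarray]
    genes: list[GeneAnnotation]
    repeat_mask: IntervalSet
    peaks: dict[str, list[PeakCall]]
    signal: dict[str, SignalTrack]
    identity: IdentityTrack
    expression: dict[str, pd.DataFrame]
    manifest_peaks: pd.DataFrame
    manifest_genes: pd.DataFrame
    manifest_cnes: pd.DataFrame

    def sequences(self) -> dict[str, str]:
        return {c: "".join(BASES[i] for i in codes) for c, codes in self.genome_codes.items()}

    def write(self, outdir) -> dict[str, Path]:
        """Emit all files (FASTA, GFF3, BED, bedGraph, TSV, manifest)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["genome"] = outdir / "genome.fa"
        zio.write_fasta(self.sequences(), paths["genome"])
        paths["genes"] = outdir / "genes.gff3"
        zio.write_gene_annotation(self.genes, paths["genes"])
        with open(outdir / "repeat_mask.bed", "w") as fh:
            for iv in self.repeat_mask.intervals():
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\trepeat\n")
        paths["repeat_mask"] = outdir / "repeat_mask.bed"
        for stage in (STAGE_A, STAGE_B):
            paths[f"peaks_{stage}"] = outdir / f"peaks_{stage}.bed"
            zio.write_peaks(self.peaks[stage], paths[f"peaks_{stage}"])
            paths[f"signal_{stage}"] = outdir / f"signal_{stage}.bedgraph"
            zio.write_track(self.signal[stage], paths[f"signal_{stage}"])
            paths[f"expression_{stage}"] = outdir / f"expression_{stage}.tsv"
            zio.write_expression(self.expression[stage], paths[f"expression_{stage}"])
        paths["identity"] = outdir / "identity.bedgraph"
        zio.write_track(self.identity, paths["identity"])
        for name, df in (
            ("manifest_peaks", self.manifest_peaks),
            ("manifest_genes", self.manifest_genes),
            ("manifest_cnes", self.manifest_cnes),
        ):
            paths[name] = outdir / f"{name}.tsv"
            df.to_csv(paths[name], sep="\t", index=False, float_format="%.10g")
        paths["config"] = outdir / "config.yaml"
        self.config.to_yaml(paths["config"])
        with open(outdir / "chrom_sizes.json", "w") as fh:
            json.dump(self.chrom_sizes, fh, sort_keys=True)
        paths["chrom_sizes"] = outdir / "chrom_sizes.json"
        return paths


# ---------------------------------------------------------------------------
# genome + genes

def _chrom_sizes(config: SimulationConfig) -> dict[str, int]:
    base = config.genome_size // config.n_chroms
    sizes = {}
    for i in range(config.n_chroms):
        extra = config.genome_size - base * config.n_chroms if i == 0 else 0
        sizes[f"chr{i + 1}"] = base + extra
    return sizes


def generate_genome(
    config: SimulationConfig, rng
) -> tuple[dict[str, int], dict[str, np.ndarray], list[GeneAnnotation], IntervalSet]:
    """Background sequence, spaced genes, and AT-repeat blocks."""
    rng = np.random.default_rng(rng)
    chrom_sizes = _chrom_sizes(config)
    genome = {
        c: rng.integers(0, 4, size=n, dtype=np.int8) for c, n in chrom_sizes.items()
    }
    genes = _place_genes(config, chrom_sizes, rng)
    repeat_mask = _place_repeats(config, chrom_sizes, genes, rng)
    for iv in repeat_mask.intervals():
        block = genome[iv.chrom][iv.start : iv.end]
        block[0::2] = 0  # A
        block[1::2] = 3  # T
    return chrom_sizes, genome, genes, repeat_mask


def _place_genes(config, chrom_sizes, rng) -> list[GeneAnnotation]:
    if config.n_genes == 0:
        return []
    edge = 20_000
    slot = 2 * config.min_gene_spacing
    chroms = sorted(chrom_sizes)
    slots_per_chrom = {
        c: max(0, (chrom_sizes[c] - 2 * edge) // slot) for c in chroms
    }
    total_slots = sum(slots_per_chrom.values())
    if total_slots < config.n_genes:
        raise ValidationError(
            f"cannot place {config.n_genes} genes at spacing "
            f"{config.min_gene_spacing} bp; use a larger genome"
        )
    # allocate genes to chromosomes proportionally to capacity
    alloc = {c: config.n_genes * slots_per_chrom[c] // total_slots for c in chroms}
    i = 0
    while sum(alloc.values()) < config.n_genes:
        c = chroms[i % len(chroms)]
        if alloc[c] < slots_per_chrom[c]:
            alloc[c] += 1
        i += 1
    genes = []
    k = 0
    lmin, lmax = config.gene_length_range
    for c in chroms:
        if alloc[c] == 0:
            continue
        chosen = np.sort(rng.choice(slots_per_chrom[c], size=alloc[c], replace=False))
        for s in chosen:
            tss = edge + int(s) * slot + int(rng.integers(0, config.min_gene_spacing))
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(lmin, lmax + 1))
            if strand == "+":
                start, end = tss, min(tss + length, chrom_sizes[c])
            else:
                start, end = max(0, tss - length + 1), tss + 1
            k += 1
            genes.append(
                GeneAnnotation(f"g{k:04d}", GenomicInterval(c, start, end, strand))
            )
    return genes


def _place_repeats(config, chrom_sizes, genes, rng) -> IntervalSet:
    n_sites = 2 * config.n_peaks_per_stage
    n_blocks = int(np.ceil(config.repeat_frac_rate * n_sites * 1.5)) + 3
    block_len = 700
    gene_zones = IntervalSet(
        (g.chrom, max(0, g.interval.start - 7_000), g.interval.end + 7_000)
        for g in genes
    )
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    placed: list[tuple[str, int, int]] = []
    attempts = 0
    while len(placed) < n_blocks and attempts < 200 * n_blocks:
        attempts += 1
        c = chroms[rng.choice(len(chroms), p=probs)]
        s = int(rng.integers(2_000, chrom_sizes[c] - block_len - 2_000))
        if gene_zones.overlaps(c, s - 1_000, s + block_len + 1_000):
            continue
        if any(
            cc == c and s - 2_000 < ee and ss < s + block_len + 2_000
            for cc, ss, ee in placed
        ):
            continue
        placed.append((c, s, s + block_len))
    if len(placed) < n_blocks:
        raise ValidationError("could not place repeat blocks; use a larger genome")
    return IntervalSet(placed)


# ---------------------------------------------------------------------------
# peaks + signal

class _SummitPlacer:
    """Rejection-samples summits per placement category with min spacing."""

    def __init__(self, config, chrom_sizes, genes, repeat_mask, rng):
        self.config = config
        self.chrom_sizes = chrom_sizes
        self.genes = genes
        self.rng = rng
        self.repeat_blocks = repeat_mask.intervals()
        from .peaks import _promoter_windows

        self.promoters = _promoter_windows(genes, 5000, 0)
        self.gene_spans = IntervalSet(
            (g.chrom, g.interval.start, g.interval.end) for g in genes
        )
        self.repeat_zones = IntervalSet(
            (iv.chrom, max(0, iv.start - 1_000), iv.end + 1_000)
            for iv in self.repeat_blocks
        )
        self.chroms = sorted(chrom_sizes)
        sizes = np.array([chrom_sizes[c] for c in self.chroms], dtype=float)
        self.chrom_probs = sizes / sizes.sum()
        self._summits: dict[str, list[int]] = {c: [] for c in self.chroms}
        self._repeat_cursor = 0

    def _spaced(self, chrom: str, pos: int) -> bool:
        import bisect

        lst = self._summits[chrom]
        i = bisect.bisect_left(lst, pos)
        gap = self.config.min_summit_spacing
        if i > 0 and pos - lst[i - 1] < gap:
            return False
        if i < len(lst) and lst[i] - pos < gap:
            return False
        return True

    def _commit(self, chrom: str, pos: int) -> None:
        import bisect

        bisect.insort(self._summits[chrom], pos)

    def place(self, category: str) -> tuple[str, int]:
        for _ in range(5000):
            chrom, pos = getattr(self, f"_draw_{category}")()
            if pos is None:
                continue
            if not self._spaced(chrom, pos):
                continue
            self._commit(chrom, pos)
            return chrom, pos
        raise ValidationError(
            f"cannot place more {category} peaks: genome too dense "
            "(reduce peak count or enlarge genome)"
        )

    def _draw_promoter(self):
        g = self.genes[self.rng.choice(len(self.genes))]
        off = int(self.rng.integers(600, 4_400))
        pos = g.tss - off if g.strand == "+" else g.tss + off
        if not 1_200 <= pos < self.chrom_sizes[g.chrom] - 1_200:
            return g.chrom, None
        return g.chrom, pos

    def _draw_intragenic(self):
        g = self.genes[self.rng.choice(len(self.genes))]
        pos = int(self.rng.integers(g.interval.start, g.interval.end))
        if self.promoters.overlaps(g.chrom, pos, pos + 1):
            return g.chrom, None
        if not 1_200 <= pos < self.chrom_sizes[g.chrom] - 1_200:
            return g.chrom, None
        return g.chrom, pos

    def _draw_intergenic(self):
        c = self.chroms[self.rng.choice(len(self.chroms), p=self.chrom_probs)]
        pos = int(self.rng.integers(1_200, self.chrom_sizes[c] - 1_200))
        if (
            self.gene_spans.overlaps(c, pos, pos + 1)
            or self.promoters.overlaps(c, pos, pos + 1)
            or self.repeat_zones.overlaps(c, pos, pos + 1)
        ):
            return c, None
        return c, pos

    def _draw_repeat(self):
        block = self.repeat_blocks[self._repeat_cursor % len(self.repeat_blocks)]
        self._repeat_cursor += 1
        center = (block.start + block.end) // 2
        pos = center + int(self.rng.integers(-20, 21))
        return block.chrom, pos


def generate_peaks_and_signal(
    config: SimulationConfig,
    chrom_sizes: dict[str, int],
    genome: dict[str, np.ndarray],
    genes: list[GeneAnnotation],
    repeat_mask: IntervalSet,
    rng,
) -> tuple[dict[str, list[PeakCall]], dict[str, SignalTrack], pd.DataFrame]:
    """Two stages of peaks, their signal tracks, and the site manifest.

    Each underlying binding site is class I (bound both stages), II
    (8 hpf only) or III (24 hpf only).  A site contributes a peak call and
    a triangular signal bump in the stage(s) where it is bound; a fraction
    ``motif_plant_rate`` of sites receive one exact consensus motif near
    the summit (written into the genome sequence).
    """
    rng = np.random.default_rng(rng)
    if not genes:
        raise ValidationError("peak generation requires genes")
    placer = _SummitPlacer(config, chrom_sizes, genes, repeat_mask, rng)
    n = config.n_peaks_per_stage
    shared = rng.random(n) < config.frac_shared_peaks
    n_shared = int(shared.sum())
    classes = ["I" if s else "II" for s in shared] + ["III"] * (n - n_shared)

    motif_codes = encode(config.consensus)
    L = motif_codes.size
    cats = np.array(["promoter", "intragenic", "intergenic"])
    mixture = np.asarray(config.distance_mixture, dtype=float)
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))

    rows = []
    wmin, wmax = config.peak_halfwidth_range
    for i, cls in enumerate(classes):
        is_repeat = rng.random() < config.repeat_frac_rate
        category = "repeat" if is_repeat else str(cats[rng.choice(3, p=mixture)])
        chrom, summit = placer.place(category)
        half = 250 if is_repeat else int(rng.integers(wmin, wmax + 1))
        score = float(np.round(rng.uniform(5, 100), 3))
        jitter = (
            int(rng.integers(-config.summit_jitter, config.summit_jitter + 1))
            if (cls == "I" and config.summit_jitter > 0)
            else 0
        )
        planted = rng.random() < config.motif_plant_rate
        motif_offset = None
        if planted:
            motif_offset = int(rng.integers(-360, 361 - L))
            start = summit + motif_offset
            genome[chrom][start : start + L] = motif_codes
        owner = None
        if category in ("promoter", "intragenic", "intergenic"):
            cands = tss_by_chrom.get(chrom, [])
            if cands:
                t, gid = min(cands, key=lambda x: (abs(x[0] - summit), x[1]))
                if abs(t - summit) <= 100_000:
                    owner = gid
        rows.append(
            dict(
                site_id=f"pk{i + 1:05d}",
                chrom=chrom,
                true_class=cls,
                placement=category,
                summit_a=summit if cls in ("I", "II") else pd.NA,
                summit_b=(summit + jitter) if cls in ("I", "III") else pd.NA,
                halfwidth=half,
                score=score,
                motif_planted=planted,
                motif_offset=motif_offset if planted else pd.NA,
                is_repeat=is_repeat,
                owning_gene=owner,
            )
        )
    manifest = pd.DataFrame(rows)

    peaks: dict[str, list[PeakCall]] = {STAGE_A: [], STAGE_B: []}
    for row in manifest.itertuples(index=False):
        for stage, summit in ((STAGE_A, row.summit_a), (STAGE_B, row.summit_b)):
            if pd.isna(summit):
                continue
            summit = int(summit)
            iv = GenomicInterval(row.chrom, summit - row.halfwidth, summit + row.halfwidth)
            peaks[stage].append(
                PeakCall(row.site_id, iv, summit, row.score, stage)
            )

    signal = {
        STAGE_A: _build_signal(config, chrom_sizes, peaks[STAGE_A], rng),
        STAGE_B: _build_signal(config, chrom_sizes, peaks[STAGE_B], rng),
    }
    return peaks, signal, manifest


def _build_signal(config, chrom_sizes, stage_peaks, rng) -> SignalTrack:
    """Per-bin background noise plus a triangular bump at each bound summit."""
    w = config.signal_bump_halfwidth
    h = config.signal_bump_height * config.background_signal
    arrays = {}
    for chrom in sorted(chrom_sizes):
        n = chrom_sizes[chrom]
        nbins = (n + config.signal_bin - 1) // config.signal_bin
        bins = rng.uniform(0.8, 1.2, size=nbins) * config.background_signal
        arr = np.repeat(np.round(bins, 4), config.signal_bin)[:n]
        arrays[chrom] = arr
    for p in stage_peaks:
        arr = arrays[p.chrom]
        lo = max(0, p.summit - w)
        hi = min(arr.size, p.summit + w)
        d = np.abs(np.arange(lo, hi) - p.summit)
        arr[lo:hi] += np.round(h * (1 - d / w), 4)
    for chrom in arrays:
        arrays[chrom] = np.round(arrays[chrom], 4)
    return SignalTrack.from_dense(arrays)


# ---------------------------------------------------------------------------
# conservation

def generate_conservation(
    config: SimulationConfig,
    chrom_sizes: dict[str, int],
    genes: list[GeneAnnotation],
    manifest_peaks: pd.DataFrame,
    rng,
) -> tuple[IdentityTrack, pd.DataFrame]:
    """Identity track: flat background with high-identity CNE islands.

    A fraction of islands is placed overlapping [summit - 500, summit + 500)
    of planted (non-repeat) sites; the rest go to random non-genic space.
    """
    rng = np.random.default_rng(rng)
    gene_zones = IntervalSet(
        (g.chrom, max(0, g.interval.start - 500), g.interval.end + 500) for g in genes
    )
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    lmin, lmax = config.cne_length_range
    n_near = int(round(config.cne_near_peak_frac * config.n_cnes))
    cand = manifest_peaks.loc[~manifest_peaks["is_repeat"]]
    placed: list[tuple[str, int, int, object]] = []

    def clear(c, s, e) -> bool:
        margin = 200
        return not any(
            cc == c and s - margin < ee and ss < e + margin for cc, ss, ee, _ in placed
        )

    attempts = 0
    while len(placed) < n_near and attempts < 200 * max(1, n_near) and len(cand):
        attempts += 1
        row = cand.iloc[int(rng.integers(0, len(cand)))]
        summit = int(row.summit_a if not pd.isna(row.summit_a) else row.summit_b)
        length = int(rng.integers(lmin, lmax + 1))
        s = summit + int(rng.integers(-400, 301))
        e = s + length
        if s < 100 or e > chrom_sizes[row.chrom] - 100 or not clear(row.chrom, s, e):
            continue
        placed.append((row.chrom, s, e, row.site_id))
    attempts = 0
    while len(placed) < config.n_cnes and attempts < 500 * max(1, config.n_cnes):
        attempts += 1
        c = chroms[rng.choice(len(chroms), p=probs)]
        length = int(rng.integers(lmin, lmax + 1))
        s = int(rng.integers(100, chrom_sizes[c] - length - 100))
        if gene_zones.overlaps(c, s, s + length) or not clear(c, s, s + length):
            continue
        placed.append((c, s, s + length, pd.NA))
    if len(placed) < config.n_cnes:
        raise ValidationError("could not place all CNE islands")

    steps: dict[str, list[tuple[int, int, float]]] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for c, s, e, _ in placed:
        by_chrom[c].append((s, e))
    bg = config.background_identity
    for c in chroms:
        rows = []
        pos = 0
        for s, e in sorted(by_chrom[c]):
            if bg > 0 and s > pos:
                rows.append((pos, s, bg))
            rows.append((s, e, config.cne_identity))
            pos = e
        if bg > 0 and pos < chrom_sizes[c]:
            rows.append((pos, chrom_sizes[c], bg))
        steps[c] = rows
    track = IdentityTrack(steps, comparator=config.comparator)
    manifest = pd.DataFrame(
        [
            dict(cne_id=f"cne{i + 1:04d}", chrom=c, start=s, end=e, near_site=site)
            for i, (c, s, e, site) in enumerate(sorted(placed))
        ]
    )
    return track, manifest


# ---------------------------------------------------------------------------
# expression

def generate_expression(
    config: SimulationConfig,
    genes: list[GeneAnnotation],
    manifest_peaks: pd.DataFrame,
    rng,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-stage expression tables with ground-truth target flags.

    A gene is a true target of a stage when it owns a planted (non-repeat)
    site bound in that stage; such genes get |log2 FC| = log2(de_effect) +
    N(0, noise_sd) in a random direction and Beta(target_p_alpha, 1)
    p-values (so P(p <= a) = a**target_p_alpha); all other genes are nulls
    with N(0, noise_sd) log fold changes and uniform p-values.
    """
    rng = np.random.default_rng(rng)
    owners = manifest_peaks.dropna(subset=["owning_gene"])
    bound = {
        STAGE_A: set(owners.loc[owners["true_class"].isin(["I", "II"]), "owning_gene"]),
        STAGE_B: set(owners.loc[owners["true_class"].isin(["I", "III"]), "owning_gene"]),
    }
    contrast = {STAGE_A: "morphant_vs_control", STAGE_B: "gfp_pos_vs_neg"}
    tables = {}
    gene_rows = []
    gene_ids = [g.gene_id for g in genes]
    truth: dict[str, dict[str, tuple[bool, str]]] = {}
    for stage in (STAGE_A, STAGE_B):
        rows = []
        truth[stage] = {}
        for gid in gene_ids:
            is_target = gid in bound[stage]
            direction = "up" if rng.random() < 0.5 else "down"
            if is_target:
                l2 = np.log2(config.de_effect) + rng.normal(0, config.noise_sd)
                # Beta(a, 1) by inverse CDF (x = U**(1/a)); numpy's beta
                # sampler is inaccurate for very small shape parameters
                a = config.target_p_alpha
                p = float(rng.uniform(0, 1) ** (1 / a)) if a > 0 else 0.0
            else:
                l2 = rng.normal(0, config.noise_sd)
                direction = "up" if l2 >= 0 else "down"
                l2 = abs(l2)
                p = float(rng.uniform(0, 1))
            rows.append(
                dict(
                    gene_id=gid,
                    fold_change=float(np.round(2.0 ** max(l2, 0.0), 6)),
                    direction=direction,
                    p_value=float(np.round(p, 10)),
                    stage=stage,
                    contrast=contrast[stage],
                )
            )
            truth[stage][gid] = (is_target, direction)
        tables[stage] = pd.DataFrame(rows)
    for g in genes:
        t8, d8 = truth[STAGE_A][g.gene_id]
        t24, d24 = truth[STAGE_B][g.gene_id]
        gene_rows.append(
            dict(
                gene_id=g.gene_id,
                chrom=g.chrom,
                tss=g.tss,
                strand=g.strand,
                target_8hpf=t8,
                direction_8hpf=d8 if t8 else pd.NA,
                target_24hpf=t24,
                direction_24hpf=d24 if t24 else pd.NA,
            )
        )
    return tables, pd.DataFrame(gene_rows)


# ---------------------------------------------------------------------------
# orchestration

def generate(config: SimulationConfig) -> SyntheticDataset:
    """Run the whole generator deterministically from ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    rng_genome, rng_peaks, rng_cons, rng_expr = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    chrom_sizes, genome, genes, repeat_mask = generate_genome(config, rng_genome)
    peaks, signal, manifest_peaks = generate_peaks_and_signal(
        config, chrom_sizes, genome, genes, repeat_mask, rng_peaks
    )
    identity, manifest_cnes = generate_conservation(
        config, chrom_sizes, genes, manifest_peaks, rng_cons
    )
    expression, manifest_genes = generate_expression(
        config, genes, manifest_peaks, rng_expr
    )
    return SyntheticDataset(
        config=config,
        chrom_sizes=chrom_sizes,
        genome_codes=genome,
        genes=genes,
        repeat_mask=repeat_mask,
        peaks=peaks,
        signal=signal,
        identity=identity,
        expression=expression,
        manifest_peaks=manifest_peaks,
        manifest_genes=manifest_genes,
        manifest_cnes=manifest_cnes,
    )


def true_region_classes(
    manifest_peaks: pd.DataFrame, regions
) -> list[str]:
    """Ground-truth class of each merged region.

    A region is truly bound at a stage if *any* generated binding site —
    including sites later removed by repeat filtering, whose signal bumps
    remain in the tracks — has that stage's summit inside the region.
    """
    import bisect

    per_stage: dict[str, dict[str, list[int]]] = {"a": {}, "b": {}}
    for row in manifest_peaks.itertuples(index=False):
        for key, summit in (("a", row.summit_a), ("b", row.summit_b)):
            if not pd.isna(summit):
                per_stage[key].setdefault(row.chrom, []).append(int(summit))
    for d in per_stage.values():
        for lst in d.values():
            lst.sort()

    def any_in(key, chrom, start, end) -> bool:
        lst = per_stage[key].get(chrom, [])
        i = bisect.bisect_left(lst, start)
        return i < len(lst) and lst[i] < end

    out = []
    for r in regions:
        bound_a = any_in("a", r.chrom, r.start, r.end)
        bound_b = any_in("b", r.chrom, r.start, r.end)
        if not (bound_a or bound_b):
            raise ValidationError(
                f"region {r.chrom}:{r.start}-{r.end} contains no true site"
            )
        out.append("I" if bound_a and bound_b else "II" if bound_a else "III")
    return out
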