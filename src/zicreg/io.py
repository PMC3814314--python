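"""Readers and writers for the formats the pipeline touches.

All readers emit 0-based half-open coordinates regardless of the input
dialect.  Peak lists arrive as BED4+/BED6 (summit as a ``summit=`` key in
the name column) or narrowPeak (summit as the 10th-column offset); gene
annotation as GFF3, GTF or BED12; tracks as bedGraph or fixed-step WIG;
motifs in MEME minimal format; expression tables as TSV.
"""

from __future__ import annotations

import logging
import re
import textwrap
from collections import defaultdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import GeneAnnotation, GenomicInterval, PeakCall, ValidationError
from .tracks import IdentityTrack, SignalTrack

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed line; the message names the file and line number."""


# ---------------------------------------------------------------------------
# Peaks

DEFAULT_PEAK_COLUMNS = {"chrom": 0, "start": 1, "end": 2, "name": 3, "score": 4}


def _parse_name_field(name: str) -> dict:
    out: dict = {}
    for part in name.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
        elif part:
            out.setdefault("id", part)
    return out


def read_peaks(
    path,
    stage: str,
    one_based: bool = False,
    column_map: Optional[dict] = None,
) -> list[PeakCall]:
    """Read a peak list and attach ``stage`` to every record.

    ``column_map`` overrides the default column layout with 0-based column
    indices for ``chrom``, ``start``, ``end`` and optionally ``summit``
    (absolute coordinate), ``score``, ``qvalue`` and ``name``.  Without it,
    the summit is taken from a ``summit=`` key in the 4th column, or — for
    10-column narrowPeak input — from the 10th-column offset.  With
    ``one_based=True``, starts and summits are 1-based and intervals are
    inclusive of their end.
    """
    peaks: list[PeakCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            try:
                peaks.append(
                    _parse_peak_line(fields, stage, one_based, column_map, lineno)
                )
            except (IndexError, TypeError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed peak line") from exc
            except ValueError as exc:
                if isinstance(exc, ValidationError):
                    raise ValidationError(f"{path}:{lineno}: {exc}") from None
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return peaks


def _parse_peak_line(fields, stage, one_based, column_map, lineno) -> PeakCall:
    cm = dict(DEFAULT_PEAK_COLUMNS, **(column_map or {}))
    chrom = fields[cm["chrom"]]
    start = int(fields[cm["start"]])
    end = int(fields[cm["end"]])
    summit = None
    score = 0.0
    qvalue = None
    peak_id = None
    if column_map and "summit" in column_map:
        summit = int(fields[cm["summit"]])
        if "score" in cm and cm["score"] < len(fields):
            score = float(fields[cm["score"]])
        if "qvalue" in cm and cm["qvalue"] < len(fields):
            qvalue = float(fields[cm["qvalue"]])
        if "name" in cm and cm["name"] < len(fields):
            peak_id = fields[cm["name"]]
    elif len(fields) == 10 and "=" not in fields[3]:
        # narrowPeak: summit offset in the 10th column, q in the 9th
        peak_id = fields[3] if fields[3] != "." else None
        score = float(fields[4])
        q = float(fields[8])
        qvalue = 10 ** (-q) if q >= 0 else None
        offset = int(fields[9])
        if offset < 0:
            raise ValueError("narrowPeak summit offset is -1 (absent)")
        summit = start + offset
    else:
        meta = _parse_name_field(fields[3]) if len(fields) > 3 else {}
        if "summit" not in meta:
            raise ValueError("no summit (need summit= key or narrowPeak layout)")
        summit = int(meta["summit"])
        peak_id = meta.get("id")
        if "qvalue" in meta:
            qvalue = float(meta["qvalue"])
        if len(fields) > 4:
            score = float(fields[4])
    if one_based:
        start -= 1
        summit -= 1
    interval = GenomicInterval(chrom, start, end)
    return PeakCall(
        peak_id=peak_id or f"{stage}_peak{lineno}",
        interval=interval,
        summit=summit,
        score=score,
        stage=stage,
        qvalue=qvalue,
    )


def write_peaks(peaks, path) -> None:
    """Write peaks as BED6 with the summit in the name column (round-trips)."""
    with open(path, "w") as fh:
        for p in peaks:
            name = f"id={p.peak_id};summit={p.summit}"
            if p.qvalue is not None:
                name += f";qvalue={p.qvalue:.6g}"
            fh.write(
                f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{name}\t{p.score:.6g}\t.\n"
            )


# ---------------------------------------------------------------------------
# Gene annotation

_GFF_ATTR = re.compile(r"\s*([^=;]+)=([^;]*)")
_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gene_annotation(path) -> list[GeneAnnotation]:
    """Read GFF3, GTF or BED12 and collapse each gene to its longest transcript.

    The TSS is the strand-aware transcript start.  A gene without a strand
    is an error; a gene id recurring with conflicting coordinates is an
    error listing the offending ids.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".gff", ".gff3"}:
        spans = _gene_spans_gff(path, gtf=False)
    elif suffix == ".gtf":
        spans = _gene_spans_gff(path, gtf=True)
    elif suffix in {".bed", ".bed12"}:
        spans = _gene_spans_bed12(path)
    else:
        raise ParseError(f"unrecognized annotation format: {path.name}")
    genes = []
    for gene_id, candidates in sorted(spans.items()):
        chrom, start, end, strand = max(
            candidates, key=lambda c: (c[2] - c[1], c)
        )
        if strand not in {"+", "-"}:
            raise ValidationError(f"gene {gene_id} has no strand")
        genes.append(
            GeneAnnotation(gene_id, GenomicInterval(chrom, start, end, strand))
        )
    return genes


def _gene_spans_gff(path, gtf: bool) -> dict[str, list[tuple]]:
    """Per gene id, candidate transcript spans (chrom, start, end, strand)."""
    transcripts: dict[str, list[tuple]] = defaultdict(list)
    gene_rows: dict[str, list[tuple]] = defaultdict(list)
    tx_types = {"mRNA", "transcript", "ncRNA", "lnc_RNA"}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            chrom, _, ftype, start1, end1, _, strand, _, attrs = f[:9]
            try:
                span = (chrom, int(start1) - 1, int(end1), strand)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from None
            pat = _GTF_ATTR if gtf else _GFF_ATTR
            ad = dict(pat.findall(attrs))
            if ftype == "gene":
                gid = ad.get("gene_id") or ad.get("ID")
                if gid:
                    gene_rows[gid].append(span)
            elif ftype in tx_types:
                gid = ad.get("gene_id") or ad.get("Parent") or ad.get("ID")
                if gid:
                    transcripts[gid].append(span)
    dupes = sorted(
        gid for gid, rows in gene_rows.items() if len(set(rows)) > 1
    )
    if dupes:
        raise ValidationError(
            "duplicate gene ids with conflicting coordinates: " + ", ".join(dupes)
        )
    spans: dict[str, list[tuple]] = dict(gene_rows)
    for gid, rows in transcripts.items():
        spans[gid] = rows  # transcripts define the gene where present
    return spans


def _gene_spans_bed12(path) -> dict[str, list[tuple]]:
    spans: dict[str, list[tuple]] = defaultdict(list)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: BED12 needs >= 6 columns")
            spans[f[3]].append((f[0], int(f[1]), int(f[2]), f[5]))
    return spans


def write_gene_annotation(genes, path, source: str = "zicreg") -> None:
    """Write genes as GFF3 (one gene + one mRNA record per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.interval.start, g.gene_id)):
            s1, e1 = g.interval.start + 1, g.interval.end
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\t{source}\tmRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Tracks

def read_track(path, kind: str = "signal", library_size: Optional[float] = None):
    """Read a bedGraph or fixed-step WIG file.

    ``kind`` selects :class:`SignalTrack` (default) or :class:`IdentityTrack`.
    A ``#library_size=`` or ``#comparator=`` header comment is honored.
    Overlapping steps and identity values outside [0, 1] are errors.
    """
    if kind not in {"signal", "identity"}:
        raise ValueError("kind must be 'signal' or 'identity'")
    steps: dict[str, list[tuple[int, int, float]]] = defaultdict(list)
    meta: dict[str, str] = {}
    wig_state = None  # (chrom, next_start, step, span) for fixedStep blocks
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(\w+)\s*=\s*(\S+)", line)
                if m:
                    meta[m.group(1)] = m.group(2)
                continue
            if line.startswith(("track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(p.split("=") for p in line.split()[1:])
                wig_state = (
                    kv["chrom"],
                    int(kv["start"]) - 1,  # WIG is 1-based
                    int(kv.get("step", 1)),
                    int(kv.get("span", kv.get("step", 1))),
                )
                continue
            f = line.split()
            try:
                if wig_state is not None and len(f) == 1:
                    chrom, pos, step, span = wig_state
                    steps[chrom].append((pos, pos + span, float(f[0])))
                    wig_state = (chrom, pos + step, step, span)
                else:
                    steps[f[0]].append((int(f[1]), int(f[2]), float(f[3])))
            except (ValueError, IndexError):
                raise ParseError(f"{path}:{lineno}: malformed track line") from None
    if not steps:
        log.warning("empty track file: %s", path)
    if kind == "identity":
        return IdentityTrack(steps, comparator=meta.get("comparator", "unknown"))
    lib = library_size
    if lib is None and "library_size" in meta:
        lib = float(meta["library_size"])
    if lib is None:
        lib = sum(
            sum(v * (e - s) for s, e, v in rows) for rows in steps.values()
        ) or 1.0
        log.info("no library size given; using track integral %.4g", lib)
    return SignalTrack(steps, library_size=lib)


def write_track(track, path) -> None:
    """Write a track as bedGraph with its metadata in header comments."""
    with open(path, "w") as fh:
        if isinstance(track, SignalTrack):
            fh.write(f"#library_size={track.library_size:.10g}\n")
        elif isinstance(track, IdentityTrack):
            fh.write(f"#comparator={track.comparator}\n")
        for chrom in track.chroms:
            for s, e, v in track.steps(chrom):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            fh.write(textwrap.fill(sequences[name], width=width))
            fh.write("\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a plain dict (small genomes only)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


# ---------------------------------------------------------------------------
# Expression tables

EXPRESSION_COLUMNS = ["gene_id", "fold_change", "direction", "p_value"]


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EXPRESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing expression columns {sorted(missing)}")
    if ((df["p_value"] < 0) | (df["p_value"] > 1)).any():
        raise ValidationError(f"{path}: p-values outside [0, 1]")
    if (df["fold_change"] <= 0).any():
        raise ValidationError(f"{path}: non-positive fold changes")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# MEME minimal motif format
#
# Biopython's minimal-format parser rescales probabilities into integer
# counts, which does not round-trip arbitrary probability columns, so the
# (tiny) format is read and written directly here.

def read_meme(path):
    """Read MEME minimal format; returns a list of :class:`zicreg.motifs.Pwm`."""
    from .motifs import Pwm

    background = None
    motifs = []
    name = None
    rows: list[list[float]] = []
    expect_bg = False
    in_matrix = False

    def flush():
        nonlocal name, rows, in_matrix
        if name is not None and rows:
            motifs.append(
                Pwm(np.array(rows), name=name, background=background)
            )
        name, rows, in_matrix = None, [], False

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if expect_bg and line:
                vals = line.split()
                background = np.array(
                    [float(vals[vals.index(b) + 1]) for b in "ACGT"]
                )
                expect_bg = False
                continue
            if line.startswith("Background letter frequencies"):
                expect_bg = True
            elif line.startswith("MOTIF"):
                flush()
                name = line.split()[1]
            elif line.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix and line and line[0] in "0123456789.":
                rows.append([float(x) for x in line.split()])
            elif in_matrix and (not line or not line[0] in "0123456789."):
                in_matrix = False
    flush()
    if not motifs:
        raise ParseError(f"{path}: no motifs found")
    return motifs


def write_meme(pwms, path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {v:.6g}" for b, v in zip("ACGT", bg)) + "\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.raw_probs:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
            fh.write("\n")
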